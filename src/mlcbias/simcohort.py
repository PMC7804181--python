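"""Synthetic cohorts with disease ascertainment of a behavioural trait.

Generates the data structures the rest of the package analyses: a polygenic
behavioural trait Y, a disease liability D (liability-threshold model for the
binary disease), ascertainment of the behaviour (individuals in the top
fraction of liability reduce their reported Y by a fixed number of SDs and are
labelled LESS), misreports (underreporting and non-response, optionally
liability-dependent), and a J-shaped exposure-outcome world for risk-curve
experiments.

Four scenarios govern the genetic architecture:

    I   — D independent of Y; the causal SNPs affect Y only.
    II  — Y causal for D (liability-scale effect b_yd); SNPs affect Y and
          D only through Y.
    III — Y and D independent; the causal SNPs affect D only.
    IV  — Y causal for D, plus a second, disjoint set of SNPs affecting D
          directly.

All phenotypes are built to unit variance; the disease is liability above the
standard-normal quantile set by the configured prevalence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

# Synthetic chromosome layout: one chromosome, 1-based positions, fixed spacing.
POSITION_SPACING = 100_000

LESS, SAME, MORE = "LESS", "SAME", "MORE"
ILLNESS_OR_DOCTOR = "ILLNESS_OR_DOCTOR"
HEALTH_PRECAUTION = "HEALTH_PRECAUTION"
FINANCIAL = "FINANCIAL"
OTHER = "OTHER"
NONE = "NONE"

SCENARIOS = ("I", "II", "III", "IV")


class ConfigurationError(ValueError):
    """Raised for invalid simulation configuration."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Genetic architecture and sample layout of one simulated cohort.

    ``h2_y``/``h2_d`` are the variances of the direct genetic components of Y
    and of D (D's applies in scenarios III/IV only); ``b_yd`` is the causal
    effect of Y on D per SD of Y on the liability scale (scenarios II/IV).
    """

    scenario_id: str = "I"
    n_individuals: int = 10_000
    n_snps: int = 1_000
    n_causal_y: int = 100
    n_causal_d: int = 100
    h2_y: float = 0.3
    h2_d: float = 0.3
    b_yd: float = 0.3
    disease_prevalence: float = 0.15
    maf_range: tuple[float, float] = (0.01, 0.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario_id not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario_id!r}")
        if not 0.0 <= self.h2_y <= 1.0:
            raise ConfigurationError("h2_y must lie in [0, 1]")
        if not 0.0 <= self.h2_d <= 1.0:
            raise ConfigurationError("h2_d must lie in [0, 1]")
        if not 0.0 < self.disease_prevalence < 1.0:
            raise ConfigurationError("disease_prevalence must lie in (0, 1)")
        _check_maf_range(self.maf_range)
        needed = self.n_causal_y * (self.scenario_id != "III") + self.n_causal_d * (
            self.scenario_id in ("III", "IV")
        )
        if needed > self.n_snps:
            raise ConfigurationError(
                f"causal sets ({needed}) exceed number of SNPs ({self.n_snps})"
            )
        # residual liability variance must be non-negative
        var_gen_d = self.h2_d if self.scenario_id in ("III", "IV") else 0.0
        var_yd = self.b_yd**2 if self.scenario_id in ("II", "IV") else 0.0
        if var_gen_d + var_yd > 1.0:
            raise ConfigurationError("h2_d + b_yd^2 exceeds unit liability variance")


@dataclass(frozen=True)
class AscertainmentConfig:
    """Disease ascertainment of the behaviour.

    The top ``threshold_q`` fraction of liability gets its reported behaviour
    reduced by ``shift_c`` sample SDs of the true behaviour and is labelled
    LESS; a sub-fraction ``illness_fraction`` of those carry the
    illness-or-doctor reason, the rest OTHER.
    """

    threshold_q: float = 0.10
    shift_c: float = 2.0
    illness_fraction: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.threshold_q < 1.0:
            raise ConfigurationError("threshold_q must lie in [0, 1)")
        if self.shift_c < 0:
            raise ConfigurationError("shift_c must be >= 0")
        if not 0.0 <= self.illness_fraction <= 1.0:
            raise ConfigurationError("illness_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class MisreportConfig:
    """Underreporting (reported value forced to 0) and non-response (missing).

    Per-individual probabilities are logistic in liability with slope
    ``*_liability_dependence`` (log-odds per SD of liability), with the
    intercept calibrated so the marginal rate equals the configured fraction.
    """

    underreport_frac: float = 0.0
    underreport_liability_dependence: float = 0.0
    nonresponse_frac: float = 0.0
    nonresponse_liability_dependence: float = 0.0

    def __post_init__(self) -> None:
        for f in (self.underreport_frac, self.nonresponse_frac):
            if not 0.0 <= f <= 1.0:
                raise ConfigurationError("misreport fractions must lie in [0, 1]")


@dataclass
class Cohort:
    """One simulated cohort: genotypes, phenotypes and change-group labels."""

    genotypes: np.ndarray  # (n, m) allele counts in {0, 1, 2}
    positions: np.ndarray  # (m,) 1-based bp on one synthetic chromosome
    snp_ids: np.ndarray  # (m,) str
    true_y: np.ndarray
    reported_y: np.ndarray  # NaN = missing (non-response)
    liability_d: np.ndarray
    disease: np.ndarray  # 0/1
    sex: np.ndarray  # 0/1
    age: np.ndarray  # years
    change_group: np.ndarray  # LESS / SAME / MORE
    reason: np.ndarray  # reason for reduction; NONE outside LESS
    causal_idx_y: np.ndarray
    causal_idx_d: np.ndarray
    true_beta_y: np.ndarray  # (m,) per-SNP direct effect on Y
    true_gamma_d: np.ndarray  # (m,) per-SNP direct effect on D
    drinker_status: np.ndarray | None = None  # optional: never/former/current
    config: ScenarioConfig | None = None

    @property
    def n(self) -> int:
        return self.genotypes.shape[0]

    @property
    def m(self) -> int:
        return self.genotypes.shape[1]

    def copy(self) -> "Cohort":
        return Cohort(
            genotypes=self.genotypes,  # genotypes are never mutated in place
            positions=self.positions,
            snp_ids=self.snp_ids,
            true_y=self.true_y.copy(),
            reported_y=self.reported_y.copy(),
            liability_d=self.liability_d.copy(),
            disease=self.disease.copy(),
            sex=self.sex.copy(),
            age=self.age.copy(),
            change_group=self.change_group.copy(),
            reason=self.reason.copy(),
            causal_idx_y=self.causal_idx_y,
            causal_idx_d=self.causal_idx_d,
            true_beta_y=self.true_beta_y,
            true_gamma_d=self.true_gamma_d,
            drinker_status=None
            if self.drinker_status is None
            else self.drinker_status.copy(),
            config=self.config,
        )

    def subset(self, idx: np.ndarray) -> "Cohort":
        """Row-subset of the cohort (individuals), sharing SNP metadata."""
        c = self.copy()
        c.genotypes = self.genotypes[idx]
        for name in (
            "true_y",
            "reported_y",
            "liability_d",
            "disease",
            "sex",
            "age",
            "change_group",
            "reason",
        ):
            setattr(c, name, getattr(self, name)[idx])
        if self.drinker_status is not None:
            c.drinker_status = self.drinker_status[idx]
        return c

    def to_phenotype_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "id": np.arange(self.n),
                "sex": self.sex,
                "age": self.age,
                "true_y": self.true_y,
                "reported_y": self.reported_y,
                "liability_d": self.liability_d,
                "disease": self.disease,
                "change_group": self.change_group,
                "reason": self.reason,
            }
        )
        if self.drinker_status is not None:
            df["drinker_status"] = self.drinker_status
        return df


def _check_maf_range(maf_range) -> None:
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ConfigurationError(f"maf_range {maf_range} must lie within (0, 0.5]")


def default_positions(m: int) -> np.ndarray:
    """1-based bp positions at fixed spacing on one synthetic chromosome."""
    return 1 + POSITION_SPACING * np.arange(m, dtype=np.int64)


def default_snp_ids(m: int) -> np.ndarray:
    return np.array([f"snp{j}" for j in range(m)])


def simulate_genotypes(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.01, 0.5),
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """HWE, linkage-equilibrium genotypes: per-SNP binomial(2, MAF) counts.

    MAFs are uniform on ``maf_range``. Deterministic given ``seed``.
    """
    _check_maf_range(maf_range)
    if rng is None:
        rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_range[0], maf_range[1], size=m)
    return rng.binomial(2, mafs, size=(n, m)).astype(np.int8)


def simulate_genotypes_ld(
    n: int,
    m: int,
    maf_range: tuple[float, float] = (0.05, 0.5),
    block_size: int = 20,
    rho: float = 0.8,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Block-correlated genotypes: AR(1) latent Gaussians within blocks.

    Two haplotypes per individual; within a block the latent Gaussian follows
    z_j = rho*z_{j-1} + sqrt(1-rho^2)*eps, restarting at block boundaries, and
    the allele is carried when the latent falls below the MAF quantile. Gives
    LD decaying roughly as rho^|i-j| within blocks, zero across blocks.
    """
    _check_maf_range(maf_range)
    if not 0.0 <= rho < 1.0:
        raise ConfigurationError("rho must lie in [0, 1)")
    if rng is None:
        rng = np.random.default_rng(seed)
    mafs = rng.uniform(maf_range[0], maf_range[1], size=m)
    thresh = stats.norm.ppf(mafs)
    geno = np.zeros((n, m), dtype=np.int8)
    for _hap in range(2):
        z = np.empty((n, m))
        eps = rng.standard_normal((n, m))
        for j in range(m):
            if j % block_size == 0:
                z[:, j] = eps[:, j]
            else:
                z[:, j] = rho * z[:, j - 1] + math.sqrt(1 - rho**2) * eps[:, j]
        geno += (z < thresh).astype(np.int8)
    return geno


def _scaled_effects(
    genotypes: np.ndarray, causal_idx: np.ndarray, h2: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw causal effects and scale so the genetic component has variance h2.

    Returns (per-SNP effect vector over all m SNPs, genetic values).
    """
    m = genotypes.shape[1]
    beta = np.zeros(m)
    if h2 == 0.0 or len(causal_idx) == 0:
        return beta, np.zeros(genotypes.shape[0])
    raw = rng.standard_normal(len(causal_idx))
    g = genotypes[:, causal_idx].astype(float) @ raw
    v = g.var()
    if v == 0:
        raise ConfigurationError("causal genotypes carry no variance")
    scale = math.sqrt(h2 / v)
    beta[causal_idx] = raw * scale
    g = g * scale
    return beta, g - g.mean()  # centred so downstream thresholds see mean 0


def simulate_scenario(cfg: ScenarioConfig) -> Cohort:
    """Simulate one cohort under the configured scenario.

    Y = X·beta + e_y with the genetic part scaled to variance ``h2_y`` and
    var(Y)=1; the liability D adds b_yd·Y (scenarios II/IV) and a direct
    genetic part of variance ``h2_d`` (scenarios III/IV) to Gaussian noise so
    var(D)=1. Disease is liability above the (1−prevalence) normal quantile.
    ``reported_y`` starts equal to ``true_y`` and ``change_group`` to SAME.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_geno, rng_eff, rng_noise, rng_misc = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    n, m = cfg.n_individuals, cfg.n_snps
    genotypes = simulate_genotypes(n, m, cfg.maf_range, rng=rng_geno)

    snp_order = rng_eff.permutation(m)
    y_genetic = cfg.scenario_id != "III"
    d_genetic = cfg.scenario_id in ("III", "IV")
    y_on_d = cfg.scenario_id in ("II", "IV")

    causal_idx_y = np.sort(snp_order[: cfg.n_causal_y]) if y_genetic else np.array([], int)
    causal_idx_d = (
        np.sort(snp_order[cfg.n_causal_y : cfg.n_causal_y + cfg.n_causal_d])
        if d_genetic
        else np.array([], int)
    )

    beta_y, g_y = _scaled_effects(
        genotypes, causal_idx_y, cfg.h2_y if y_genetic else 0.0, rng_eff
    )
    gamma_d, g_d = _scaled_effects(
        genotypes, causal_idx_d, cfg.h2_d if d_genetic else 0.0, rng_eff
    )

    h2y = cfg.h2_y if y_genetic else 0.0
    true_y = g_y + rng_noise.standard_normal(n) * math.sqrt(max(1.0 - h2y, 0.0))

    var_e_d = 1.0
    liability = np.zeros(n)
    if y_on_d:
        liability += cfg.b_yd * true_y
        var_e_d -= cfg.b_yd**2
    if d_genetic:
        liability += g_d
        var_e_d -= cfg.h2_d
    liability = liability + rng_noise.standard_normal(n) * math.sqrt(max(var_e_d, 0.0))

    threshold = stats.norm.ppf(1.0 - cfg.disease_prevalence)
    disease = (liability > threshold).astype(np.int8)

    sex = rng_misc.integers(0, 2, size=n).astype(np.int8)
    age = rng_misc.uniform(40.0, 70.0, size=n)

    return Cohort(
        genotypes=genotypes,
        positions=default_positions(m),
        snp_ids=default_snp_ids(m),
        true_y=true_y,
        reported_y=true_y.copy(),
        liability_d=liability,
        disease=disease,
        sex=sex,
        age=age,
        change_group=np.full(n, SAME, dtype=object),
        reason=np.full(n, NONE, dtype=object),
        causal_idx_y=causal_idx_y,
        causal_idx_d=causal_idx_d,
        true_beta_y=beta_y,
        true_gamma_d=gamma_d,
        config=cfg,
    )


def apply_ascertainment(
    cohort: Cohort,
    acfg: AscertainmentConfig,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Shift reported behaviour down for the top-liability fraction.

    Exactly ``ceil(q*n)`` individuals with the highest liability (ties broken
    by index) get ``reported_y = true_y − c·SD(true_y)`` and change_group
    LESS, with reason ILLNESS_OR_DOCTOR for the configured sub-fraction and
    OTHER for the rest. All other records are untouched.
    """
    out = cohort.copy()
    k = math.ceil(acfg.threshold_q * cohort.n)
    if k == 0:
        return out
    # stable sort on -liability: ties resolved by ascending index
    order = np.argsort(-cohort.liability_d, kind="stable")
    top = order[:k]
    sd = float(np.std(cohort.true_y, ddof=1))
    out.reported_y[top] = cohort.true_y[top] - acfg.shift_c * sd
    out.change_group[top] = LESS
    n_ill = int(round(acfg.illness_fraction * k))
    if rng is not None:
        ill = rng.permutation(k)[:n_ill]
    else:
        ill = np.arange(n_ill)
    reasons = np.full(k, OTHER, dtype=object)
    reasons[ill] = ILLNESS_OR_DOCTOR
    out.reason[top] = reasons
    return out


def _calibrate_logistic_intercept(
    frac: float, slope: float, liability: np.ndarray
) -> float:
    """Intercept a such that mean(sigmoid(a + slope*D)) == frac."""
    if frac <= 0.0:
        return -np.inf
    if frac >= 1.0:
        return np.inf

    def marginal(a: float) -> float:
        return float(np.mean(special.expit(a + slope * liability))) - frac

    lo, hi = -50.0, 50.0
    if marginal(lo) > 0 or marginal(hi) < 0:
        raise ConfigurationError("marginal misreport rate is not calibratable")
    return optimize.brentq(marginal, lo, hi, xtol=1e-12)


def apply_misreport(
    cohort: Cohort,
    mcfg: MisreportConfig,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> Cohort:
    """Inject underreporting (reported value 0) and non-response (missing).

    Each mechanism is Bernoulli with a logistic-in-liability probability whose
    intercept is calibrated so the marginal rate equals the configured
    fraction. Non-response is applied after underreporting and overrides it.
    """
    out = cohort.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    if mcfg.underreport_frac > 0:
        a = _calibrate_logistic_intercept(
            mcfg.underreport_frac,
            mcfg.underreport_liability_dependence,
            cohort.liability_d,
        )
        p = special.expit(a + mcfg.underreport_liability_dependence * cohort.liability_d)
        hit = rng.random(cohort.n) < p
        out.reported_y[hit] = 0.0
    if mcfg.nonresponse_frac > 0:
        a = _calibrate_logistic_intercept(
            mcfg.nonresponse_frac,
            mcfg.nonresponse_liability_dependence,
            cohort.liability_d,
        )
        p = special.expit(a + mcfg.nonresponse_liability_dependence * cohort.liability_d)
        hit = rng.random(cohort.n) < p
        out.reported_y[hit] = np.nan
    return out


@dataclass(frozen=True)
class JCurve:
    """Piecewise-quadratic dose-response with a unique interior minimum.

    y = left_coef*(x−x_min)^2 left of the minimum, right_coef*(x−x_min)^2 to
    the right (plus ``base``). Positive coefficients give the J shape.
    """

    x_min: float = 1.0
    left_coef: float = 1.0
    right_coef: float = 0.5
    base: float = 0.0

    def __post_init__(self) -> None:
        if self.left_coef <= 0 or self.right_coef <= 0:
            raise ConfigurationError("JCurve requires positive curvature on both sides")

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        d = x - self.x_min
        return self.base + np.where(d < 0, self.left_coef, self.right_coef) * d**2


def simulate_jshape_world(
    n: int,
    curve,
    seed: int = 0,
    h2: float = 0.5,
    m: int = 200,
    n_causal: int = 50,
    noise_sd: float = 0.5,
    maf_range: tuple[float, float] = (0.05, 0.5),
) -> pd.DataFrame:
    """Polygenic exposure x, outcome y = curve(x) + noise.

    Returns a frame with columns ``x``, ``genetic_predictor_x`` (the true
    genetic component of x) and ``y``. Any callable curve is accepted;
    :class:`JCurve` provides the standard piecewise-quadratic J.
    """
    ss = np.random.SeedSequence(seed)
    rng_geno, rng_eff, rng_noise = (np.random.default_rng(s) for s in ss.spawn(3))
    genotypes = simulate_genotypes(n, m, maf_range, rng=rng_geno)
    causal = np.sort(rng_eff.permutation(m)[:n_causal])
    _, g = _scaled_effects(genotypes, causal, h2, rng_eff)
    x = g + rng_noise.standard_normal(n) * math.sqrt(max(1.0 - h2, 0.0))
    y = np.asarray(curve(x), dtype=float) + rng_noise.standard_normal(n) * noise_sd
    return pd.DataFrame({"x": x, "genetic_predictor_x": g, "y": y})


# ---------------------------------------------------------------------------
# Cohort I/O: phenotype TSV + plain-text genotype matrix + JSON config
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, outdir) -> None:
    """Write phenotypes (TSV), SNP map (TSV), genotypes (text matrix), config."""
    import json
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cohort.to_phenotype_frame().to_csv(outdir / "pheno.tsv", sep="\t", index=False)
    snps = pd.DataFrame(
        {
            "snp": cohort.snp_ids,
            "pos": cohort.positions,
            "beta_y": cohort.true_beta_y,
            "gamma_d": cohort.true_gamma_d,
        }
    )
    snps.to_csv(outdir / "snps.tsv", sep="\t", index=False)
    np.savetxt(outdir / "geno.txt", cohort.genotypes, fmt="%d")
    if cohort.config is not None:
        cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(cohort.config).items()}
        (outdir / "config.json").write_text(json.dumps(cfg, indent=1))


def read_cohort(indir) -> Cohort:
    import json
    from pathlib import Path

    indir = Path(indir)
    pheno = pd.read_csv(indir / "pheno.tsv", sep="\t")
    snps = pd.read_csv(indir / "snps.tsv", sep="\t")
    genotypes = np.loadtxt(indir / "geno.txt", dtype=np.int8, ndmin=2)
    cfg = None
    cfg_path = indir / "config.json"
    if cfg_path.exists():
        raw = json.loads(cfg_path.read_text())
        raw["maf_range"] = tuple(raw["maf_range"])
        cfg = ScenarioConfig(**raw)
    beta_y = snps["beta_y"].to_numpy()
    gamma_d = snps["gamma_d"].to_numpy()
    return Cohort(
        genotypes=genotypes,
        positions=snps["pos"].to_numpy(),
        snp_ids=snps["snp"].to_numpy(),
        true_y=pheno["true_y"].to_numpy(float),
        reported_y=pheno["reported_y"].to_numpy(float),
        liability_d=np.zeros(len(pheno)) if "liability_d" not in pheno else pheno["liability_d"].to_numpy(float),
        disease=pheno["disease"].to_numpy(np.int8),
        sex=pheno["sex"].to_numpy(np.int8),
        age=pheno["age"].to_numpy(float),
        change_group=pheno["change_group"].to_numpy(object),
        reason=pheno["reason"].to_numpy(object),
        causal_idx_y=np.flatnonzero(beta_y != 0),
        causal_idx_d=np.flatnonzero(gamma_d != 0),
        true_beta_y=beta_y,
        true_gamma_d=gamma_d,
        drinker_status=pheno["drinker_status"].to_numpy(object)
        if "drinker_status" in pheno
        else None,
        config=cfg,
    )
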