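"""Correlation of true SNP effects (r_b) between two summary-statistic sets.

Estimated GWAS effects are true effects plus estimation error, so the naive
correlation of two columns of betas is attenuated (and, with overlapping
samples, contaminated by correlated errors). The estimator here removes the
error variance by the method of moments:

    var_true_k = var(b_k) − mean(se_k²)            k = 1, 2
    cov_true   = cov(b_1, b_2) − overlap_term
    r_b        = cov_true / sqrt(var_true_1 · var_true_2)

with the overlap term zero for non-overlapping samples and otherwise
estimated from the mean product of z-scores at null SNPs. The standard error
comes from a delete-one-SNP jackknife.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .assoc import ClumpConfig
from .simcohort import ScenarioConfig


class UnstableEstimateError(ValueError):
    """Estimation-error variance exceeds the total effect variance."""


@dataclass
class RbEstimate:
    """Error-corrected SNP-effect correlation with jackknife SE.

    ``rb`` is clamped to [−1, 1]; ``rb_raw`` keeps the unclamped value and
    ``clamped`` flags when they differ.
    """

    rb: float
    rb_raw: float
    se: float
    n_snps: int
    overlap_term: float
    clamped: bool

    def to_dict(self) -> dict:
        return {
            "rb": self.rb,
            "rb_raw": self.rb_raw,
            "se": self.se,
            "n_snps": self.n_snps,
            "overlap_term": self.overlap_term,
            "clamped": self.clamped,
        }


def _harmonised_effects(
    set1: pd.DataFrame, set2: pd.DataFrame, snps
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Aligned (b1, se1, b2, se2) over shared SNPs, signs harmonised to set1."""
    a = set1.set_index("snp")
    b = set2.set_index("snp")
    if snps is None:
        ids = a.index.intersection(b.index)
    else:
        ids = pd.Index(np.asarray(snps))
        ids = ids[ids.isin(a.index) & ids.isin(b.index)]
    a = a.loc[ids]
    b = b.loc[ids]
    flip = (a["a1"].to_numpy() == b["a2"].to_numpy()) & (
        a["a2"].to_numpy() == b["a1"].to_numpy()
    )
    same = (a["a1"].to_numpy() == b["a1"].to_numpy()) & (
        a["a2"].to_numpy() == b["a2"].to_numpy()
    )
    if not np.all(same | flip):
        from .mlc import HarmonisationError

        raise HarmonisationError("allele mismatch between summary sets")
    b1 = a["beta"].to_numpy(float)
    se1 = a["se"].to_numpy(float)
    b2 = np.where(flip, -b["beta"].to_numpy(float), b["beta"].to_numpy(float))
    se2 = b["se"].to_numpy(float)
    ok = np.isfinite(b1) & np.isfinite(b2) & (se1 > 0) & (se2 > 0)
    return b1[ok], se1[ok], b2[ok], se2[ok]


def _rb_from_moments(
    b1: np.ndarray,
    se1: np.ndarray,
    b2: np.ndarray,
    se2: np.ndarray,
    overlap_r: float,
) -> float:
    v1 = np.var(b1, ddof=1) - np.mean(se1**2)
    v2 = np.var(b2, ddof=1) - np.mean(se2**2)
    if v1 <= 0 or v2 <= 0:
        raise UnstableEstimateError(
            "estimation-error variance exceeds effect variance "
            f"(var_true_1={v1:.3g}, var_true_2={v2:.3g}); the trait may carry "
            "no detectable genetic signal at these SNPs"
        )
    cov = np.cov(b1, b2, ddof=1)[0, 1] - overlap_r * np.mean(se1 * se2)
    return float(cov / np.sqrt(v1 * v2))


def _overlap_r(set1: pd.DataFrame, set2: pd.DataFrame) -> float:
    """Error correlation from the mean product of z-scores at null SNPs.

    Null SNPs are those with |z| < 2 in both sets; for independent samples the
    expectation is 0.
    """
    a = set1.set_index("snp")
    b = set2.set_index("snp")
    ids = a.index.intersection(b.index)
    z1 = (a.loc[ids, "beta"] / a.loc[ids, "se"]).to_numpy(float)
    z2 = (b.loc[ids, "beta"] / b.loc[ids, "se"]).to_numpy(float)
    ok = np.isfinite(z1) & np.isfinite(z2) & (np.abs(z1) < 2) & (np.abs(z2) < 2)
    if ok.sum() < 10:
        return 0.0
    return float(np.clip(np.mean(z1[ok] * z2[ok]), -1.0, 1.0))


def estimate_rb(
    set1: pd.DataFrame,
    set2: pd.DataFrame,
    snps=None,
    overlap: bool = False,
) -> RbEstimate:
    """Error-corrected correlation of true SNP effects between two scans.

    ``snps`` restricts the estimate to a SNP subset (e.g. the causal set in
    simulations or clumped significant SNPs otherwise); ``overlap=True``
    estimates and removes the correlated-error term for overlapping samples.
    Raises :class:`UnstableEstimateError` when either trait's effect variance
    does not exceed its estimation-error variance.
    """
    b1, se1, b2, se2 = _harmonised_effects(set1, set2, snps)
    n = b1.size
    if n < 3:
        raise ValueError("need at least 3 shared SNPs")
    overlap_r = _overlap_r(set1, set2) if overlap else 0.0
    rb_raw = _rb_from_moments(b1, se1, b2, se2, overlap_r)

    # delete-one-SNP jackknife
    jack = np.empty(n)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        mask[i] = False
        try:
            jack[i] = _rb_from_moments(b1[mask], se1[mask], b2[mask], se2[mask], overlap_r)
        except UnstableEstimateError:
            jack[i] = rb_raw
        mask[i] = True
    se = float(np.sqrt((n - 1) / n * np.sum((jack - jack.mean()) ** 2)))
    if se == 0:
        se = np.finfo(float).tiny  # degenerate but positive, per contract

    rb = float(np.clip(rb_raw, -1.0, 1.0))
    return RbEstimate(
        rb=rb,
        rb_raw=rb_raw,
        se=se,
        n_snps=int(n),
        overlap_term=float(overlap_r * np.mean(se1 * se2)),
        clamped=rb != rb_raw,
    )


def rb_grid(
    scenario: ScenarioConfig,
    q_grid=(0.10, 0.20, 0.30, 0.40),
    c_grid=(1.0, 2.0, 3.0, 4.0, 5.0),
    reps: int = 20,
    corrected: bool = False,
    snp_mode: str = "causal",
    seed: int = 0,
    include_baseline: bool = True,
) -> pd.DataFrame:
    """Mean r̂_b ± SEM over replicates for each (q, c) ascertainment setting.

    For every replicate a fresh cohort is simulated; the behaviour scan is
    either the plain whole-sample scan (``corrected=False``) or the stratified
    IVW meta-scan after MLC correction; the disease scan is of the liability.
    ``snp_mode='causal'`` evaluates r_b at the union of true causal SNPs,
    ``'clumped'`` at genome-wide-significant clumped lead SNPs of the
    behaviour scan. ``q=0`` rows (no ascertainment) are included as the
    baseline when requested.
    """
    from . import mlc as mlc_mod
    from .assoc import clump, gwas_from_cohort
    from .simcohort import AscertainmentConfig, apply_ascertainment, simulate_scenario

    if snp_mode not in ("causal", "clumped"):
        raise ValueError("snp_mode must be 'causal' or 'clumped'")
    grid = [(0.0, 0.0)] if include_baseline else []
    grid += [(q, c) for q in q_grid for c in c_grid]
    ss = np.random.SeedSequence(seed)
    rep_seeds = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(reps)]
    records: dict[tuple[float, float], list[float]] = {g: [] for g in grid}
    for rep_seed in rep_seeds:
        cfg = ScenarioConfig(**{**vars(scenario), "seed": rep_seed})
        base = simulate_scenario(cfg)
        d_scan = gwas_from_cohort(base, base.liability_d)
        snps = None
        if snp_mode == "causal":
            causal = np.union1d(base.causal_idx_y, base.causal_idx_d).astype(int)
            snps = base.snp_ids[causal]
        for q, c in grid:
            coh = apply_ascertainment(base, AscertainmentConfig(q, c)) if q > 0 else base
            if corrected:
                y_scan = mlc_mod.ivw_meta(mlc_mod.stratified_gwas(coh, mlc_mod.SIMULATION_RULES))
            else:
                y_scan = mlc_mod.uncorrected_gwas(coh)
            use = snps
            if snp_mode == "clumped":
                use = clump(y_scan, coh.genotypes, ClumpConfig())
                if len(use) < 3:
                    continue
            try:
                est = estimate_rb(y_scan, d_scan, snps=use)
            except UnstableEstimateError:
                continue
            records[(q, c)].append(est.rb)
    rows = []
    for (q, c), vals in records.items():
        vals = np.asarray(vals)
        rows.append(
            {
                "q": q,
                "c": c,
                "mean_rb": vals.mean() if vals.size else np.nan,
                "sem_rb": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan,
                "n_reps": vals.size,
            }
        )
    return pd.DataFrame(rows)
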