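"""MLC correction: stratified scans, IVW meta-analysis, down-sampling test.

The correction works in two steps: phenotype QC (see :mod:`mlcbias.phenoqc`),
then a scan stratified by longitudinal-change group (LESS/SAME/MORE) with
within-group, within-sex standardisation, combined by fixed-effect
inverse-variance-weighted (IVW) meta-analysis. Standardising within strata
removes the mean and variance differences that disease ascertainment induces
between the groups, which is what de-biases the combined scan.

The down-sampling excess test asks whether the number of loci lost (or
gained) by the correction exceeds what a like-sized random loss of
individuals explains.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc as assoc_mod
from . import phenoqc
from .assoc import ClumpConfig
from .phenoqc import FilterReport, QcRules
from .simcohort import ILLNESS_OR_DOCTOR, LESS, Cohort


class StratumSizeError(ValueError):
    """A change-group stratum is below the configured minimum size."""


class HarmonisationError(ValueError):
    """Effect alleles cannot be reconciled across result sets."""


class InsufficientReplicationError(ValueError):
    """Too few down-sampling replicates."""


def _standardized_stratum_phenotype(
    cohort: Cohort, idx: np.ndarray, rules: QcRules
) -> tuple[np.ndarray, np.ndarray]:
    """Within-sex standardised reported phenotype for one stratum.

    Returns (z-values over the stratum rows, retained mask over stratum rows).
    Age is regressed out within sex; sex differences vanish by construction.
    """
    z, retained = phenoqc.standardize_by_group(
        cohort.reported_y[idx],
        cohort.sex[idx],
        rules,
        covariates=cohort.age[idx],
    )
    return z, retained


def stratified_gwas(
    cohort: Cohort,
    rules: QcRules | None = None,
    covariates: np.ndarray | None = None,
    min_group_size: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-change-group scans on within-group, within-sex standardised values.

    Illness/doctor reducers are removed from the LESS stratum when the rules
    say so. A stratum emptied entirely by the rules is skipped (it contributes
    no scan); a stratum that survives but falls below the minimum size raises
    :class:`StratumSizeError`.
    """
    rules = rules or QcRules()
    min_size = rules.min_group_size if min_group_size is None else min_group_size
    results: dict[str, pd.DataFrame] = {}
    for g in pd.unique(cohort.change_group):
        idx = np.flatnonzero(cohort.change_group == g)
        if g == LESS and rules.drop_illness_reducers:
            idx = idx[cohort.reason[idx] != ILLNESS_OR_DOCTOR]
        idx = idx[~np.isnan(cohort.reported_y[idx])]
        if idx.size == 0:
            continue
        if idx.size < min_size:
            raise StratumSizeError(
                f"stratum {g!r} has {idx.size} usable individuals (< {min_size})"
            )
        z, retained = _standardized_stratum_phenotype(cohort, idx, rules)
        rows = idx[retained]
        results[str(g)] = assoc_mod.run_gwas(
            cohort.genotypes[rows],
            z[retained],
            covariates=None if covariates is None else covariates[rows],
            snp_ids=cohort.snp_ids,
            positions=cohort.positions,
        )
    if not results:
        raise StratumSizeError("no stratum survives the rules")
    return results


#: Rule set for the simulated (two-group) correction: in simulations the
#: ascertained set *is* the LESS group, so the correction is the plain
#: LESS/SAME split with within-group standardisation and meta-analysis;
#: reason-based removal is a real-data refinement and stays off here.
SIMULATION_RULES = QcRules(drop_illness_reducers=False)


def ivw_meta(groups: list[pd.DataFrame] | dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Fixed-effect inverse-variance-weighted meta-analysis across scans.

    beta = Σ w_g b_g / Σ w_g with w_g = 1/se_g²; se = (Σ w_g)^(−1/2); two-sided
    normal p. Effect alleles are harmonised to the first scan: a swapped
    A1/A2 pair flips the sign (and freq), anything else raises. Cochran's Q
    and its p are reported per SNP but never filter.
    """
    if isinstance(groups, dict):
        groups = list(groups.values())
    if not groups:
        raise ValueError("no scans to combine")
    base = groups[0]
    ids = base["snp"].to_numpy()
    k = len(groups)
    B = np.full((k, len(ids)), np.nan)
    W = np.zeros((k, len(ids)))
    N = np.zeros((k, len(ids)))
    for gi, df in enumerate(groups):
        df = df.set_index("snp").reindex(ids)
        a1 = df["a1"].to_numpy()
        a2 = df["a2"].to_numpy()
        b = df["beta"].to_numpy(float)
        same = (a1 == base["a1"].to_numpy()) & (a2 == base["a2"].to_numpy())
        flipped = (a1 == base["a2"].to_numpy()) & (a2 == base["a1"].to_numpy())
        known = df["beta"].notna().to_numpy()
        bad = known & ~(same | flipped)
        if bad.any():
            raise HarmonisationError(
                f"unresolvable allele mismatch at {ids[bad][:5].tolist()}"
            )
        b = np.where(flipped, -b, b)
        se = df["se"].to_numpy(float)
        ok = known & np.isfinite(se) & (se > 0)
        B[gi, ok] = b[ok]
        W[gi, ok] = 1.0 / se[ok] ** 2
        N[gi, ok] = df["n"].to_numpy(float)[ok]
    wsum = W.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = np.nansum(W * B, axis=0) / wsum
        se = 1.0 / np.sqrt(wsum)
        z = beta / se
        q = np.nansum(W * (B - beta) ** 2, axis=0)
    k_groups = (W > 0).sum(axis=0)
    p = 2.0 * stats.norm.sf(np.abs(z))
    q_p = np.where(
        k_groups > 1, stats.chi2.sf(q, np.maximum(k_groups - 1, 1)), np.nan
    )
    out = pd.DataFrame(
        {
            "snp": ids,
            "pos": base["pos"].to_numpy(),
            "a1": base["a1"].to_numpy(),
            "a2": base["a2"].to_numpy(),
            "freq": base["freq"].to_numpy(),
            "beta": beta,
            "se": se,
            "p": p,
            "n": N.sum(axis=0).astype(np.int64),
            "k_groups": k_groups,
            "q": q,
            "q_p": q_p,
        }
    )
    none = k_groups == 0
    out.loc[none, ["beta", "se", "p"]] = np.nan
    out["monomorphic"] = none
    return out


@dataclass
class MlcResult:
    """Output bundle of the full correction: meta scan, QC ledger, loci."""

    meta: pd.DataFrame
    report: FilterReport
    loci: list[str]
    groups: dict[str, pd.DataFrame] = field(default_factory=dict)


def mlc_correct(
    cohort: Cohort,
    rules: QcRules | None = None,
    ccfg: ClumpConfig = ClumpConfig(),
    covariates: np.ndarray | None = None,
) -> MlcResult:
    """The full MLC correction: QC → stratified scans → IVW meta → clump."""
    rules = rules or QcRules()
    qc_cohort, report = phenoqc.qc_filter(cohort, rules)
    groups = stratified_gwas(qc_cohort, rules, covariates=covariates)
    meta = ivw_meta(groups)
    loci = assoc_mod.clump(meta, qc_cohort.genotypes, ccfg)
    return MlcResult(meta=meta, report=report, loci=loci, groups=groups)


def uncorrected_gwas(
    cohort: Cohort,
    rules: QcRules | None = None,
    covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """Whole-sample scan of the reported phenotype (no change-group strata).

    The phenotype is still standardised within sex with age regressed out,
    mirroring routine GWAS phenotype preparation, but no stratification by
    longitudinal change is applied: ascertainment shifts stay in the data.
    """
    rules = rules or QcRules()
    idx = np.flatnonzero(~np.isnan(cohort.reported_y))
    z, retained = _standardized_stratum_phenotype(cohort, idx, rules)
    rows = idx[retained]
    return assoc_mod.run_gwas(
        cohort.genotypes[rows],
        z[retained],
        covariates=None if covariates is None else covariates[rows],
        snp_ids=cohort.snp_ids,
        positions=cohort.positions,
    )


@dataclass
class ExcessTestResult:
    """Observed vs expected locus turnover under random down-sampling.

    ``z`` and ``p`` follow the summary-arithmetic convention
    z=(observed−mean)/sem with a two-sided normal p. ``p_empirical`` is the
    exact randomized-rank p of the observed count among the replicate counts
    (one-sided, large counts extreme), which is uniform by construction under
    the resampling null; prefer it for calibration questions.
    """

    observed: float
    expected_mean: float
    expected_sem: float
    z: float
    p: float
    reps: int
    p_empirical: float | None = None
    losses: list[int] | None = None
    gains: list[int] | None = None


def empirical_rank_p(observed: float, reference, rng: np.random.Generator) -> float:
    """Exact randomized-rank p of an observed count among reference draws.

    One-sided (large counts extreme): p = (#{ref > obs} + U·(#{ref = obs}+1))
    / (len(ref)+1). Uniform on (0, 1) by construction when the observed count
    is exchangeable with the reference draws, discrete ties included.
    """
    ref = np.asarray(reference, dtype=float)
    n_greater = int(np.sum(ref > observed))
    n_tied = int(np.sum(ref == observed))
    return float((n_greater + rng.uniform() * (n_tied + 1)) / (ref.size + 1))


def excess_z(
    observed: float, expected_mean: float, expected_sem: float, reps: int = 0
) -> ExcessTestResult:
    """Summary-arithmetic excess test: z=(obs−mean)/sem, two-sided normal p."""
    if expected_sem <= 0:
        raise ValueError("expected_sem must be positive")
    z = (observed - expected_mean) / expected_sem
    return ExcessTestResult(
        observed=observed,
        expected_mean=expected_mean,
        expected_sem=expected_sem,
        z=float(z),
        p=float(2.0 * stats.norm.sf(abs(z))),
        reps=reps,
    )


def _match_loci(
    base_leads: list[str],
    base_pos: dict[str, int],
    new_leads: list[str],
    new_pos: dict[str, int],
    window_bp: int,
) -> int:
    """Count base loci with no new lead within the reciprocal window."""
    lost = 0
    new_positions = np.array([new_pos[s] for s in new_leads], dtype=np.int64)
    for s in base_leads:
        if new_positions.size == 0 or np.min(np.abs(new_positions - base_pos[s])) > window_bp:
            lost += 1
    return lost


def downsample_excess(
    cohort: Cohort,
    n_remove: int,
    reps: int,
    seed: int = 0,
    ccfg: ClumpConfig = ClumpConfig(),
    rules: QcRules | None = None,
    observed: float | None = None,
) -> ExcessTestResult:
    """Locus turnover expected from removing ``n_remove`` random individuals.

    For each replicate, individuals are removed uniformly at random *before*
    QC (mimicking a smaller cohort), the whole-sample scan and clumping are
    rerun, and loci lost/gained relative to the full scan are counted by
    window matching of lead SNPs. The z-test compares ``observed`` (when
    given; e.g. the loss from an MLC correction) against the replicate mean
    and s.e.m.; ``p_empirical`` uses the randomized rank instead.
    """
    if reps < 2:
        raise InsufficientReplicationError("need at least 2 replicates")
    if n_remove >= cohort.n:
        raise ValueError("n_remove must be smaller than the cohort")
    rules = rules or QcRules()
    rng = np.random.default_rng(seed)
    base_scan = uncorrected_gwas(cohort, rules)
    base_leads = assoc_mod.clump(base_scan, cohort.genotypes, ccfg)
    pos_map = dict(zip(cohort.snp_ids.tolist(), cohort.positions.tolist()))
    losses, gains = [], []
    for _ in range(reps):
        keep = rng.permutation(cohort.n)[: cohort.n - n_remove]
        sub = cohort.subset(np.sort(keep))
        scan = uncorrected_gwas(sub, rules)
        leads = assoc_mod.clump(scan, sub.genotypes, ccfg)
        losses.append(_match_loci(base_leads, pos_map, leads, pos_map, ccfg.window_bp))
        gains.append(_match_loci(leads, pos_map, base_leads, pos_map, ccfg.window_bp))
    mean = float(np.mean(losses))
    sem = float(np.std(losses, ddof=1) / math.sqrt(reps))
    obs = float(observed) if observed is not None else mean
    if sem > 0:
        z = (obs - mean) / sem
        p = float(2.0 * stats.norm.sf(abs(z)))
    else:
        z, p = (0.0, 1.0) if obs == mean else (math.inf, 0.0)
    # exact randomized rank among the replicates (one-sided, larger = extreme)
    p_emp = empirical_rank_p(obs, losses, rng)
    return ExcessTestResult(
        observed=obs,
        expected_mean=mean,
        expected_sem=sem,
        z=float(z),
        p=p,
        reps=reps,
        p_empirical=float(p_emp),
        losses=losses,
        gains=gains,
    )
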