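"""Binned exposure-disease risk curves and polygenic-predictor curves.

The J-shaped risk curve (elevated risk at zero/low exposure, minimum at
moderate exposure) can be manufactured by reference-bin contamination: when
the moderate-exposure reference bin is enriched with individuals who reduced
their exposure *because of* disease (the LESS group), the reference carries
excess cases and every other bin's odds ratio is pushed down. This module
computes per-bin odds ratios against a reference bin with optional exclusion
of change groups from the reference, per-bin change-group composition, and
risk curves across polygenic-score bins with an enforced train/evaluation
split.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assoc as assoc_mod
from .assoc import ClumpConfig


class ReferenceBinError(ValueError):
    """Reference bin lacks cases or controls after exclusions."""


class LeakageError(ValueError):
    """Training and evaluation samples overlap."""


def odds_ratio_2x2(a: int, b: int, c: int, d: int) -> tuple[float, tuple[float, float]]:
    """OR = (a·d)/(b·c) with the Woolf 95% CI on the log scale.

    a/b are cases/controls in the index group, c/d in the reference. A 0.5
    continuity correction is applied to all cells when any cell is zero.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    orr = (a * d) / (b * c)
    se_log = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    lo = orr * np.exp(-1.96 * se_log)
    hi = orr * np.exp(1.96 * se_log)
    return float(orr), (float(lo), float(hi))


@dataclass
class RiskCurve:
    """Per-bin odds ratios vs a reference bin, with group composition.

    ``table`` has one row per bin (bin, n, cases, odds_ratio, ci_low,
    ci_high); ``composition`` the per-bin change-group fractions (rows sum
    to 1); ``reference_bin`` indexes the table.
    """

    edges: np.ndarray
    table: pd.DataFrame
    reference_bin: int
    composition: pd.DataFrame | None = None

    def to_frame(self) -> pd.DataFrame:
        out = self.table.copy()
        out["is_reference"] = out.index == self.reference_bin
        return out


def risk_curve(
    exposure,
    disease,
    groups=None,
    bins=(0.0, 25.0, 50.0, 100.0, 200.0),
    reference: int = 0,
    exclude_from_reference: set | frozenset = frozenset(),
    include_lowest: bool = True,
) -> RiskCurve:
    """Binned odds-ratio curve of disease against exposure.

    Bins are left-open right-closed intervals over ``bins`` edges (the first
    optionally closed on the left). Each bin's OR comes from the bin-vs-
    reference 2×2 table with a Woolf CI; members of ``exclude_from_reference``
    groups are removed from the *reference side* of every comparison only
    (their own bins still count them). The reference bin's OR is 1 by
    definition.
    """
    x = np.asarray(exposure, dtype=float)
    y = np.asarray(disease).astype(int)
    edges = np.asarray(bins, dtype=float)
    bin_idx = pd.cut(
        x, edges, right=True, labels=False, include_lowest=include_lowest
    )
    ok = ~pd.isna(bin_idx)
    bin_idx = np.where(ok, bin_idx, -1).astype(int)
    n_bins = len(edges) - 1
    if not 0 <= reference < n_bins:
        raise ReferenceBinError(f"reference bin {reference} out of range")

    groups = None if groups is None else np.asarray(groups)
    ref_rows = ok & (bin_idx == reference)
    if groups is not None and exclude_from_reference:
        ref_rows &= ~np.isin(groups, list(exclude_from_reference))
    ref_cases = int(y[ref_rows].sum())
    ref_ctrls = int((1 - y[ref_rows]).sum())
    if ref_cases == 0 or ref_ctrls == 0:
        raise ReferenceBinError("reference bin lacks cases or controls after exclusions")

    rows = []
    comp_rows = []
    group_levels = [] if groups is None else list(pd.unique(groups))
    for b in range(n_bins):
        in_bin = ok & (bin_idx == b)
        n_b = int(in_bin.sum())
        cases = int(y[in_bin].sum())
        if b == reference:
            orr, ci = 1.0, (1.0, 1.0)
        elif n_b == 0:
            orr, ci = np.nan, (np.nan, np.nan)
        else:
            orr, ci = odds_ratio_2x2(cases, n_b - cases, ref_cases, ref_ctrls)
        rows.append(
            {
                "bin": f"({edges[b]:g}, {edges[b + 1]:g}]",
                "n": n_b,
                "cases": cases,
                "odds_ratio": orr,
                "ci_low": ci[0],
                "ci_high": ci[1],
            }
        )
        if groups is not None:
            total = max(n_b, 1)
            comp_rows.append(
                {
                    "bin": rows[-1]["bin"],
                    **{
                        str(g): float(np.sum(in_bin & (groups == g))) / total
                        for g in group_levels
                    },
                }
            )
    table = pd.DataFrame(rows)
    composition = pd.DataFrame(comp_rows) if comp_rows else None
    return RiskCurve(
        edges=edges, table=table, reference_bin=reference, composition=composition
    )


def polygenic_score(
    genotypes: np.ndarray,
    training_assoc: pd.DataFrame,
    snp_ids: np.ndarray,
    selected: list[str],
) -> np.ndarray:
    """Σ beta_j · allele count over the selected SNPs."""
    lookup = training_assoc.set_index("snp")["beta"]
    cols = [int(np.flatnonzero(snp_ids == s)[0]) for s in selected]
    betas = lookup.loc[list(selected)].to_numpy(float)
    return genotypes[:, cols].astype(float) @ betas


def pgs_curve(
    genotypes: np.ndarray,
    training_assoc: pd.DataFrame,
    disease,
    snp_ids: np.ndarray,
    train_idx: np.ndarray,
    eval_idx: np.ndarray,
    bins: int = 5,
    reference: int = 0,
    cfg: ClumpConfig = ClumpConfig(),
    positions: np.ndarray | None = None,
) -> RiskCurve:
    """Disease risk across polygenic-score quantile bins (evaluation split).

    ``training_assoc`` must come from a scan of the training rows only; the
    split is validated (overlap raises :class:`LeakageError`). Score SNPs are
    the clumped leads of the training scan at the configured threshold.
    """
    train_idx = np.asarray(train_idx)
    eval_idx = np.asarray(eval_idx)
    if np.intersect1d(train_idx, eval_idx).size:
        raise LeakageError("training and evaluation samples overlap")
    selected = assoc_mod.clump(training_assoc, genotypes[train_idx], cfg)
    if not selected:
        raise ValueError("no score SNP passes the threshold")
    score = polygenic_score(genotypes[eval_idx], training_assoc, snp_ids, selected)
    y = np.asarray(disease).astype(int)[eval_idx]
    qs = np.quantile(score, np.linspace(0, 1, bins + 1))
    qs[0] -= 1e-9  # include the minimum in the first bin
    qs = np.unique(qs)
    return risk_curve(score, y, bins=qs, reference=min(reference, len(qs) - 2))


def train_eval_split(n: int, train_frac: float = 0.5, seed: int = 0):
    """Seeded disjoint train/evaluation index split."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    k = int(round(train_frac * n))
    return np.sort(perm[:k]), np.sort(perm[k:])


def ascertained_risk_world(
    n: int = 10_000,
    seed: int = 0,
    q: float = 0.20,
    c: float = 3.0,
    b_yd: float = 0.7,
    prevalence: float = 0.15,
    disease_liability_corr: float = 0.7,
    m: int = 200,
    n_causal: int = 50,
):
    """Cohort world for the reference-contamination risk-curve demonstration.

    Builds a behaviour-causes-disease cohort, ascertains the top-``q``
    liability fraction (reported behaviour down by ``c`` SDs, labelled LESS),
    and draws the *observed* disease from a latent only partially correlated
    with the ascertainment liability (``disease_liability_corr``), so the
    LESS group is case-enriched without coinciding with the case set — the
    structure behind the manufactured J shape. Pair with a wide lowest
    reference bin (e.g. quantile edges 0/.4/.6/.8/1) so the reference absorbs
    the shifted LESS group, mirroring the wide moderate-consumption reference
    of epidemiological practice. Returns ``(exposure, disease, groups,
    cohort)``.
    """
    from scipy import stats

    from .simcohort import (
        AscertainmentConfig,
        ScenarioConfig,
        apply_ascertainment,
        simulate_scenario,
    )

    cfg = ScenarioConfig(
        "II", n_individuals=n, n_snps=m, n_causal_y=n_causal, b_yd=b_yd,
        disease_prevalence=prevalence, seed=seed,
    )
    cohort = simulate_scenario(cfg)
    cohort = apply_ascertainment(cohort, AscertainmentConfig(q, c))
    rho = disease_liability_corr
    rng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
    latent = rho * cohort.liability_d + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    disease = (latent > stats.norm.ppf(1 - prevalence)).astype(int)
    return cohort.reported_y, disease, cohort.change_group, cohort


def binned_mean_curve(x, y, bins: int = 10) -> pd.DataFrame:
    """Mean of y across equal-count bins of x (dose-response summary)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    qs = np.unique(np.quantile(x, np.linspace(0, 1, bins + 1)))
    idx = np.clip(np.searchsorted(qs, x, side="right") - 1, 0, len(qs) - 2)
    rows = []
    for b in range(len(qs) - 1):
        sel = idx == b
        rows.append(
            {
                "bin": b,
                "x_mid": float(x[sel].mean()) if sel.any() else np.nan,
                "mean_y": float(y[sel].mean()) if sel.any() else np.nan,
                "n": int(sel.sum()),
            }
        )
    return pd.DataFrame(rows)


def interior_minimum(values: np.ndarray) -> bool:
    """True when the minimum of a curve falls strictly inside its range."""
    v = np.asarray(values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size < 3:
        return False
    k = int(np.argmin(v))
    return 0 < k < v.size - 1
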