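"""Summary-statistic Mendelian randomisation: Wald, IVW, median estimators.

Instruments are clumped genome-wide-significant SNPs of the exposure scan.
Per instrument the Wald ratio b_out/b_exp estimates the causal effect b_xy;
IVW combines ratios with weights b_exp²/se_out² (equivalently a weighted
regression of outcome on exposure effects through the origin, fixed-effect
SE); the simple and weighted medians are robust alternatives with bootstrap
SEs. An optional iterated outlier screen approximates HEIDI-style instrument
filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import assoc as assoc_mod
from .assoc import ClumpConfig

WALD = "WALD"
IVW = "IVW"
SIMPLE_MEDIAN = "SIMPLE_MEDIAN"
WEIGHTED_MEDIAN = "WEIGHTED_MEDIAN"


class NoInstrumentError(ValueError):
    """No SNP passes the instrument-selection threshold."""


class WeakInstrumentError(ValueError):
    """An instrument has a zero exposure effect."""


class InsufficientInstrumentsError(ValueError):
    """Median estimators need at least 3 instruments."""


@dataclass
class CausalEstimate:
    """One exposure→outcome causal-effect estimate from summary statistics."""

    method: str
    b_xy: float
    se: float
    ci95: tuple[float, float]
    n_iv: int
    removed_outliers: list[str] = field(default_factory=list)
    direction: str = "forward"

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "b_xy": self.b_xy,
            "se": self.se,
            "ci95": list(self.ci95),
            "n_iv": self.n_iv,
            "removed_outliers": self.removed_outliers,
            "direction": self.direction,
        }


def select_ivs(
    exposure: pd.DataFrame,
    genotypes: np.ndarray,
    cfg: ClumpConfig = ClumpConfig(),
) -> list[str]:
    """Clump the exposure scan into independent instruments.

    Defaults are the standard genome-wide criteria (p < 5e-8, 1 Mb window,
    r² < 0.01). Raises :class:`NoInstrumentError` when nothing passes.
    """
    ivs = assoc_mod.clump(exposure, genotypes, cfg)
    if not ivs:
        raise NoInstrumentError("no SNP passes the instrument threshold")
    return ivs


def _iv_effects(
    ivs: list[str], exposure: pd.DataFrame, outcome: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Harmonised (b_exp, se_exp, b_out, se_out, ids) over the instruments."""
    e = exposure.set_index("snp").loc[ivs]
    o = outcome.set_index("snp").loc[ivs]
    flip = (e["a1"].to_numpy() == o["a2"].to_numpy()) & (
        e["a2"].to_numpy() == o["a1"].to_numpy()
    )
    same = (e["a1"].to_numpy() == o["a1"].to_numpy()) & (
        e["a2"].to_numpy() == o["a2"].to_numpy()
    )
    if not np.all(same | flip):
        from .mlc import HarmonisationError

        raise HarmonisationError("allele mismatch between exposure and outcome")
    b_exp = e["beta"].to_numpy(float)
    se_exp = e["se"].to_numpy(float)
    b_out = np.where(flip, -o["beta"].to_numpy(float), o["beta"].to_numpy(float))
    se_out = o["se"].to_numpy(float)
    if np.any(b_exp == 0) or np.any(~np.isfinite(b_exp)):
        raise WeakInstrumentError("an instrument has zero exposure effect")
    return b_exp, se_exp, b_out, se_out, np.asarray(ivs)


def ivw_estimate(
    ivs: list[str],
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    outlier_screen: bool = False,
    outlier_k: float = 3.0,
    direction: str = "forward",
) -> CausalEstimate:
    """Inverse-variance-weighted combination of per-instrument Wald ratios.

    b_xy = Σ w_j r_j / Σ w_j with r_j = b_out/b_exp and w_j = b_exp²/se_out²;
    se = (Σ w_j)^(−1/2) (fixed effect). With one instrument this is exactly
    the Wald ratio. ``outlier_screen`` drops instruments whose ratio deviates
    from the IVW estimate by more than ``outlier_k`` ratio-SEs, once, and
    re-estimates.
    """
    b_exp, se_exp, b_out, se_out, ids = _iv_effects(ivs, exposure, outcome)
    removed: list[str] = []
    for _pass in range(2):
        ratios = b_out / b_exp
        w = b_exp**2 / se_out**2
        b = float(np.sum(w * ratios) / np.sum(w))
        se = float(1.0 / np.sqrt(np.sum(w)))
        if not outlier_screen or _pass == 1 or ids.size <= 2:
            break
        se_ratio = se_out / np.abs(b_exp)
        keep = np.abs(ratios - b) <= outlier_k * se_ratio
        if keep.all() or not keep.any():
            break  # nothing deviant, or everything would go: keep the estimate
        removed = ids[~keep].tolist()
        b_exp, se_exp, b_out, se_out, ids = (
            b_exp[keep],
            se_exp[keep],
            b_out[keep],
            se_out[keep],
            ids[keep],
        )
    method = WALD if ids.size == 1 else IVW
    return CausalEstimate(
        method=method,
        b_xy=b,
        se=se,
        ci95=(b - 1.96 * se, b + 1.96 * se),
        n_iv=int(ids.size),
        removed_outliers=removed,
        direction=direction,
    )


def _weighted_median(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Interpolated weighted median (standard MR definition)."""
    order = np.argsort(ratios)
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - 0.5 * w
    return float(np.interp(0.5, s, r))


def median_estimates(
    ivs: list[str],
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    n_boot: int = 1000,
    seed: int = 0,
    direction: str = "forward",
) -> tuple[CausalEstimate, CausalEstimate]:
    """Simple and weighted median of Wald ratios with parametric-bootstrap SE.

    The weighted median uses normalised inverse-variance weights of the
    ratios; the simple median is the same with equal weights. Bootstrap
    resamples the per-SNP effects from their sampling distributions.
    """
    b_exp, se_exp, b_out, se_out, ids = _iv_effects(ivs, exposure, outcome)
    if ids.size < 3:
        raise InsufficientInstrumentsError("median estimators need >= 3 instruments")
    ratios = b_out / b_exp
    se_ratio2 = se_out**2 / b_exp**2 + b_out**2 * se_exp**2 / b_exp**4
    w_inv = 1.0 / se_ratio2
    eq = np.ones_like(ratios)

    b_simple = _weighted_median(ratios, eq)
    b_weighted = _weighted_median(ratios, w_inv)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 2))
    for i in range(n_boot):
        be = b_exp + rng.standard_normal(ids.size) * se_exp
        bo = b_out + rng.standard_normal(ids.size) * se_out
        be = np.where(be == 0, np.finfo(float).tiny, be)
        rr = bo / be
        sr2 = se_out**2 / be**2 + bo**2 * se_exp**2 / be**4
        boots[i, 0] = _weighted_median(rr, eq)
        boots[i, 1] = _weighted_median(rr, 1.0 / sr2)
    se_s, se_w = boots.std(axis=0, ddof=1)

    def _mk(method: str, b: float, se: float) -> CausalEstimate:
        return CausalEstimate(
            method=method,
            b_xy=b,
            se=float(se),
            ci95=(b - 1.96 * se, b + 1.96 * se),
            n_iv=int(ids.size),
            direction=direction,
        )

    return _mk(SIMPLE_MEDIAN, b_simple, se_s), _mk(WEIGHTED_MEDIAN, b_weighted, se_w)


def reverse_analysis(
    exposure: pd.DataFrame,
    outcome: pd.DataFrame,
    genotypes: np.ndarray,
    cfg: ClumpConfig = ClumpConfig(),
    **kwargs,
) -> CausalEstimate:
    """Swap exposure and outcome and re-run IVW; direction recorded."""
    ivs = select_ivs(outcome, genotypes, cfg)
    return ivw_estimate(ivs, outcome, exposure, direction="reverse", **kwargs)
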