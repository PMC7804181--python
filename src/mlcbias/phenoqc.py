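"""Phenotypic quality control for self-reported behavioural traits.

Implements the first step of the MLC (misreports and longitudinal changes)
correction: rule-based removal of suspect reporters with a conserving filter
ledger, the log2(x+1) consumption transform, per-group covariate adjustment
and z-standardisation with outlier screens, and Welch's t test from summary
statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats

from .simcohort import ILLNESS_OR_DOCTOR, LESS, Cohort


class SchemaError(ValueError):
    """A rule requires a field the input does not carry."""


class AccountingError(ValueError):
    """Counts inconsistent with their denominator."""


class DomainError(ValueError):
    """Input outside the mathematical domain of the operation."""


class DegenerateGroupError(ValueError):
    """A standardisation group is constant or too small."""


@dataclass(frozen=True)
class QcRules:
    """Switches and thresholds for the phenotype QC step.

    ``raw_outlier_sd`` is the per-group mean±k·SD screen applied to the (by
    default transformed) raw values; ``post_adjust_z`` masks |z| above the
    threshold after covariate adjustment and z-scoring.
    """

    drop_never_drinkers: bool = True
    drop_zero_consumption_current: bool = True
    drop_nonresponse: bool = True
    drop_illness_reducers: bool = True
    raw_outlier_sd: float = 7.0
    post_adjust_z: float = 5.0
    min_group_size: int = 50

    def __post_init__(self) -> None:
        if self.raw_outlier_sd <= 0 or self.post_adjust_z <= 0:
            raise DomainError("outlier thresholds must be positive")


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class FilterReport:
    """Ordered ledger of removals: (rule, n_removed, n_remaining) rows.

    Conserves counts: n_input == n_remaining_last + sum(n_removed).
    """

    n_input: int
    rows: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, rule: str, n_removed: int) -> None:
        remaining = (self.rows[-1][2] if self.rows else self.n_input) - n_removed
        if remaining < 0:
            raise AccountingError(f"rule {rule!r} removes more than remain")
        self.rows.append((rule, n_removed, remaining))

    @property
    def n_remaining(self) -> int:
        return self.rows[-1][2] if self.rows else self.n_input

    def validate(self) -> None:
        if self.n_input != self.n_remaining + sum(r[1] for r in self.rows):
            raise AccountingError("filter ledger does not conserve counts")

    def to_frame(self, denominator: int | None = None) -> pd.DataFrame:
        den = denominator or self.n_input
        df = pd.DataFrame(self.rows, columns=["rule", "n_removed", "n_remaining"])
        df["pct_removed"] = [
            _round_half_up(100.0 * r / den) if den else float("nan")
            for r in df["n_removed"]
        ]
        return df

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_input": self.n_input,
                "rows": [
                    {"rule": r, "n_removed": nr, "n_remaining": nl}
                    for r, nr, nl in self.rows
                ],
                "n_remaining": self.n_remaining,
            },
            indent=1,
        )


def qc_filter(cohort: Cohort, rules: QcRules) -> tuple[Cohort, FilterReport]:
    """Rule-based removal of suspect reporters, in fixed order.

    Order: never drinkers → zero-consumption current drinkers → non-response →
    illness/doctor reducers (LESS stratum only). Each individual is attributed
    to the first matching rule, so removals are disjoint by construction.
    """
    report = FilterReport(n_input=cohort.n)
    keep = np.ones(cohort.n, dtype=bool)

    if rules.drop_never_drinkers:
        if cohort.drinker_status is None:
            hit = np.zeros(cohort.n, dtype=bool)  # simulated cohorts: all current
        else:
            hit = keep & (cohort.drinker_status == "never")
        keep &= ~hit
        report.add("never_drinkers", int(hit.sum()))

    if rules.drop_zero_consumption_current:
        current = (
            np.ones(cohort.n, dtype=bool)
            if cohort.drinker_status is None
            else (cohort.drinker_status == "current")
        )
        hit = keep & current & (cohort.reported_y == 0)
        keep &= ~hit
        report.add("zero_consumption", int(hit.sum()))

    if rules.drop_nonresponse:
        hit = keep & np.isnan(cohort.reported_y)
        keep &= ~hit
        report.add("nonresponse", int(hit.sum()))

    if rules.drop_illness_reducers:
        hit = keep & (cohort.change_group == LESS) & (cohort.reason == ILLNESS_OR_DOCTOR)
        keep &= ~hit
        report.add("illness_reducers", int(hit.sum()))

    report.validate()
    return cohort.subset(np.flatnonzero(keep)), report


def filter_accounting(
    group_counts: dict[str, int], denominator: int
) -> pd.DataFrame:
    """Percentage table for labelled counts against a common denominator.

    Percentages are 100·count/denominator reported at one decimal with
    half-up rounding; the complement count/percentage is included per row.
    """
    if denominator <= 0:
        raise AccountingError("denominator must be positive")
    rows = []
    for name, count in group_counts.items():
        if count > denominator:
            raise AccountingError(f"count for {name!r} exceeds denominator")
        if count < 0:
            raise AccountingError(f"negative count for {name!r}")
        rows.append(
            {
                "group": name,
                "count": count,
                "denominator": denominator,
                "pct": _round_half_up(100.0 * count / denominator),
                "complement_count": denominator - count,
                "complement_pct": _round_half_up(100.0 * (denominator - count) / denominator),
            }
        )
    return pd.DataFrame(rows)


def transform_consumption(values) -> np.ndarray:
    """log2(x + 1) transform for right-skewed consumption; NaN propagates."""
    x = np.asarray(values, dtype=float)
    if np.any(x[~np.isnan(x)] < 0):
        raise DomainError("consumption values must be non-negative")
    return np.log2(x + 1.0)


def standardize_by_group(
    values,
    group,
    rules: QcRules | None = None,
    covariates: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-group covariate adjustment and z-standardisation with outlier masks.

    Within each group: (1) drop raw values outside mean ± ``raw_outlier_sd``
    SDs; (2) regress out the covariates (with intercept); (3) z-score; (4)
    mask |z| > ``post_adjust_z``; (5) re-standardise the retained values so
    retained group mean is exactly 0 and variance exactly 1 (ddof=1).

    Returns ``(z, retained)`` where ``z`` is NaN for missing or excluded
    entries and ``retained`` is the boolean inclusion mask.
    """
    rules = rules or QcRules()
    x = np.asarray(values, dtype=float)
    group = np.asarray(group)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != x.shape[0]:
            covariates = covariates.T
    z = np.full(x.shape, np.nan)
    retained = np.zeros(x.shape, dtype=bool)
    for g in pd.unique(group):
        gi = np.flatnonzero((group == g) & ~np.isnan(x))
        if gi.size < 2:
            raise DegenerateGroupError(f"group {g!r} has fewer than 2 values")
        v = x[gi]
        if np.std(v, ddof=1) == 0:
            raise DegenerateGroupError(f"group {g!r} is constant")
        # raw outlier screen
        mu, sd = v.mean(), v.std(ddof=1)
        ok = np.abs(v - mu) <= rules.raw_outlier_sd * sd
        gi, v = gi[ok], v[ok]
        # covariate adjustment
        if covariates is not None:
            design = np.column_stack([np.ones(gi.size), covariates[gi]])
            coef, *_ = np.linalg.lstsq(design, v, rcond=None)
            v = v - design @ coef
        sd = v.std(ddof=1)
        if sd == 0:
            raise DegenerateGroupError(f"group {g!r} is constant after adjustment")
        zz = (v - v.mean()) / sd
        ok = np.abs(zz) <= rules.post_adjust_z
        gi, zz = gi[ok], zz[ok]
        if zz.size >= 2 and zz.std(ddof=1) > 0:
            zz = (zz - zz.mean()) / zz.std(ddof=1)  # exact 0/1 after masking
        z[gi] = zz
        retained[gi] = True
    return z, retained


def welch_t(
    mean1: float,
    se1: float,
    mean2: float,
    se2: float,
    n1: int | None = None,
    n2: int | None = None,
) -> tuple[float, float]:
    """Welch's two-sample t from summary statistics.

    t = (mean1 − mean2)/sqrt(se1² + se2²). With per-group sizes the
    Welch–Satterthwaite degrees of freedom and the t distribution are used;
    otherwise the normal approximation (df effectively infinite at biobank
    scale).
    """
    if se1 <= 0 or se2 <= 0:
        raise DomainError("standard errors must be positive")
    t = (mean1 - mean2) / float(np.hypot(se1, se2))
    if n1 is not None and n2 is not None:
        df = (se1**2 + se2**2) ** 2 / (se1**4 / (n1 - 1) + se2**4 / (n2 - 1))
        p = 2.0 * stats.t.sf(abs(t), df)
    else:
        p = 2.0 * stats.norm.sf(abs(t))
    return float(t), float(p)


def welch_t_from_samples(x1, x2) -> tuple[float, float]:
    """Welch's t from raw samples, via the summary-statistic path."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    return welch_t(
        x1.mean(),
        x1.std(ddof=1) / np.sqrt(x1.size),
        x2.mean(),
        x2.std(ddof=1) / np.sqrt(x2.size),
        n1=x1.size,
        n2=x2.size,
    )
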