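"""Per-SNP association scans and greedy LD clumping.

The scan is ordinary least squares of the phenotype on each SNP's allele count
with shared covariates, computed for all SNPs at once via
Frisch–Waugh–Lovell residualisation (exactly equivalent to per-SNP OLS with
the full design). Clumping greedily reduces hits to independent lead SNPs by
p-value, base-pair window and sample LD r².
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]


class DesignError(ValueError):
    """Rank-deficient or misaligned design."""


class DataError(ValueError):
    """Unusable phenotype input."""


@dataclass(frozen=True)
class ClumpConfig:
    """Greedy clumping parameters: window, significance and LD thresholds."""

    window_bp: int = 1_000_000
    p_threshold: float = 5e-8
    r2_threshold: float = 0.01

    def __post_init__(self) -> None:
        if self.window_bp <= 0 or self.r2_threshold <= 0:
            raise ValueError("clump thresholds must be positive")
        if not 0.0 < self.p_threshold < 1.0:
            raise ValueError("p_threshold must lie in (0, 1)")


def run_gwas(
    genotypes: np.ndarray,
    phenotype,
    covariates: np.ndarray | None = None,
    snp_ids: np.ndarray | None = None,
    positions: np.ndarray | None = None,
    exact_t: bool = False,
) -> pd.DataFrame:
    """Per-SNP OLS scan of phenotype on allele count + covariates + intercept.

    Rows with missing phenotype are dropped for the whole scan. Monomorphic
    SNPs are flagged (``monomorphic=True``) with NaN estimates. p-values are
    two-sided from the normal approximation by default (``exact_t=True`` uses
    the t distribution with the OLS residual df).

    Returns a frame with columns snp, pos, a1, a2, freq, beta, se, p, n,
    monomorphic.
    """
    y = np.asarray(phenotype, dtype=float)
    genotypes = np.asarray(genotypes)
    n_all, m = genotypes.shape
    if y.shape[0] != n_all:
        raise DesignError("phenotype and genotypes are misaligned")
    use = ~np.isnan(y)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, dtype=float))
        if covariates.shape[0] != n_all:
            covariates = covariates.T
        if covariates.shape[0] != n_all:
            raise DesignError("covariates and genotypes are misaligned")
        use &= ~np.isnan(covariates).any(axis=1)
    n = int(use.sum())
    if n == 0:
        raise DataError("all phenotype values are missing")
    y = y[use]
    if np.std(y) == 0:
        raise DataError("phenotype is constant")
    G = genotypes[use].astype(float)

    # covariate design with intercept; project out of y and G (FWL)
    if covariates is not None:
        C = np.column_stack([np.ones(n), covariates[use]])
    else:
        C = np.ones((n, 1))
    if np.linalg.matrix_rank(C) < C.shape[1]:
        raise DesignError("covariate design is rank deficient")
    Q, _ = np.linalg.qr(C)
    y_r = y - Q @ (Q.T @ y)
    G_r = G - Q @ (Q.T @ G)

    gTg = np.einsum("ij,ij->j", G_r, G_r)
    mono = G.std(axis=0) == 0
    gTg_safe = np.where(gTg > 0, gTg, np.nan)
    beta = (G_r.T @ y_r) / gTg_safe
    # residual variance of the full per-SNP model: df = n - (covariates+1) - 1
    df = n - C.shape[1] - 1
    if df <= 0:
        raise DesignError("not enough observations for the design")
    rss = y_r @ y_r - beta**2 * gTg_safe
    rss = np.maximum(rss, 0.0)
    se = np.sqrt(rss / df / gTg_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = beta / se
    if exact_t:
        p = 2.0 * stats.t.sf(np.abs(z), df)
    else:
        p = 2.0 * stats.norm.sf(np.abs(z))
    beta[mono] = np.nan
    se[mono] = np.nan
    p[mono] = np.nan

    if snp_ids is None:
        snp_ids = np.array([f"snp{j}" for j in range(m)])
    if positions is None:
        from .simcohort import default_positions

        positions = default_positions(m)
    return pd.DataFrame(
        {
            "snp": snp_ids,
            "pos": np.asarray(positions, dtype=np.int64),
            "a1": "A",
            "a2": "G",
            "freq": G.mean(axis=0) / 2.0,
            "beta": beta,
            "se": se,
            "p": p,
            "n": n,
            "monomorphic": mono,
        }
    )


def gwas_from_cohort(
    cohort,
    phenotype,
    covariates: np.ndarray | None = None,
    exact_t: bool = False,
) -> pd.DataFrame:
    """Scan a cohort's genotypes against an arbitrary phenotype vector."""
    return run_gwas(
        cohort.genotypes,
        phenotype,
        covariates=covariates,
        snp_ids=cohort.snp_ids,
        positions=cohort.positions,
        exact_t=exact_t,
    )


def _r2_to_lead(G: np.ndarray, lead: int, others: np.ndarray) -> np.ndarray:
    """Sample allele-count r² between the lead SNP and each other SNP.

    Computed over complete pairs (rows with neither value missing).
    """
    g0 = G[:, lead]
    out = np.zeros(others.size)
    finite0 = ~np.isnan(g0)
    for k, j in enumerate(others):
        gj = G[:, j]
        ok = finite0 & ~np.isnan(gj)
        a, b = g0[ok], gj[ok]
        if a.size < 2 or a.std() == 0 or b.std() == 0:
            out[k] = 0.0
        else:
            r = np.corrcoef(a, b)[0, 1]
            out[k] = r * r
    return out


def clump(
    assoc: pd.DataFrame,
    genotypes: np.ndarray,
    cfg: ClumpConfig = ClumpConfig(),
) -> list[str]:
    """Greedy clumping into independent lead SNPs.

    Repeatedly take the lowest-p SNP passing ``p_threshold`` as a lead and
    drop every remaining SNP within ``window_bp`` of it or with sample
    r² ≥ ``r2_threshold`` to it. Ties on p break by position, then id.
    Returns lead SNP ids in selection order (possibly empty).
    """
    cand = assoc.loc[assoc["p"].notna() & (assoc["p"] < cfg.p_threshold)].copy()
    if cand.empty:
        return []
    cand["_row"] = np.arange(len(assoc))[assoc["p"].notna() & (assoc["p"] < cfg.p_threshold)]
    cand = cand.sort_values(["p", "pos", "snp"], kind="mergesort").reset_index(drop=True)
    G = np.asarray(genotypes, dtype=float)
    pos = cand["pos"].to_numpy()
    rows = cand["_row"].to_numpy()
    alive = np.ones(len(cand), dtype=bool)
    leads: list[str] = []
    for i in range(len(cand)):
        if not alive[i]:
            continue
        leads.append(str(cand.at[i, "snp"]))
        alive[i] = False
        rest = np.flatnonzero(alive)
        if rest.size == 0:
            break
        near = np.abs(pos[rest] - pos[i]) <= cfg.window_bp
        far = rest[~near]
        kill = set(rest[near].tolist())
        if far.size:
            r2 = _r2_to_lead(G, int(rows[i]), rows[far])
            kill.update(far[r2 >= cfg.r2_threshold].tolist())
        alive[list(kill)] = False
    return leads


# ---------------------------------------------------------------------------
# COJO .ma-style summary-statistic I/O
# ---------------------------------------------------------------------------

def to_ma(assoc: pd.DataFrame) -> pd.DataFrame:
    """Convert a scan frame to the .ma column layout (SNP A1 A2 freq b se p N)."""
    return pd.DataFrame(
        {
            "SNP": assoc["snp"],
            "A1": assoc["a1"],
            "A2": assoc["a2"],
            "freq": assoc["freq"],
            "b": assoc["beta"],
            "se": assoc["se"],
            "p": assoc["p"],
            "N": assoc["n"],
        }
    )


def write_ma(assoc: pd.DataFrame, path) -> None:
    """Write summary statistics as tab-separated .ma (bit-exact column order)."""
    df = assoc if list(assoc.columns[:8]) == MA_COLUMNS else to_ma(assoc)
    df.to_csv(path, sep="\t", index=False, columns=MA_COLUMNS)


def read_ma(path, positions: pd.DataFrame | None = None) -> pd.DataFrame:
    """Read .ma summary statistics back into the internal scan layout.

    ``positions`` optionally maps SNP id → bp (columns snp, pos); without it
    positions are set to the row index (clumping then degenerates to the
    p-value ordering unless ids match a known map).
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MA_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f".ma file lacks columns {missing}")
    out = pd.DataFrame(
        {
            "snp": df["SNP"].astype(str),
            "a1": df["A1"],
            "a2": df["A2"],
            "freq": df["freq"].astype(float),
            "beta": df["b"].astype(float),
            "se": df["se"].astype(float),
            "p": df["p"].astype(float),
            "n": df["N"],
        }
    )
    if positions is not None:
        out = out.merge(positions[["snp", "pos"]], on="snp", how="left")
    else:
        out["pos"] = np.arange(len(out), dtype=np.int64)
    out["monomorphic"] = out["beta"].isna()
    return out[["snp", "pos", "a1", "a2", "freq", "beta", "se", "p", "n", "monomorphic"]]
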