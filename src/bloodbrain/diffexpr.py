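"""Moderated-t differential expression between CIE and Air groups.

Per-gene (optionally weighted) least-squares fits are combined with an
empirical-Bayes prior on the residual variances: the prior degrees of
freedom d0 and prior variance s0^2 are estimated by moment matching on the
log residual variances, and each gene's posterior variance

    s~_g^2 = (d0 * s0^2 + d_g * s_g^2) / (d0 + d_g)

shrinks the per-gene variance toward the prior.  The moderated t uses
s~_g^2 in the standard error and has d0 + d_g degrees of freedom, giving
stable inference at the small per-group sample sizes typical of animal
studies.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import special, stats

from bloodbrain.ingest import ExpressionMatrix
from bloodbrain.modlink import hypergeometric_tail

__all__ = [
    "GeneSet",
    "fit_moderated",
    "deg_set",
    "deg_overlap_test",
    "group_design",
]


@dataclasses.dataclass(frozen=True)
class GeneSet:
    """A named set of gene ids, optionally tagged with a regulation direction."""

    name: str
    genes: frozenset
    direction: str = "both"  # up | down | both

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        if self.direction not in ("up", "down", "both"):
            raise ValueError(f"bad direction {self.direction!r}")

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene) -> bool:
        return gene in self.genes


def group_design(groups: pd.Series | np.ndarray, reference: str = "Air") -> np.ndarray:
    """Two-column design (intercept, group indicator) for a binary contrast."""
    groups = np.asarray(groups)
    levels = np.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly 2 groups, got {levels.tolist()}")
    other = levels[levels != reference]
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} not present")
    indicator = (groups == other[0]).astype(float)
    return np.column_stack([np.ones(len(groups)), indicator])


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on the inverse scale)."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-8 * y:
            break
    return y


def estimate_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match (d0, s0^2) on log residual variances.

    Under the scaled-chi-square model, log(s_g^2) is a shifted log-chi-square
    whose mean and variance involve digamma/trigamma terms; matching the
    empirical moments of log(s_g^2) yields the prior.  Returns
    (inf, exp(mean)) when the observed spread is no larger than the sampling
    spread (no evidence of variance heterogeneity).
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    z = np.log(s2[ok])
    if z.size < 2:
        return np.inf, float(np.exp(z.mean())) if z.size else 1.0
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    n = e.size
    evar = ((e - emean) ** 2).sum() / (n - 1) - special.polygamma(1, df / 2.0)
    if evar <= 0:
        return np.inf, float(np.exp(emean))
    d0 = 2.0 * _trigamma_inverse(evar)
    s0_2 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return d0, s0_2


def fit_moderated(
    expr: ExpressionMatrix,
    design: np.ndarray,
    contrast: np.ndarray,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Per-gene weighted least squares with empirical-Bayes variance shrinkage.

    Parameters
    ----------
    expr : expression matrix; its ``weights`` (if any) enter the fits.
    design : (n_samples, p) full-rank design matrix.
    contrast : length-p vector; the reported effect is ``contrast @ beta``.
    prior_df : override the estimated prior degrees of freedom (0 gives the
        ordinary t-statistic; large values pin every posterior variance at
        s0^2).  None estimates it from the data.

    Returns a table indexed by gene with columns logFC, mean_expr, s2, df,
    d0, s0_2, s2_post, t, p, p_adj_BH.
    """
    design = np.asarray(design, dtype=float)
    contrast = np.asarray(contrast, dtype=float)
    n, p = design.shape
    if contrast.shape != (p,):
        raise ValueError(f"contrast length {contrast.shape} != design columns {p}")
    if np.linalg.matrix_rank(design) < p:
        raise ValueError("design matrix is rank deficient")
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")

    y = expr.values
    w = expr.weights
    n_genes = expr.n_genes

    logfc = np.empty(n_genes)
    unscaled = np.empty(n_genes)  # c' (X'WX)^-1 c
    s2 = np.empty(n_genes)

    if w is None:
        Q, R = np.linalg.qr(design)
        xtx_inv = np.linalg.inv(R.T @ R)
        u = float(contrast @ xtx_inv @ contrast)
        coef = np.linalg.solve(R, Q.T @ y.T).T
        resid = y - coef @ design.T
        logfc[:] = coef @ contrast
        unscaled[:] = u
        s2[:] = (resid**2).sum(axis=1) / df_resid
    else:
        for g in range(n_genes):
            wg = w[g]
            xw = design * wg[:, None]
            xtwx = design.T @ xw
            xtwx_inv = np.linalg.inv(xtwx)
            beta = xtwx_inv @ (xw.T @ y[g])
            resid = y[g] - design @ beta
            logfc[g] = contrast @ beta
            unscaled[g] = contrast @ xtwx_inv @ contrast
            s2[g] = (wg * resid**2).sum() / df_resid

    if prior_df is None:
        d0, s0_2 = estimate_prior(s2, df_resid)
    else:
        d0 = float(prior_df)
        _, s0_2 = estimate_prior(s2, df_resid)
        if not np.isfinite(d0):
            d0 = np.inf

    if np.isinf(d0):
        s2_post = np.full(n_genes, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid

    stderr = np.sqrt(unscaled * s2_post)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(stderr > 0, logfc / stderr, 0.0)
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    pvals = np.clip(pvals, np.nextafter(0, 1), 1.0)

    order = np.argsort(pvals, kind="stable")
    m = n_genes
    bh = np.empty(m)
    ranked = pvals[order] * m / np.arange(1, m + 1)
    bh[order] = np.minimum.accumulate(ranked[::-1])[::-1]
    bh = np.clip(bh, 0, 1)

    return pd.DataFrame(
        {
            "logFC": logfc,
            "mean_expr": y.mean(axis=1),
            "s2": s2,
            "df": float(df_resid),
            "d0": d0,
            "s0_2": s0_2,
            "s2_post": s2_post,
            "t": t,
            "p": pvals,
            "p_adj_BH": bh,
        },
        index=expr.genes,
    )


def deg_set(table: pd.DataFrame, alpha: float = 0.05, direction: str = "both",
            name: str | None = None) -> GeneSet:
    """Genes at nominal p < alpha, optionally restricted by fold-change sign."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    mask = table["p"] < alpha
    if direction == "up":
        mask &= table["logFC"] > 0
    elif direction == "down":
        mask &= table["logFC"] < 0
    elif direction != "both":
        raise ValueError(f"bad direction {direction!r}")
    genes = frozenset(table.index[mask])
    return GeneSet(name or f"DEG_{direction}", genes, direction)


def deg_overlap_test(set_a: GeneSet, set_b: GeneSet, universe: GeneSet) -> tuple[int, float]:
    """Overlap count and one-sided hypergeometric p for two DEG sets."""
    uni = universe.genes
    if not set_a.genes <= uni or not set_b.genes <= uni:
        raise ValueError("DEG sets must be subsets of the universe")
    overlap = len(set_a.genes & set_b.genes)
    p = hypergeometric_tail(overlap, len(set_a), len(set_b), len(uni))
    return overlap, p
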