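"""Blood-brain gene-level correlation analyses.

Two designs are supported.  Between-subject: each point is a gene, and the
normalized expression averaged across subjects in blood is correlated
(Spearman) with the average in a brain region — the design available to
human studies that pair living-donor blood with postmortem brain.
Within-subject: each point is a subject measured in both tissues, giving a
per-gene Spearman correlation across matched animals, with step-down
Holm-Bonferroni control over the thousands of genes tested.  Sex
differences in a correlation are assessed with the Fisher z test for
independent samples.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from bloodbrain.ingest import ExpressionMatrix, SampleMetadata

__all__ = [
    "between_subject_correlation",
    "within_subject_correlation",
    "holm_adjust",
    "compare_independent_correlations",
]


def between_subject_correlation(expr_a: ExpressionMatrix, expr_b: ExpressionMatrix):
    """Spearman correlation of per-gene mean expression across two tissues.

    Genes are averaged over all samples in each tissue (irrespective of
    treatment); the correlation is over the shared genes.  Returns
    (rho, p, table of per-gene means).
    """
    shared = expr_a.genes.intersection(expr_b.genes)
    if len(shared) < 10:
        raise ValueError(f"only {len(shared)} shared genes (< 10)")
    mean_a = expr_a.to_frame().loc[shared].mean(axis=1)
    mean_b = expr_b.to_frame().loc[shared].mean(axis=1)
    rho, p = stats.spearmanr(mean_a, mean_b)
    table = pd.DataFrame({"mean_a": mean_a, "mean_b": mean_b})
    return float(rho), float(p), table


def within_subject_correlation(
    expr_a: ExpressionMatrix,
    expr_b: ExpressionMatrix,
    metadata: SampleMetadata,
    tissue_a: str,
    tissue_b: str,
    min_subjects: int = 5,
) -> pd.DataFrame:
    """Per-gene Spearman correlation across subjects measured in both tissues.

    Samples are matched by subject id through the metadata; for each shared
    gene the expression vectors over matched subjects are rank-correlated.
    Holm adjustment runs over all genes tested.  Returns a table indexed by
    gene with columns rho, p, p_holm, n.
    """
    meta_a = metadata.for_tissue(tissue_a).set_index("subject_id")
    meta_b = metadata.for_tissue(tissue_b).set_index("subject_id")
    subjects = meta_a.index.intersection(meta_b.index)
    if len(subjects) == 0:
        raise ValueError("no subjects measured in both tissues")
    if len(subjects) < min_subjects:
        raise ValueError(f"only {len(subjects)} matched subjects (< {min_subjects})")

    samples_a = meta_a.loc[subjects, "sample_id"].tolist()
    samples_b = meta_b.loc[subjects, "sample_id"].tolist()
    shared = expr_a.genes.intersection(expr_b.genes)

    frame_a = expr_a.to_frame().loc[shared, samples_a].to_numpy()
    frame_b = expr_b.to_frame().loc[shared, samples_b].to_numpy()

    # rank rows once, then correlate with Pearson on ranks (Spearman with
    # average ranks for ties)
    ranks_a = stats.rankdata(frame_a, axis=1)
    ranks_b = stats.rankdata(frame_b, axis=1)
    ra = ranks_a - ranks_a.mean(axis=1, keepdims=True)
    rb = ranks_b - ranks_b.mean(axis=1, keepdims=True)
    num = (ra * rb).sum(axis=1)
    den = np.sqrt((ra**2).sum(axis=1) * (rb**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(den > 0, num / den, np.nan)
    rho = np.clip(rho, -1.0, 1.0)

    n = len(subjects)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = rho * np.sqrt((n - 2) / np.maximum(1.0 - rho**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), n - 2)
    p = np.where(np.isnan(rho), np.nan, np.clip(p, np.nextafter(0, 1), 1.0))
    p = np.where(np.abs(rho) >= 1.0, np.nextafter(0, 1), p)

    return pd.DataFrame(
        {"rho": rho, "p": p, "p_holm": holm_adjust(p), "n": n}, index=shared
    )


def holm_adjust(pvals) -> np.ndarray:
    """Step-down Holm-Bonferroni adjustment.

    Sorted ascending, adjusted_(i) = max_{j<=i} min(1, (m-j+1) * p_(j)),
    returned in the input order.  NaN p-values propagate as NaN and do not
    count toward m.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        p = p.ravel()
    ok = ~np.isnan(p)
    if ((p[ok] < 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must be in [0, 1]")
    out = np.full(p.shape, np.nan)
    m = int(ok.sum())
    if m == 0:
        return out
    idx = np.where(ok)[0]
    order = idx[np.argsort(p[idx], kind="stable")]
    mult = m - np.arange(m)
    stepped = np.minimum(1.0, np.maximum.accumulate(mult * p[order]))
    out[order] = stepped
    return out


def compare_independent_correlations(r1: float, n1: int, r2: float, n2: int):
    """Fisher z test for equality of two independent correlations.

    z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided
    normal p.  Used e.g. to compare a blood-brain correlation between males
    and females.
    """
    for r, n in ((r1, n1), (r2, n2)):
        if not abs(r) < 1:
            raise ValueError("|r| must be < 1 for the Fisher transform")
        if n <= 3:
            raise ValueError("need n > 3 per group")
    z1, z2 = np.arctanh(r1), np.arctanh(r2)
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (z1 - z2) / se
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
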