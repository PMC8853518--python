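"""Count ingestion and normalization.

Raw tag counts are converted to log2 counts-per-million (log-CPM) to remove
library-size differences, optionally with per-observation precision weights
estimated from the empirical mean-variance trend of the data (the classic
heteroscedasticity correction for RNA-seq counts): per-gene residual
standard deviations are smoothed against average log-count with lowess, and
each observation's weight is the inverse predicted variance at its fitted
log-count.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

__all__ = [
    "CountMatrix",
    "ExpressionMatrix",
    "SampleMetadata",
    "read_counts",
    "read_metadata",
    "logcpm",
    "voom",
]

METADATA_COLUMNS = [
    "sample_id",
    "subject_id",
    "tissue",
    "sex",
    "group",
    "consumption",
    "preference",
]


@dataclasses.dataclass
class CountMatrix:
    """Integer gene-by-sample count matrix for one tissue.

    Library sizes are the column sums of ``counts``; they are recomputed on
    construction so the invariant cannot drift.
    """

    genes: pd.Index
    samples: pd.Index
    counts: np.ndarray  # (n_genes, n_samples) non-negative integers
    library_size: np.ndarray = dataclasses.field(init=False)

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.samples = pd.Index(self.samples)
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.genes), len(self.samples)):
            raise ValueError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.genes)} genes x {len(self.samples)} samples"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.equal(np.mod(self.counts, 1), 0)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if self.genes.has_duplicates:
            dupes = self.genes[self.genes.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dupes[:5]}")
        if self.samples.has_duplicates:
            raise ValueError("duplicate sample ids")
        self.library_size = self.counts.sum(axis=0)

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.genes, columns=self.samples)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        idx = self.samples.get_indexer(pd.Index(sample_ids))
        if (idx < 0).any():
            raise KeyError("unknown sample ids in subset")
        return CountMatrix(self.genes, pd.Index(sample_ids), self.counts[:, idx])


@dataclasses.dataclass
class ExpressionMatrix:
    """Normalized log2-CPM expression, optionally with precision weights."""

    genes: pd.Index
    samples: pd.Index
    values: np.ndarray  # (n_genes, n_samples) log2-CPM
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.genes = pd.Index(self.genes)
        self.samples = pd.Index(self.samples)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.genes), len(self.samples)):
            raise ValueError("value matrix shape does not match gene/sample ids")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.values.shape:
                raise ValueError("weights must match the value matrix shape")
            if not np.all(self.weights > 0):
                raise ValueError("weights must be strictly positive")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.genes, columns=self.samples)


class SampleMetadata:
    """Per-sample annotations: subject, tissue, sex, group and drinking traits.

    One row per sample; (subject_id, tissue) pairs are unique so that the
    same subject measured in several tissues can be matched across them.
    """

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in METADATA_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        table = table.loc[:, METADATA_COLUMNS].copy()
        if table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in metadata")
        if table.duplicated(subset=["subject_id", "tissue"]).any():
            raise ValueError("(subject_id, tissue) pairs must be unique")
        self.table = table.reset_index(drop=True)

    def for_tissue(self, tissue: str) -> pd.DataFrame:
        sub = self.table[self.table["tissue"] == tissue]
        if sub.empty:
            raise KeyError(f"no samples for tissue {tissue!r}")
        return sub.reset_index(drop=True)

    def for_samples(self, sample_ids) -> pd.DataFrame:
        sub = self.table.set_index("sample_id").loc[list(sample_ids)]
        return sub.reset_index()

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    def __len__(self) -> int:
        return len(self.table)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a counts TSV (first column gene id, remaining columns samples)."""
    path = Path(path)
    table = pd.read_csv(path, sep="\t", index_col=0)
    if table.columns.empty:
        raise ValueError(f"{path}: no sample columns (missing header?)")
    if table.index.has_duplicates:
        dupes = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicated gene ids {dupes[:5]}")
    values = table.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        bad = np.argwhere(~table.map(lambda v: isinstance(v, (int, np.integer))).to_numpy())
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-integer cell at gene {table.index[r]!r}, sample {table.columns[c]!r}"
        )
    if not np.all(np.equal(np.mod(values, 1), 0)):
        bad = np.argwhere(np.mod(values, 1) != 0)
        r, c = bad[0]
        raise ValueError(
            f"{path}: non-integer cell at gene {table.index[r]!r}, sample {table.columns[c]!r}"
        )
    return CountMatrix(table.index, table.columns, values.astype(np.int64))


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read the sample metadata TSV."""
    return SampleMetadata(pd.read_csv(path, sep="\t"))


def logcpm(counts: CountMatrix, prior: float = 0.5) -> ExpressionMatrix:
    """log2 counts-per-million with a prior count.

    value(g, s) = log2((count + prior) / (library_size + 2*prior) * 1e6).
    The prior guards the logarithm at zero counts; the doubled prior in the
    denominator keeps the values a proper log-proportion.
    """
    if prior <= 0:
        raise ValueError("prior must be > 0")
    lib = counts.library_size.astype(float)
    if (lib <= 0).any():
        raise ValueError("library sizes must be positive")
    values = np.log2((counts.counts + prior) / (lib + 2.0 * prior) * 1e6)
    return ExpressionMatrix(counts.genes, counts.samples, values)


def _fit_residual_sd(y: np.ndarray, design: np.ndarray, weights: np.ndarray | None = None):
    """Per-gene least-squares fit; returns (fitted values, residual sd, df)."""
    n, p = design.shape
    df = n - p
    Q, R = np.linalg.qr(design)
    # beta = R^-1 Q'y'; hat = Q Q'
    coef = np.linalg.solve(R, Q.T @ y.T).T
    fitted = coef @ design.T
    resid = y - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / df)
    return fitted, sigma, df


def voom(counts: CountMatrix, design: np.ndarray, prior: float = 0.5,
         span: float = 0.5) -> ExpressionMatrix:
    """log-CPM with mean-variance precision weights.

    Fits each gene's log-CPM to ``design`` by least squares, smooths
    sqrt(residual sd) against average log2-count with lowess (fraction
    ``span``), and converts the trend evaluated at each observation's fitted
    log-count into an inverse-variance weight.
    """
    design = np.asarray(design, dtype=float)
    n = counts.n_samples
    if design.ndim != 2 or design.shape[0] != n:
        raise ValueError("design must be (n_samples, n_covariates)")
    if design.shape[1] >= n:
        raise ValueError("fewer samples than design columns")
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if n - design.shape[1] < 2:
        raise ValueError("need >= 2 residual degrees of freedom")

    expr = logcpm(counts, prior=prior)
    y = expr.values
    lib = counts.library_size.astype(float) + 2.0 * prior

    fitted, sigma, _df = _fit_residual_sd(y, design)

    # mean log2 count per gene (back from CPM scale using the mean log library)
    sx = y.mean(axis=1) + np.mean(np.log2(lib)) - np.log2(1e6)
    sy = np.sqrt(sigma)

    ok = sigma > 1e-12  # genes with exactly-zero residual sd carry no trend info
    if ok.sum() < 10:
        trend_x = np.array([sx.min(), sx.max()])
        trend_y = np.array([max(sy.mean(), 1e-6)] * 2)
    else:
        smoothed = _sm_lowess(sy[ok], sx[ok], frac=span, return_sorted=True)
        trend_x, trend_y = smoothed[:, 0], smoothed[:, 1]
        trend_x, keep = np.unique(trend_x, return_index=True)
        trend_y = trend_y[keep]

    # each observation's fitted log-count, interpolated on the trend
    fitted_logcount = fitted + np.log2(lib)[None, :] - np.log2(1e6)
    pred_sqrt_sd = np.interp(fitted_logcount, trend_x, trend_y)
    pred_sqrt_sd = np.clip(pred_sqrt_sd, 1e-6, None)
    weights = pred_sqrt_sd**-4.0

    return ExpressionMatrix(counts.genes, counts.samples, y, weights)
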