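"""Low-count filtering, logCPM and mean-variance precision weights.

The filter reproduces the standard grouped low-expression rule for bulk
RNA-seq count matrices (a CPM cutoff that must be met in at least the
smallest group's worth of samples, plus a total-count floor).  Expression
is modelled on the log2 counts-per-million scale with the usual 0.5 / 1
pseudo-count offsets, and each observation receives an inverse-variance
precision weight read off a lowess trend of residual standard deviation
against average log count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

__all__ = [
    "CountMatrix",
    "WeightedExpression",
    "filter_low_counts",
    "compute_logcpm",
    "estimate_precision_weights",
]


@dataclass
class CountMatrix:
    """Integer gene x sample counts with derived library sizes."""

    gene_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (genes, samples)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("count matrix shape does not match ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("non-integer counts")
            self.counts = self.counts.astype(np.int64)
        if (self.lib_sizes <= 0).any():
            raise ValueError("every sample needs a positive library size")

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def subset_genes(self, keep: list[str]) -> "CountMatrix":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in keep]
        return CountMatrix(list(keep), list(self.sample_ids), self.counts[rows])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.gene_ids, columns=self.sample_ids)


@dataclass
class WeightedExpression:
    """Paired logCPM and precision-weight matrices (same shape)."""

    gene_ids: list[str]
    sample_ids: list[str]
    logcpm: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        self.logcpm = np.asarray(self.logcpm, dtype=float)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.logcpm.shape != self.weights.shape:
            raise ValueError("logcpm and weights shapes differ")
        if not np.isfinite(self.logcpm).all():
            raise ValueError("non-finite logcpm")
        if not (np.isfinite(self.weights).all() and (self.weights > 0).all()):
            raise ValueError("weights must be finite and positive")


def filter_low_counts(
    counts: CountMatrix,
    groups,
    min_count: float = 50,
    min_total_count: float = 15,
) -> list[str]:
    """Gene ids passing the grouped low-count filter, in input order.

    The CPM cutoff is ``min_count / median(lib_sizes) * 1e6``.  A gene is
    kept if its CPM reaches the cutoff in at least ``n*`` samples -- where
    ``n*`` is the smallest group size ``s``, softened to ``10 + (s-10)*0.7``
    when ``s`` exceeds 10 -- and its total count reaches
    ``min_total_count``.  Comparisons carry a small relative slack so exact
    boundary cases are kept.
    """
    groups = np.asarray(groups)
    if len(groups) != len(counts.sample_ids):
        raise ValueError("one group label per sample required")
    sizes = pd.Series(groups).value_counts()
    if (sizes == 0).any():
        raise ValueError("empty group")
    s = float(sizes.min())
    n_star = s if s <= 10 else 10.0 + (s - 10.0) * 0.7

    lib = counts.lib_sizes.astype(float)
    cutoff = min_count / np.median(lib) * 1e6
    cpm = counts.counts / lib[None, :] * 1e6
    tol = 1e-10
    enough_samples = (cpm >= cutoff * (1 - tol)).sum(axis=1) >= n_star - 1e-14
    enough_total = counts.counts.sum(axis=1) >= min_total_count * (1 - tol)
    keep = enough_samples & enough_total
    return [g for g, k in zip(counts.gene_ids, keep) if k]


def compute_logcpm(counts: CountMatrix) -> np.ndarray:
    """log2((count + 0.5) / (lib_size + 1) * 1e6), genes x samples."""
    lib = counts.lib_sizes.astype(float)
    return np.log2((counts.counts + 0.5) / (lib + 1.0)[None, :] * 1e6)


def estimate_precision_weights(
    counts: CountMatrix,
    design: np.ndarray,
    span: float = 0.5,
) -> WeightedExpression:
    """Estimate per-observation precision weights from the mean-variance trend.

    Per gene, logCPM is regressed on ``design`` by least squares; the
    square root of the residual standard deviation is smoothed (lowess,
    ``span`` fraction) against average log2 count.  Each observation's
    sqrt-sd is then predicted from its fitted log count by piecewise-linear
    interpolation on the trend (constant beyond the ends) and the weight is
    the predicted value to the power -4, i.e. an inverse variance.
    """
    design = np.asarray(design, dtype=float)
    n, p = design.shape
    if n != len(counts.sample_ids):
        raise ValueError("design rows must match samples")
    if n - p < 2:
        raise ValueError("need at least two residual degrees of freedom")

    lib = counts.lib_sizes.astype(float)
    logcpm = compute_logcpm(counts)

    Q, _ = np.linalg.qr(design)
    fitted = (Q @ (Q.T @ logcpm.T)).T
    resid = logcpm - fitted
    sigma = np.sqrt((resid**2).sum(axis=1) / (n - p))
    sqrt_sd = np.sqrt(np.maximum(sigma, 1e-8))

    # average log2 count, shifted back from the CPM scale
    avg_log_count = logcpm.mean(axis=1) + np.mean(np.log2(lib + 1.0)) - np.log2(1e6)

    trend = lowess(sqrt_sd, avg_log_count, frac=span, it=3, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    # collapse duplicate abscissae so interpolation is well defined
    tx, inv = np.unique(tx, return_inverse=True)
    ty = np.bincount(inv, weights=ty) / np.bincount(inv)

    fitted_log_count = fitted + np.log2(lib + 1.0)[None, :] - np.log2(1e6)
    pred = np.interp(fitted_log_count, tx, ty)
    pred = np.maximum(pred, 1e-6)
    weights = pred**-4.0

    return WeightedExpression(
        gene_ids=list(counts.gene_ids),
        sample_ids=list(counts.sample_ids),
        logcpm=logcpm,
        weights=weights,
    )
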