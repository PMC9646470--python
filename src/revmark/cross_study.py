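"""Cross-cohort validation of effect sizes.

Discovered repeat-length associations are checked against an independent
unpaired case/control cohort: per gene, a two-sample Wilcoxon rank-sum
test on normalized log counts and a simple case-minus-control mean
difference, then Pearson correlation of the two effect-size vectors over
shared genes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ExternalCohort",
    "wilcoxon_two_sample",
    "group_mean_difference",
    "effect_size_concordance",
]

#: combined sample size at or below which the exact null distribution is
#: enumerated (cheap) rather than normal-approximated
EXACT_LIMIT = 12


@dataclass
class ExternalCohort:
    """Normalized log-count matrix with case/control labels."""

    gene_ids: list[str]
    logcounts: np.ndarray  # (genes, samples)
    labels: list[str]      # 'case' / 'control'

    def __post_init__(self) -> None:
        self.logcounts = np.asarray(self.logcounts, dtype=float)
        labels = np.asarray(self.labels)
        if not set(labels) <= {"case", "control"}:
            raise ValueError("labels must be 'case' or 'control'")
        for lab in ("case", "control"):
            if (labels == lab).sum() < 2:
                raise ValueError(f"need at least two '{lab}' samples")
        if self.logcounts.shape != (len(self.gene_ids), len(labels)):
            raise ValueError("matrix shape does not match ids/labels")

    @property
    def case_mask(self) -> np.ndarray:
        return np.asarray(self.labels) == "case"


def wilcoxon_two_sample(x, y) -> tuple[float, float]:
    """Two-sided two-sample Wilcoxon (Mann-Whitney) rank-sum test.

    Mid-ranks for ties; exact enumeration when the combined sample is
    small and tie-free, otherwise the normal approximation with
    continuity and tie corrections.  Returns the rank-sum statistic of
    the first sample and the two-sided p-value.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty group")
    has_ties = len(np.unique(np.r_[x, y])) < x.size + y.size
    method = "exact" if (x.size + y.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    rank_sum = float(res.statistic + x.size * (x.size + 1) / 2.0)
    return rank_sum, float(res.pvalue)


def group_mean_difference(cohort: ExternalCohort) -> pd.Series:
    """Per-gene mean(case) - mean(control) of normalized log counts."""
    case = cohort.case_mask
    diff = cohort.logcounts[:, case].mean(axis=1) - cohort.logcounts[:, ~case].mean(axis=1)
    return pd.Series(diff, index=cohort.gene_ids, name="mean_difference")


def effect_size_concordance(
    internal: pd.Series, external: pd.Series
) -> tuple[float, int, pd.DataFrame]:
    """Pearson r between two per-gene effect-size vectors on shared ids."""
    shared = internal.index.intersection(external.index)
    if len(shared) < 3:
        raise ValueError("need at least three shared genes")
    a = internal.loc[shared].astype(float)
    b = external.loc[shared].astype(float)
    r = float(stats.pearsonr(a, b)[0])
    scatter = pd.DataFrame(
        {"gene_id": shared, "internal": a.to_numpy(), "external": b.to_numpy()}
    )
    return r, int(len(shared)), scatter
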