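"""Significant-set construction, reversal statistics and clustering.

A "reversal" biomarker is a gene significantly associated with both the
CTG-repeat length (disease load) and the compound therapy-response score,
with opposite coefficient signs: expression pushed away from normal by the
disease moves back toward normal in clinical responders.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

__all__ = [
    "GeneSet",
    "ReversalReport",
    "bh_fdr",
    "select_significant",
    "intersect_sets",
    "reversal_stats",
    "residualized_response_effects",
    "per_patient_delta",
    "cluster_deltas",
    "pearson_corr_test",
]


@dataclass
class GeneSet:
    label: str
    gene_ids: list[str]
    signs: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate ids in gene set")
        missing = [g for g in self.gene_ids if g not in self.signs]
        if missing:
            raise ValueError(f"ids without a direction sign: {missing[:5]}")

    @property
    def n_up(self) -> int:
        return sum(1 for g in self.gene_ids if self.signs[g] > 0)

    @property
    def n_down(self) -> int:
        return sum(1 for g in self.gene_ids if self.signs[g] < 0)


@dataclass
class ReversalReport:
    overlap_ids: list[str]
    pearson_r_all: float
    pearson_r_overlap: float
    sign_opposition_fraction: float
    n_genes_all: int
    per_gene: pd.DataFrame | None = None


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment; missing values pass through."""
    p = np.asarray(pvals, dtype=float)
    out = np.full(p.shape, np.nan)
    mask = np.isfinite(p)
    pm = p[mask]
    if ((pm <= 0) | (pm > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    m = pm.size
    if m == 0:
        return out
    order = np.argsort(pm, kind="stable")
    ranked = pm[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[mask] = adj
    return out


def select_significant(
    results: pd.DataFrame, alpha: float = 0.05, label: str = "set"
) -> GeneSet:
    """Genes with q < alpha, signed by their coefficient."""
    usable = results[results["q_fdr"].notna()]
    hits = usable[usable["q_fdr"] < alpha]
    ids = list(hits["gene_id"].astype(str))
    signs = {g: (1 if c > 0 else -1) for g, c in zip(ids, hits["coef"])}
    return GeneSet(label=label, gene_ids=ids, signs=signs)


def intersect_sets(a: GeneSet, b: GeneSet) -> GeneSet:
    """Id intersection; the stored sign comes from ``a`` (both are kept
    downstream by :func:`reversal_stats`, which works from the result
    tables)."""
    common = [g for g in a.gene_ids if g in set(b.gene_ids)]
    return GeneSet(
        label=f"{a.label}&{b.label}",
        gene_ids=common,
        signs={g: a.signs[g] for g in common},
    )


def reversal_stats(
    ctg_results: pd.DataFrame,
    response_results: pd.DataFrame,
    overlap: GeneSet,
) -> ReversalReport:
    """Coefficient concordance between the disease and response models.

    Pearson r between the CTG and response coefficient vectors is computed
    over all shared genes and over the overlap set; the sign-opposition
    fraction is the share of overlap genes whose two coefficients have
    opposite signs.
    """
    merged = ctg_results.merge(
        response_results, on="gene_id", suffixes=("_ctg", "_resp")
    )
    merged = merged[merged["converged_ctg"] & merged["converged_resp"]]
    r_all = (
        float(stats.pearsonr(merged["coef_ctg"], merged["coef_resp"])[0])
        if len(merged) >= 2
        else float("nan")
    )
    sub = merged[merged["gene_id"].isin(set(overlap.gene_ids))]
    r_overlap = (
        float(stats.pearsonr(sub["coef_ctg"], sub["coef_resp"])[0])
        if len(sub) >= 2
        else float("nan")
    )
    frac = (
        float((np.sign(sub["coef_ctg"]) == -np.sign(sub["coef_resp"])).mean())
        if len(sub)
        else float("nan")
    )
    return ReversalReport(
        overlap_ids=list(overlap.gene_ids),
        pearson_r_all=r_all,
        pearson_r_overlap=r_overlap,
        sign_opposition_fraction=frac,
        n_genes_all=int(len(merged)),
        per_gene=sub[["gene_id", "coef_ctg", "coef_resp"]].reset_index(drop=True),
    )


def residualized_response_effects(expr, samples, scores) -> pd.DataFrame:
    """Confounding check: response effects on repeat-length residuals.

    Stage 1 fits intercept + timepoint + repeat length per gene with a
    patient random intercept and extracts conditional residuals (fixed and
    random parts removed).  Stage 2 fits the zero-at-baseline response
    covariate on those residuals, again with a patient random intercept.
    Returns the per-gene response coefficients from the full model and from
    the residualized model plus their Pearson r (as attribute ``pearson_r``
    on the returned frame).
    """
    from .lmm import Model, _BatchedREML, build_design
    from .prep import WeightedExpression

    d_ctg = build_design(samples, None, Model.CTG)
    eng = _BatchedREML(expr.logcpm, expr.weights, d_ctg.matrix, d_ctg.groups)
    theta, _, _ = eng.optimize()
    est = eng.estimates(theta)

    # conditional residuals in the engine's (sorted) sample order
    E = eng.Y - est["beta"] @ eng.X.T
    WE = eng.W * E
    segWE = np.add.reduceat(WE, eng.starts, axis=1)
    counts = np.diff(np.r_[eng.starts, eng.n])
    blup = np.repeat(theta[:, None] / (1.0 + theta[:, None] * eng.S) * segWE, counts, axis=1)
    resid_sorted = E - blup
    resid = np.empty_like(resid_sorted)
    resid[:, eng.order] = resid_sorted
    w_orig = expr.weights

    resid_expr = WeightedExpression(
        gene_ids=list(expr.gene_ids),
        sample_ids=list(expr.sample_ids),
        logcpm=resid,
        weights=w_orig,
    )

    # stage 2: intercept + zero-at-baseline response (timepoint effect is
    # already removed, so the design is reduced accordingly)
    samples = samples.reset_index(drop=True)
    cbt = (samples["timepoint"].to_numpy() == "T10M").astype(float)
    lookup = dict(zip(scores["patient_id"].astype(str), scores["compound_response"]))
    resp = np.array([lookup[p] for p in samples["patient_id"].astype(str)])
    X2 = np.column_stack([np.ones(len(samples)), resp * cbt])
    if np.linalg.matrix_rank(X2) < 2:
        raise ValueError("response covariate has no variation (all scores zero?)")
    eng2 = _BatchedREML(resid, w_orig, X2, d_ctg.groups)
    theta2, _, _ = eng2.optimize()
    est2 = eng2.estimates(theta2)

    d_resp = build_design(samples, scores, Model.RESPONSE)
    eng3 = _BatchedREML(expr.logcpm, expr.weights, d_resp.matrix, d_resp.groups)
    theta3, _, _ = eng3.optimize()
    est3 = eng3.estimates(theta3)

    out = pd.DataFrame(
        {
            "gene_id": list(expr.gene_ids),
            "coef_response_full": est3["beta"][:, d_resp.coef_index],
            "coef_response_residualized": est2["beta"][:, 1],
        }
    )
    out.attrs["pearson_r"] = float(
        stats.pearsonr(
            out["coef_response_full"], out["coef_response_residualized"]
        )[0]
    )
    return out


def per_patient_delta(expr, samples: pd.DataFrame) -> pd.DataFrame:
    """Patient x gene matrix of logCPM(T10M) - logCPM(T0)."""
    samples = samples.reset_index(drop=True)
    col = {s: i for i, s in enumerate(expr.sample_ids)}
    pivot = samples.pivot(index="patient_id", columns="timepoint", values="sample_id")
    if "T0" not in pivot.columns or "T10M" not in pivot.columns:
        raise ValueError("both timepoints required")
    if pivot.isna().any().any():
        bad = list(pivot[pivot.isna().any(axis=1)].index.astype(str))
        raise ValueError(f"unpaired patient(s): {bad}")
    i0 = [col[s] for s in pivot["T0"]]
    i1 = [col[s] for s in pivot["T10M"]]
    delta = expr.logcpm[:, i1] - expr.logcpm[:, i0]
    return pd.DataFrame(delta.T, index=pivot.index.astype(str), columns=expr.gene_ids)


def cluster_deltas(delta: pd.DataFrame, gene_subset: list[str]):
    """Complete-linkage clustering of per-patient expression changes.

    Values are z-scored per gene (centered and scaled) before Euclidean
    complete-linkage agglomeration on both axes.  Zero-variance genes are
    dropped with a warning entry.  Returns (patient leaf order, gene leaf
    order, patient linkage, gene linkage, dropped genes).
    """
    if len(gene_subset) == 0:
        raise ValueError("empty gene subset")
    if len(delta) < 2:
        raise ValueError("need at least two patients")
    sub = delta[list(gene_subset)]
    sd = sub.std(axis=0, ddof=1)
    dropped = list(sd[sd == 0].index.astype(str))
    sub = sub[[g for g in sub.columns if g not in set(dropped)]]
    if sub.shape[1] == 0:
        raise ValueError("all genes in the subset have zero variance")
    z = (sub - sub.mean(axis=0)) / sub.std(axis=0, ddof=1)

    pat_link = hierarchy.linkage(pdist(z.to_numpy()), method="complete")
    pat_order = [str(delta.index[i]) for i in hierarchy.leaves_list(pat_link)]
    if z.shape[1] >= 2:
        gene_link = hierarchy.linkage(pdist(z.to_numpy().T), method="complete")
        gene_order = [str(z.columns[i]) for i in hierarchy.leaves_list(gene_link)]
    else:
        gene_link = None
        gene_order = [str(c) for c in z.columns]
    return pat_order, gene_order, pat_link, gene_link, dropped


def pearson_corr_test(x, y) -> tuple[float, float]:
    """Pearson r and the two-sided t-based nominal p-value."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("degenerate variance")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
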