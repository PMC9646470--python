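"""End-to-end orchestration: simulate, prep, score, fit, discover, validate.

One global seed is fanned out to per-stage child seeds (stage names
hashed with CRC32), so each stage is independently reproducible.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import discovery, io, lmm, prep, scores
from .cross_study import effect_size_concordance, group_mean_difference
from .simulate import TruthConfig, generate_cohort, generate_external_cohort

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed, kept below 2**31."""
    return (seed * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class RunConfig:
    outdir: str = "out"
    seed: int = 0
    truth: TruthConfig = field(default_factory=TruthConfig)
    alpha_fdr: float = 0.05
    min_count: float = 50
    min_total_count: float = 15
    weight_span: float = 0.5
    external_n_cases: int = 20
    external_n_controls: int = 20

    def __post_init__(self) -> None:
        if not (0 < self.alpha_fdr < 1):
            raise ValueError("alpha_fdr must lie in (0, 1)")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        truth = TruthConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (raw.pop("truth", {}) or {}).items()
        })
        return cls(truth=truth, **raw)


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run report."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # simulate ---------------------------------------------------------------
    tc = config.truth
    tc.seed = stage_seed(config.seed, "simulate")
    counts, samples, outcomes, measures, truth = generate_cohort(tc)
    io.write_counts(counts.to_frame(), outdir / "counts.tsv")
    io.write_table(samples, outdir / "samples.tsv")
    io.write_table(outcomes, outdir / "outcomes.tsv")
    io.write_table(measures, outdir / "measures.tsv")
    io.write_table(truth.gene_frame(), outdir / "truth.tsv")
    io.write_table(truth.patient_frame(), outdir / "truth_patients.tsv")

    # prep -------------------------------------------------------------------
    groups = samples["timepoint"].to_numpy()
    kept = prep.filter_low_counts(
        counts, groups, config.min_count, config.min_total_count
    )
    filtered = counts.subset_genes(kept)
    design = np.column_stack(
        [np.ones(len(samples)), (groups == "T10M").astype(float)]
    )
    expr = prep.estimate_precision_weights(filtered, design, span=config.weight_span)
    io.write_table(
        pd.DataFrame(expr.logcpm, index=kept, columns=expr.sample_ids),
        outdir / "logcpm.tsv",
        index=True,
    )
    io.write_table(
        pd.DataFrame(expr.weights, index=kept, columns=expr.sample_ids),
        outdir / "weights.tsv",
        index=True,
    )

    # score ------------------------------------------------------------------
    resp_scores, scaled = scores.compute_scores(outcomes, measures)
    io.write_table(resp_scores, outdir / "response_scores.tsv")

    # fit --------------------------------------------------------------------
    results = {}
    for model in (lmm.Model.CBT, lmm.Model.CTG, lmm.Model.RESPONSE):
        res = lmm.fit_all_genes(expr, samples, resp_scores, model)
        results[model.value] = res
        io.write_table(
            res[
                [
                    "gene_id", "coef", "se", "t", "df", "p", "q_fdr",
                    "fold_change", "converged",
                ]
            ],
            outdir / f"results_{model.value}.tsv",
        )

    # discover ---------------------------------------------------------------
    sets = {
        name: discovery.select_significant(results[name], config.alpha_fdr, name)
        for name in ("cbt", "ctg", "response")
    }
    overlap = discovery.intersect_sets(sets["ctg"], sets["response"])
    report_rev = discovery.reversal_stats(results["ctg"], results["response"], overlap)
    io.write_table(
        pd.DataFrame({"gene_id": overlap.gene_ids}), outdir / "overlap.tsv"
    )
    if report_rev.per_gene is not None:
        io.write_table(report_rev.per_gene, outdir / "reversal_report.tsv")

    # per-gene correlation of expression change with the clinical score
    delta = discovery.per_patient_delta(expr, samples)
    score_by_patient = resp_scores.set_index("patient_id")["compound_response"]
    n_nominal = 0
    for g in overlap.gene_ids:
        r, p = discovery.pearson_corr_test(
            delta[g].to_numpy(), score_by_patient.loc[delta.index].to_numpy()
        )
        n_nominal += p < 0.05

    # validate ---------------------------------------------------------------
    ext = generate_external_cohort(
        truth,
        config.external_n_cases,
        config.external_n_controls,
        stage_seed(config.seed, "external"),
    )
    ext_effect = group_mean_difference(ext)
    internal = results["ctg"].set_index("gene_id")["coef"]
    ctg_in_expr = [g for g in truth.ctg_set if g in set(kept)]
    conc_r, n_shared, scatter = effect_size_concordance(
        internal.loc[ctg_in_expr], ext_effect
    )
    io.write_table(scatter, outdir / "concordance.tsv")

    report = {
        "seed": config.seed,
        "stage_seeds": {
            s: stage_seed(config.seed, s) for s in ("simulate", "external")
        },
        "n_genes_simulated": tc.n_genes,
        "n_genes_after_filter": len(kept),
        "sets": {
            name: {"total": len(s.gene_ids), "up": s.n_up, "down": s.n_down}
            for name, s in sets.items()
        },
        "n_nonconverged": {
            name: int((~results[name]["converged"]).sum()) for name in results
        },
        "overlap": {
            "n": len(overlap.gene_ids),
            "pearson_r_overlap": report_rev.pearson_r_overlap,
            "pearson_r_all_genes": report_rev.pearson_r_all,
            "sign_opposition_fraction": report_rev.sign_opposition_fraction,
            "n_nominal_delta_correlations": int(n_nominal),
        },
        "external": {
            "concordance_r_ctg_genes": conc_r,
            "n_shared_genes": n_shared,
        },
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
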