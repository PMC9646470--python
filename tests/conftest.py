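import numpy as np
import pandas as pd
import pytest

from revmark.lmm import Model, fit_all_genes
from revmark.prep import estimate_precision_weights, filter_low_counts
from revmark.scores import compute_scores
from revmark.simulate import TruthConfig, generate_cohort


def paired_samples(n_patients: int, rng=None, ctg=None) -> pd.DataFrame:
    """A minimal paired sample sheet for n patients."""
    if ctg is None:
        rng = rng or np.random.default_rng(0)
        ctg = rng.integers(120, 900, n_patients)
    return pd.DataFrame(
        {
            "sample_id": [f"P{i:02d}_{t}" for i in range(n_patients) for t in ("T0", "T10M")],
            "patient_id": [f"P{i:02d}" for i in range(n_patients) for _ in range(2)],
            "timepoint": ["T0", "T10M"] * n_patients,
            "ctg_length": np.repeat(np.asarray(ctg, dtype=int), 2),
        }
    )


@pytest.fixture(scope="session")
def small_cohort():
    """One fully prepped small synthetic cohort shared across tests."""
    cfg = TruthConfig(
        n_genes=800,
        n_cbt_genes=50,
        n_ctg_genes=80,
        n_response_genes=40,
        n_reversal_genes=25,
        n_patients=18,
        libsize_scale=0.1,
        seed=202,
    )
    counts, samples, outcomes, measures, truth = generate_cohort(cfg)
    groups = samples["timepoint"].to_numpy()
    kept = filter_low_counts(counts, groups)
    design = np.column_stack([np.ones(len(samples)), (groups == "T10M").astype(float)])
    expr = estimate_precision_weights(counts.subset_genes(kept), design)
    scores, _ = compute_scores(outcomes, measures)
    return {
        "config": cfg,
        "counts": counts,
        "samples": samples,
        "outcomes": outcomes,
        "measures": measures,
        "truth": truth,
        "kept": kept,
        "expr": expr,
        "scores": scores,
    }


@pytest.fixture(scope="session")
def small_results(small_cohort):
    """Per-gene model results for all three designs on the small cohort."""
    return {
        m.value: fit_all_genes(
            small_cohort["expr"],
            small_cohort["samples"],
            small_cohort["scores"],
            m,
        )
        for m in (Model.CBT, Model.CTG, Model.RESPONSE)
    }
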