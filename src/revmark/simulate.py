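"""Synthetic paired-cohort generator with planted ground truth.

Emulates a small clinical-trial transcriptome study: ``n_patients``
patients sampled before (T0) and after (T10M) a behavioural intervention,
negative-binomial gene counts with per-patient random intercepts, a
disease-load covariate (modal CTG-repeat length of the expanded allele),
a latent therapy response driving both a multi-instrument clinical outcome
panel and a set of response-associated genes, and a planted set of
"reversal" genes whose repeat-length and response effects have opposite
signs.  Everything is drawn from a single seed and recorded in
:class:`CohortTruth`, so recovery of the planted structure can be scored
exactly.

On the log2 scale, the expected expression of gene ``g`` in patient ``p``
at timepoint ``t`` is

    eta = mu_g + u_gp + delta_g * I(t=T10M)
          + gamma_g * CTG_p / 100 + rho_g * r_p * I(t=T10M)

with ``u_gp ~ N(0, tau_g^2)`` the patient-gene intercept, and counts are
negative binomial (variance = mean + phi_g * mean^2) at a depth set by the
sample's library size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prep import CountMatrix
from .cross_study import ExternalCohort

__all__ = [
    "TruthConfig",
    "CohortTruth",
    "SamplingConfig",
    "generate_cohort",
    "generate_external_cohort",
    "sample_patients",
]


@dataclass
class TruthConfig:
    """All knobs of the generator; defaults mirror the emulated study.

    Effect magnitudes are log2 fold changes drawn uniformly from the given
    (low, high) magnitude band with random signs; the repeat-length effect
    is per 100 repeats.  Library sizes are log-normal around 30M read
    pairs, scaled down by ``libsize_scale`` for desk-scale work.
    """

    n_patients: int = 27
    n_genes: int = 10_000
    n_cbt_genes: int = 500
    n_ctg_genes: int = 600
    n_response_genes: int = 300
    n_reversal_genes: int = 100
    ctg_range: tuple[int, int] = (120, 900)
    cbt_log2fc_range: tuple[float, float] = (0.2, 1.2)
    ctg_log2fc_per100_range: tuple[float, float] = (0.1, 0.4)
    response_log2fc_range: tuple[float, float] = (0.15, 0.6)
    response_range: tuple[float, float] = (-1.5, 2.75)
    baseline_log2_mean: float = 4.0
    baseline_log2_sd: float = 2.0
    libsize_log_mean: float = float(np.log(3e7))
    libsize_log_sd: float = 0.25
    libsize_scale: float = 0.01
    nb_dispersion_range: tuple[float, float] = (0.01, 0.2)
    random_intercept_sd_range: tuple[float, float] = (0.05, 0.3)
    n_measures: int = 10
    measure_loading_range: tuple[float, float] = (0.5, 1.5)
    measure_noise_sd: float = 0.5
    n_lower_is_better: int = 3
    seed: int = 0

    def validate(self) -> None:
        sizes = (
            self.n_cbt_genes,
            self.n_ctg_genes,
            self.n_response_genes,
            self.n_reversal_genes,
        )
        if any(s < 0 for s in sizes):
            raise ValueError("gene-set sizes must be non-negative")
        if self.n_reversal_genes > min(self.n_ctg_genes, self.n_response_genes):
            raise ValueError(
                "reversal genes must be a subset of both the CTG and response sets"
            )
        distinct = (
            self.n_cbt_genes
            + self.n_ctg_genes
            + (self.n_response_genes - self.n_reversal_genes)
        )
        if distinct > self.n_genes:
            raise ValueError("effect sets exceed the number of genes")
        if self.ctg_range[0] < 50:
            raise ValueError("disease alleles carry at least 50 repeats")
        if self.ctg_range[0] > self.ctg_range[1]:
            raise ValueError("invalid ctg_range")
        for name in ("nb_dispersion_range",):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be strictly positive")
        lo, hi = self.random_intercept_sd_range
        if lo < 0 or hi < lo:
            raise ValueError("random_intercept_sd_range must be non-negative")
        if self.n_lower_is_better > self.n_measures:
            raise ValueError("n_lower_is_better exceeds n_measures")
        if self.n_patients < 2 or self.n_genes < 1:
            raise ValueError("need at least two patients and one gene")


@dataclass
class CohortTruth:
    """Ground truth of one generated cohort (fully replayable)."""

    config: TruthConfig
    gene_ids: list[str]
    patient_ids: list[str]
    baseline_log2_mean: np.ndarray      # mu_g
    cbt_effect: np.ndarray              # delta_g (log2)
    ctg_effect_per100: np.ndarray       # gamma_g (log2 per 100 repeats)
    response_effect: np.ndarray         # rho_g (log2 per response unit)
    dispersion: np.ndarray              # phi_g
    random_intercept_sd: np.ndarray     # tau_g
    ctg_length: np.ndarray              # per patient
    latent_response: np.ndarray         # per patient
    random_intercepts: np.ndarray       # u_gp, (genes, patients)
    cbt_set: list[str] = field(default_factory=list)
    ctg_set: list[str] = field(default_factory=list)
    response_set: list[str] = field(default_factory=list)
    reversal_set: list[str] = field(default_factory=list)

    def gene_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "baseline_log2_mean": self.baseline_log2_mean,
                "cbt_effect": self.cbt_effect,
                "ctg_effect_per100": self.ctg_effect_per100,
                "response_effect": self.response_effect,
                "dispersion": self.dispersion,
                "random_intercept_sd": self.random_intercept_sd,
                "in_cbt_set": [g in set(self.cbt_set) for g in self.gene_ids],
                "in_ctg_set": [g in set(self.ctg_set) for g in self.gene_ids],
                "in_response_set": [g in set(self.response_set) for g in self.gene_ids],
                "in_reversal_set": [g in set(self.reversal_set) for g in self.gene_ids],
            }
        )

    def patient_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "ctg_length": self.ctg_length,
                "latent_response": self.latent_response,
            }
        )


def _signed_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    mag = rng.uniform(lo, hi, size=n)
    sign = rng.choice([-1.0, 1.0], size=n)
    return mag * sign


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Gamma-Poisson draw with variance = mean + phi * mean^2."""
    shape = 1.0 / phi
    lam = mean * rng.gamma(shape=shape, scale=1.0, size=mean.shape) / shape
    return rng.poisson(lam)


def generate_cohort(config: TruthConfig):
    """Generate counts, sample sheet, outcome panel and ground truth.

    Returns ``(CountMatrix, sample sheet, outcomes, measures, truth)``;
    the outcome table is long-form (patient_id, measure_id, timepoint,
    value) with per-measure metadata (orientation, is_control) alongside.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    G, P = config.n_genes, config.n_patients

    gene_ids = [f"G{i:05d}" for i in range(G)]
    patient_ids = [f"P{i:02d}" for i in range(P)]

    # gene-level parameters
    mu = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=G)
    phi = np.exp(
        rng.uniform(
            np.log(config.nb_dispersion_range[0]),
            np.log(config.nb_dispersion_range[1]),
            size=G,
        )
    )
    tau = rng.uniform(*config.random_intercept_sd_range, size=G)

    # effect-set memberships: CBT genes, CTG genes, extra response genes;
    # the reversal genes are the first part of the CTG set and also belong
    # to the response set with the opposite sign
    idx = rng.permutation(G)
    n_extra_resp = config.n_response_genes - config.n_reversal_genes
    cbt_idx = idx[: config.n_cbt_genes]
    ctg_idx = idx[config.n_cbt_genes : config.n_cbt_genes + config.n_ctg_genes]
    rev_idx = ctg_idx[: config.n_reversal_genes]
    extra_resp_idx = idx[
        config.n_cbt_genes
        + config.n_ctg_genes : config.n_cbt_genes
        + config.n_ctg_genes
        + n_extra_resp
    ]

    delta = np.zeros(G)
    delta[cbt_idx] = _signed_uniform(rng, *config.cbt_log2fc_range, len(cbt_idx))
    gamma = np.zeros(G)
    gamma[ctg_idx] = _signed_uniform(rng, *config.ctg_log2fc_per100_range, len(ctg_idx))
    rho = np.zeros(G)
    rho[extra_resp_idx] = _signed_uniform(
        rng, *config.response_log2fc_range, len(extra_resp_idx)
    )
    # reversal planting: response effect strictly opposite in sign to the
    # repeat-length effect
    rev_mag = rng.uniform(*config.response_log2fc_range, size=len(rev_idx))
    rho[rev_idx] = -np.sign(gamma[rev_idx]) * rev_mag

    # patient-level parameters
    ctg = np.exp(
        rng.uniform(np.log(config.ctg_range[0]), np.log(config.ctg_range[1]), size=P)
    ).round().astype(int)
    latent = rng.uniform(*config.response_range, size=P)
    u = rng.normal(0.0, 1.0, size=(G, P)) * tau[:, None]

    # expected counts; the library size sets the expected depth at the
    # cohort's baseline composition
    lib = rng.lognormal(
        config.libsize_log_mean + np.log(config.libsize_scale),
        config.libsize_log_sd,
        size=2 * P,
    )
    base_total = np.sum(2.0**mu)
    eta0 = mu[:, None] + u + gamma[:, None] * (ctg / 100.0)[None, :]
    eta1 = eta0 + delta[:, None] + rho[:, None] * latent[None, :]

    counts = np.empty((G, 2 * P), dtype=np.int64)
    sample_rows = []
    for p in range(P):
        for k, (tp, eta) in enumerate((("T0", eta0), ("T10M", eta1))):
            s = 2 * p + k
            mean = 2.0 ** eta[:, p] / base_total * lib[s]
            counts[:, s] = _nb_counts(rng, mean, phi)
            sample_rows.append(
                {
                    "sample_id": f"{patient_ids[p]}_{tp}",
                    "patient_id": patient_ids[p],
                    "timepoint": tp,
                    "ctg_length": int(ctg[p]),
                }
            )
    samples = pd.DataFrame(sample_rows)

    # clinical outcome panel: oriented change = loading * latent + noise,
    # written back as two timepoint levels on each instrument's own scale;
    # the final instrument is the pure-noise control (resting activity)
    M = config.n_measures
    loadings = rng.uniform(*config.measure_loading_range, size=M)
    orientations = np.ones(M + 1, dtype=int)
    lower_better = rng.choice(M, size=config.n_lower_is_better, replace=False)
    orientations[lower_better] = -1
    scale_units = np.exp(rng.normal(1.0, 0.8, size=M + 1))
    measure_ids = [f"M{m:02d}" for m in range(M)] + ["M_CTRL"]

    outcome_rows = []
    for m in range(M + 1):
        is_control = m == M
        base = rng.normal(50.0, 10.0, size=P)
        if is_control:
            oriented = rng.normal(0.0, config.measure_noise_sd, size=P)
        else:
            oriented = loadings[m] * latent + rng.normal(
                0.0, config.measure_noise_sd, size=P
            )
        raw_delta = orientations[m] * oriented * scale_units[m]
        for p in range(P):
            outcome_rows.append(
                (patient_ids[p], measure_ids[m], "T0", base[p] * scale_units[m])
            )
            outcome_rows.append(
                (
                    patient_ids[p],
                    measure_ids[m],
                    "T10M",
                    base[p] * scale_units[m] + raw_delta[p],
                )
            )
    outcomes = pd.DataFrame(
        outcome_rows, columns=["patient_id", "measure_id", "timepoint", "value"]
    )
    measures = pd.DataFrame(
        {
            "measure_id": measure_ids,
            "orientation": orientations,
            "is_control": [0] * M + [1],
        }
    )

    truth = CohortTruth(
        config=config,
        gene_ids=gene_ids,
        patient_ids=patient_ids,
        baseline_log2_mean=mu,
        cbt_effect=delta,
        ctg_effect_per100=gamma,
        response_effect=rho,
        dispersion=phi,
        random_intercept_sd=tau,
        ctg_length=ctg,
        latent_response=latent,
        random_intercepts=u,
        cbt_set=[gene_ids[i] for i in sorted(cbt_idx)],
        ctg_set=[gene_ids[i] for i in sorted(ctg_idx)],
        response_set=[gene_ids[i] for i in sorted(np.r_[rev_idx, extra_resp_idx].astype(int))],
        reversal_set=[gene_ids[i] for i in sorted(rev_idx)],
    )
    cm = CountMatrix(gene_ids, list(samples["sample_id"]), counts)
    return cm, samples, outcomes, measures, truth


def generate_external_cohort(
    truth: CohortTruth, n_cases: int, n_controls: int, seed: int
) -> ExternalCohort:
    """Independent unpaired case/control cohort sharing the gene truth.

    Cases carry repeat-length shifts ``gamma_g * CTG/100`` with their own
    repeat lengths drawn from the configured range; controls sit at the
    baseline means.  Returns normalized log counts (logCPM).
    """
    if n_cases < 2 or n_controls < 2:
        raise ValueError("need at least two cases and two controls")
    cfg = truth.config
    rng = np.random.default_rng(seed)
    G = len(truth.gene_ids)
    n = n_cases + n_controls

    ctg = np.exp(
        rng.uniform(np.log(cfg.ctg_range[0]), np.log(cfg.ctg_range[1]), size=n_cases)
    )
    lib = rng.lognormal(
        cfg.libsize_log_mean + np.log(cfg.libsize_scale), cfg.libsize_log_sd, size=n
    )
    base_total = np.sum(2.0**truth.baseline_log2_mean)

    eta = np.tile(truth.baseline_log2_mean[:, None], (1, n))
    eta[:, :n_cases] += truth.ctg_effect_per100[:, None] * (ctg / 100.0)[None, :]
    mean = 2.0**eta / base_total * lib[None, :]
    counts = _nb_counts(rng, mean, truth.dispersion[:, None])

    colsum = counts.sum(axis=0).astype(float)
    logcpm = np.log2((counts + 0.5) / (colsum + 1.0)[None, :] * 1e6)
    labels = ["case"] * n_cases + ["control"] * n_controls
    return ExternalCohort(list(truth.gene_ids), logcpm, labels)


@dataclass
class SamplingConfig:
    """Rules of the stratified patient-sampling procedure."""

    baseline_cols: tuple[str, ...] = ("dm1activ_t0", "sixmwt_t0", "ctg_length")
    delta_col: str = "delta_dm1activ"
    site_col: str = "site"
    missing_col: str = "missing_fraction"
    variant_col: str = "variant_repeat"
    max_missing_fraction: float = 0.2
    max_per_delta: int = 2
    n_target: int = 30


def sample_patients(
    candidates: pd.DataFrame, config: SamplingConfig, seed: int
) -> tuple[list[str], dict[str, int]]:
    """Replay of the trial's stratified sampling with audit trail.

    Filters, in order: completeness (missing fraction below the cap),
    variant-repeat exclusion, then a per-variable window of one
    interquartile range around the mean for each baseline variable.
    Survivors are drawn site-stratified in random order, capping the number
    of candidates that share the same response delta.  Returns the selected
    patient ids and the counts surviving each step.
    """
    c = config
    audit: dict[str, int] = {"candidates": len(candidates)}
    df = candidates.copy()
    for col in (*c.baseline_cols, c.delta_col):
        if df[col].isna().any():
            raise ValueError(f"missing values in filter column '{col}'")

    if c.missing_col in df.columns:
        df = df[df[c.missing_col] < c.max_missing_fraction]
    audit["after_completeness"] = len(df)
    if c.variant_col in df.columns:
        df = df[~df[c.variant_col].astype(bool)]
    audit["after_variant_exclusion"] = len(df)

    for col in c.baseline_cols:
        x = df[col].to_numpy(dtype=float)
        if len(x) == 0:
            break
        iqr = float(np.percentile(x, 75) - np.percentile(x, 25))
        center = float(np.mean(x))
        df = df[(df[col] >= center - iqr) & (df[col] <= center + iqr)]
        audit[f"after_iqr_{col}"] = len(df)

    if len(df) == 0:
        raise ValueError("no eligible patients after filtering")

    rng = np.random.default_rng(seed)
    selected: list[str] = []
    delta_counts: dict[float, int] = {}
    pools = {
        site: list(rng.permutation(site_df.index.to_numpy()))
        for site, site_df in df.groupby(c.site_col)
    }
    site_order = sorted(pools)
    while len(selected) < c.n_target and any(pools.values()):
        for site in site_order:
            if len(selected) >= c.n_target:
                break
            pool = pools[site]
            while pool:
                i = pool.pop()
                d = float(df.loc[i, c.delta_col])
                if delta_counts.get(d, 0) < c.max_per_delta:
                    delta_counts[d] = delta_counts.get(d, 0) + 1
                    selected.append(str(df.loc[i, "patient_id"]))
                    break
    audit["selected"] = len(selected)
    return selected, audit
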