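"""Compound therapy-response scoring from a multi-instrument outcome panel.

Each clinical instrument is measured at baseline (T0) and after ten months
of therapy (T10M).  Per patient and instrument the change is oriented so
that positive always means improvement (instruments where lower is better
carry orientation -1), each instrument's change column is scaled by its
uncentered root mean square (n-1 denominator) to equalise units, and the
compound response score is the per-patient mean of the scaled changes.
A flagged control instrument (resting activity) never enters the score.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "oriented_deltas",
    "scale_rms",
    "compound_response",
    "compute_scores",
]


def oriented_deltas(
    outcomes: pd.DataFrame, measures: pd.DataFrame
) -> pd.DataFrame:
    """Patient x measure matrix of orientation * (T10M - T0).

    ``outcomes`` holds rows (patient_id, measure_id, timepoint, value);
    ``measures`` holds (measure_id, orientation, is_control).  Control
    measures are dropped; a (patient, measure) pair missing either
    timepoint yields a missing delta.
    """
    known = set(measures["measure_id"].astype(str))
    seen = set(outcomes["measure_id"].astype(str))
    unknown = sorted(seen - known)
    if unknown:
        raise ValueError(f"measure(s) without metadata: {unknown}")
    dup = outcomes.duplicated(["patient_id", "measure_id", "timepoint"])
    if dup.any():
        rows = outcomes[dup][["patient_id", "measure_id", "timepoint"]]
        raise ValueError(f"duplicate outcome rows:\n{rows.to_string(index=False)}")

    wide = outcomes.pivot(
        index=["patient_id", "measure_id"], columns="timepoint", values="value"
    )
    for tp in ("T0", "T10M"):
        if tp not in wide.columns:
            wide[tp] = np.nan
    delta = (wide["T10M"] - wide["T0"]).unstack("measure_id")

    meta = measures.set_index(measures["measure_id"].astype(str))
    keep = [m for m in delta.columns if not bool(meta.loc[str(m), "is_control"])]
    delta = delta[keep]
    orient = np.array([meta.loc[str(m), "orientation"] for m in delta.columns], float)
    return delta * orient[None, :]


def scale_rms(column: pd.Series | np.ndarray) -> np.ndarray:
    """Divide by the uncentered root mean square (n-1 denominator).

    Missing values are ignored for the RMS and stay missing in the output.
    """
    x = np.asarray(column, dtype=float)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least two non-missing values to scale")
    rms = np.sqrt(np.nansum(x[mask] ** 2) / (n - 1))
    if rms == 0:
        raise ValueError("all-zero column cannot be scaled")
    out = np.where(mask, x / rms, np.nan)
    return out


def compound_response(scaled: pd.DataFrame) -> pd.DataFrame:
    """Per-patient mean of non-missing scaled deltas.

    Returns a table (patient_id, compound_response, n_measures_used);
    a patient with no usable measure raises.
    """
    n_used = scaled.notna().sum(axis=1)
    empty = list(n_used[n_used == 0].index.astype(str))
    if empty:
        raise ValueError(f"patient(s) with no usable outcome measure: {empty}")
    return pd.DataFrame(
        {
            "patient_id": scaled.index.astype(str),
            "compound_response": scaled.mean(axis=1, skipna=True).to_numpy(),
            "n_measures_used": n_used.to_numpy(),
        }
    )


def compute_scores(
    outcomes: pd.DataFrame, measures: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full scoring pipeline: orient, scale, average.

    Returns (response scores, the scaled delta matrix kept for audit).
    """
    delta = oriented_deltas(outcomes, measures)
    scaled = delta.copy()
    for col in scaled.columns:
        try:
            scaled[col] = scale_rms(scaled[col])
        except ValueError as err:
            raise ValueError(f"measure '{col}': {err}") from err
    return compound_response(scaled), scaled
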