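"""Post-fit diagnostics: clinical ADA classification versus decoded states.

The clinical rule classifies a subject as ADA positive when at least
one assay measurement exceeds the 2.4 U/mL threshold; positives are
further split into persistent and transient producers.  The decoded
hidden-state sequences give the model-side analogue (ever in
``S_ADA``, first entry time), and the two are compared subject by
subject — in particular the mean time to the first clinically positive
measurement versus the mean model-predicted first time in ``S_ADA``,
where the model is expected to call ADA production earlier than the
assay detects it.

``distribution_check`` supports the posterior-predictive comparison of
observed versus simulated variable distributions over time bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import S_ADA

CLINICAL_THRESHOLD = 2.4  # U/mL


def fraction_positive_records(ada_values, threshold: float = CLINICAL_THRESHOLD) -> float:
    """Share of ADA records above the clinical threshold — the
    empirical per-record positivity rate, the natural prior expectation
    for the NOADA->ADA transition probability."""
    v = np.asarray(ada_values, dtype=float)
    v = v[~np.isnan(v)]
    if v.size == 0:
        raise ValueError("no ADA values supplied")
    return float((v > threshold).sum() / v.size)


def classify_clinical(dataset: pd.DataFrame, threshold: float = CLINICAL_THRESHOLD) -> pd.DataFrame:
    """Per-subject clinical ADA classification from the long dataset.

    A subject is ``ever_positive`` when any ADA record (``dvid`` = 2)
    exceeds ``threshold``.  Positives whose last two or more ADA records
    are all below the threshold are labelled ``transient``, the rest
    ``persistent`` — a codified stand-in for individual profile
    inspection.  Subjects without ADA records are omitted.
    """
    obs = dataset[(dataset["evid"] == 0) & (dataset["dvid"] == 2)].sort_values("time")
    rows = []
    for sid, g in obs.groupby("subject_id", sort=True):
        v = g["dv"].to_numpy(dtype=float)
        t = g["time"].to_numpy(dtype=float)
        pos = v > threshold
        ever = bool(pos.any())
        first_t = float(t[pos][0]) if ever else np.nan
        label = ""
        if ever:
            tail_neg = 0
            for x in v[::-1]:
                if x > threshold:
                    break
                tail_neg += 1
            label = "transient" if tail_neg >= 2 else "persistent"
        rows.append((sid, ever, first_t, label))
    return pd.DataFrame(
        rows, columns=["subject_id", "ever_positive", "first_positive_time", "producer_type"]
    )


def summarize_paths(paths: dict) -> pd.DataFrame:
    """Per-subject summary of decoded state sequences.

    ``paths`` maps subject id to ``(times, states)`` arrays.  Returns
    ``ever_in_s_ada``, the first record time decoded in ``S_ADA`` (NaN
    when never) and the fraction of records in ``S_ADA``.
    """
    rows = []
    for sid, (times, states) in paths.items():
        times = np.asarray(times, dtype=float)
        states = np.asarray(states, dtype=int)
        if times.shape != states.shape:
            raise ValueError(f"subject {sid}: times and states differ in length")
        in_ada = states == S_ADA
        ever = bool(in_ada.any())
        first_t = float(times[in_ada][0]) if ever else np.nan
        rows.append((sid, ever, first_t, float(in_ada.mean())))
    return pd.DataFrame(
        rows, columns=["subject_id", "ever_in_s_ada", "first_s_ada_time", "fraction_in_s_ada"]
    )


def compare_times(clinical: pd.DataFrame, states: pd.DataFrame) -> dict:
    """Compare assay-detection times with model-predicted onset times.

    Over the subjects that are clinically ever positive (and present in
    both summaries), computes the mean time to the first positive
    measurement, the mean first decoded time in ``S_ADA`` (among those
    subjects with a decoded entry) and the per-subject paired
    differences ``first_s_ada_time - first_positive_time``.
    """
    merged = clinical.merge(states, on="subject_id", how="inner")
    pos = merged[merged["ever_positive"]]
    if pos.empty:
        return {
            "n_positive": 0,
            "mean_first_positive_time": np.nan,
            "mean_first_s_ada_time": np.nan,
            "mean_paired_difference": np.nan,
            "paired_differences": {},
        }
    diffs = (pos["first_s_ada_time"] - pos["first_positive_time"]).dropna()
    return {
        "n_positive": int(len(pos)),
        "mean_first_positive_time": float(pos["first_positive_time"].mean()),
        "mean_first_s_ada_time": float(pos["first_s_ada_time"].dropna().mean()),
        "mean_paired_difference": float(diffs.mean()) if len(diffs) else np.nan,
        "paired_differences": dict(
            zip(pos.loc[diffs.index, "subject_id"], diffs.astype(float))
        ),
    }


def distribution_check(
    observed: pd.DataFrame,
    simulated: pd.DataFrame,
    value_col: str,
    bin_days: float = 28.0,
    percentiles=(5.0, 50.0, 95.0),
) -> pd.DataFrame:
    """Observed versus simulated percentiles per time bin.

    ``observed`` needs columns ``time`` and ``value_col``; ``simulated``
    additionally ``replicate``.  For each bin the observed percentiles
    are reported next to the 5th/95th envelope (across replicates) of
    each simulated percentile.  Empty bins are dropped with a warning.
    """
    if simulated["replicate"].nunique() < 1:
        raise ValueError("at least one simulated replicate required")
    edges = np.arange(
        0.0, max(observed["time"].max(), simulated["time"].max()) + bin_days, bin_days
    )
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        obs = observed.loc[
            (observed["time"] >= lo) & (observed["time"] < hi), value_col
        ].dropna()
        sim = simulated[(simulated["time"] >= lo) & (simulated["time"] < hi)]
        if obs.empty or sim.empty:
            warnings.warn(f"time bin [{lo}, {hi}) is empty; dropped", UserWarning, stacklevel=2)
            continue
        rec = {"bin_start": lo, "bin_end": hi, "n_observed": int(len(obs))}
        per_rep = sim.groupby("replicate")[value_col]
        for q in percentiles:
            rec[f"obs_p{q:g}"] = float(np.percentile(obs, q))
            rep_q = per_rep.quantile(q / 100.0)
            rec[f"sim_p{q:g}_lo"] = float(np.percentile(rep_q, 5.0))
            rec[f"sim_p{q:g}_med"] = float(np.percentile(rep_q, 50.0))
            rec[f"sim_p{q:g}_hi"] = float(np.percentile(rep_q, 95.0))
        rows.append(rec)
    return pd.DataFrame(rows)


def decoding_agreement(true_ever: np.ndarray, decoded_ever: np.ndarray) -> float:
    """Balanced accuracy of decoded ever-in-``S_ADA`` against truth."""
    from sklearn.metrics import balanced_accuracy_score

    return float(balanced_accuracy_score(np.asarray(true_ever, bool), np.asarray(decoded_ever, bool)))
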