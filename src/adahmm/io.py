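"""Long-format dataset reading and writing.

The on-disk format is a NONMEM-style long CSV with one row per
subject-time-event: ``evid`` 1 rows are dose events (``amt`` mg),
``evid`` 0 rows are observations with ``dvid`` 1 (PK concentration,
µg/mL) or 2 (ADA measurement, U/mL) and value ``dv``; ``blq`` flags
below-LOQ values, which the reader replaces by the assay limits
(0.41 µg/mL PK, 0.6 U/mL ADA).  Covariates (``weight`` kg, ``japanese``
0/1) and ``study``/``occasion`` ride along on every row.  Simultaneous
PK and ADA rows merge into a single observation record per subject and
time.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pk import ADA_LLOQ, PK_LLOQ, Observation, SubjectSeries

COLUMNS = [
    "subject_id",
    "study",
    "time",
    "evid",
    "amt",
    "dvid",
    "dv",
    "blq",
    "occasion",
    "weight",
    "japanese",
]


def write_dataset(dataset: pd.DataFrame, path) -> None:
    """Write a long-format dataset CSV (column order normalised)."""
    missing = [c for c in COLUMNS if c not in dataset.columns]
    if missing:
        raise ValueError(f"dataset lacks required column(s): {missing}")
    dataset[COLUMNS].to_csv(path, index=False)


def subjects_to_frame(subjects: list[SubjectSeries]) -> pd.DataFrame:
    """Long-format DataFrame from :class:`SubjectSeries` objects."""
    rows = []
    for s in subjects:
        for t, amt, occ in s.dose_events:
            rows.append((s.subject_id, s.study, t, 1, amt, np.nan, np.nan, 0, occ, s.weight, int(s.japanese)))
        for o in s.observations:
            occ = s.occasion_of(o.time)
            if not np.isnan(o.pk):
                rows.append((s.subject_id, s.study, o.time, 0, np.nan, 1, o.pk, int(o.pk_blq), occ, s.weight, int(s.japanese)))
            if not np.isnan(o.ada):
                rows.append((s.subject_id, s.study, o.time, 0, np.nan, 2, o.ada, int(o.ada_blq), occ, s.weight, int(s.japanese)))
    return pd.DataFrame(rows, columns=COLUMNS).sort_values(
        ["subject_id", "time", "evid", "dvid"], kind="stable", ignore_index=True
    )


def _fail(row_no: int, msg: str) -> None:
    raise ValueError(f"row {row_no}: {msg}")


def frame_to_subjects(df: pd.DataFrame) -> list[SubjectSeries]:
    """Group and validate a long-format frame into subject series.

    Simultaneous PK and ADA rows at the same time merge into one
    observation; BLQ values are replaced by the respective limits.
    Row numbers in error messages count data rows from 1.
    """
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {missing}")
    subjects = []
    df = df.copy()
    df["_row"] = np.arange(1, len(df) + 1)
    for sid, g in df.groupby("subject_id", sort=True):
        g = g.sort_values(["time", "evid"], kind="stable")
        doses = []
        obs_map: dict[float, Observation] = {}
        for _, r in g.iterrows():
            row_no = int(r["_row"])
            t = float(r["time"])
            if t < 0:
                _fail(row_no, f"negative time {t}")
            if int(r["evid"]) == 1:
                amt = float(r["amt"])
                if not amt > 0:
                    _fail(row_no, "dose row needs amt > 0")
                doses.append((t, amt, int(r["occasion"])))
                continue
            dvid = int(r["dvid"])
            if dvid not in (1, 2):
                _fail(row_no, f"unknown dvid {dvid}")
            dv = float(r["dv"])
            if np.isnan(dv):
                _fail(row_no, "observation row needs dv")
            blq = bool(int(r["blq"]))
            if blq:
                dv = PK_LLOQ if dvid == 1 else ADA_LLOQ
            o = obs_map.setdefault(t, Observation(time=t))
            if dvid == 1:
                o.pk, o.pk_blq = dv, blq
            else:
                o.ada, o.ada_blq = dv, blq
        first = g.iloc[0]
        subjects.append(
            SubjectSeries(
                subject_id=sid,
                dose_events=doses,
                observations=[obs_map[t] for t in sorted(obs_map)],
                weight=float(first["weight"]),
                japanese=bool(int(first["japanese"])),
                study=str(first["study"]),
            )
        )
    return subjects


def read_dataset(path) -> list[SubjectSeries]:
    """Read a long-format CSV into validated :class:`SubjectSeries`."""
    return frame_to_subjects(pd.read_csv(path))


def build_hmm_records(subjects: list[SubjectSeries], iwres: pd.DataFrame):
    """Merge IWRES with ADA observations into the MHMM input arrays.

    Per subject, records are the union of observation times; the PK
    component is the weighted residual (missing where flagged or no PK
    sample), the ADA component the assay value (missing where not
    measured).  Returns ``(X, lengths, index)`` with ``index`` a frame
    of ``subject_id, time`` aligned with the rows of ``X``.
    """
    iw = iwres.set_index(["subject_id", "time"])["iwres"] if len(iwres) else None
    rows, lengths, idx = [], [], []
    for s in subjects:
        n = 0
        for o in s.observations:
            y_pk = np.nan
            if not np.isnan(o.pk) and iw is not None:
                y_pk = float(iw.get((s.subject_id, o.time), np.nan))
            y_ada = o.ada
            if np.isnan(y_pk) and np.isnan(y_ada):
                continue
            rows.append((y_pk, y_ada))
            idx.append((s.subject_id, o.time))
            n += 1
        if n:
            lengths.append(n)
    X = np.asarray(rows, dtype=float)
    return X, np.asarray(lengths, dtype=int), pd.DataFrame(idx, columns=["subject_id", "time"])
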