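"""Synthetic-cohort generation for the ADA hidden-Markov pipeline.

Two layers of simulation are provided.

``sample_mhmm`` draws directly from the hidden-Markov model itself:
hidden two-state chains started in ``S_NOADA`` and bivariate Gaussian
emissions.  This is the generative model the estimator assumes and is
what parameter-recovery experiments use.

``simulate_cohort`` emulates a multi-trial certolizumab-pegol-like
programme end to end: per-study dosing designs (Q2W/Q4W subcutaneous
dosing 50-800 mg, loading-dose arms, one dense single-dose study
without ADA sampling), covariates, individual PK parameters, a hidden
ADA chain evolving over the scheduled sampling records, clearance
inflated while a subject produces ADA (so the ADA-blind PK model
over-predicts and the weighted residuals turn negative), proportional
PK assay error with a 0.41 µg/mL LLOQ, and ADA assay values drawn from
the state's Gaussian and floored at the 0.6 U/mL LLOQ.  The output is
the long-format dataset of :mod:`adahmm.io` plus a hidden-truth table,
so every pipeline stage is testable without proprietary trial data.

``simulate_observed_from_fit`` replicates the observed variables from a
fitted model over a dataset skeleton (the posterior-predictive check:
simulated ADA values below 0.6 are set to 0.6).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hmm import S_ADA, S_NOADA, EmissionParams, TransitionParams
from .pk import ADA_LLOQ, PK_LLOQ, PKModelParams, predict_concentration

# ---------------------------------------------------------------------------
# Designs


@dataclass
class StudyDesign:
    """One trial arm's design: dosing schedule and planned sampling."""

    name: str
    n_subjects: int
    dose_mg: tuple = (400.0,)  # maintenance dose arms, one drawn per subject
    interval_days: float | None = 28.0  # None = single dose
    loading_dose_mg: float | None = None  # given at days 0, 14, 28 when set
    sampling_days: tuple = (7.0, 14.0, 28.0, 56.0, 84.0)
    ada_measured: bool = True
    japanese_fraction: float = 0.1
    weight_median: float = 70.0
    weight_cv: float = 0.2

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if list(self.sampling_days) != sorted(self.sampling_days):
            raise ValueError("sampling_days must be sorted")

    def dose_schedule(self, maintenance_mg: float) -> list[tuple[float, float, int]]:
        """(time, amount, occasion) dose events covering the sampling span."""
        last = max(self.sampling_days)
        events: list[tuple[float, float]] = []
        if self.loading_dose_mg is not None:
            events += [(d, self.loading_dose_mg) for d in (0.0, 14.0, 28.0)]
            t = 28.0 + self.interval_days
        elif self.interval_days is None:
            events.append((0.0, maintenance_mg))
            t = np.inf
        else:
            t = 0.0
        while t < last:
            events.append((t, maintenance_mg))
            t += self.interval_days
        return [(td, amt, i + 1) for i, (td, amt) in enumerate(sorted(events))]


def default_designs(scale: float = 1.0) -> list[StudyDesign]:
    """A six-study mix mirroring a phase I-III RA programme (~840
    subjects at ``scale`` = 1): mixed Q4W dose-ranging, two loading-dose
    Q2W studies, fixed-dose Q4W studies, and a dense single-dose phase I
    study without ADA sampling."""

    def n(x):
        return max(1, round(x * scale))

    return [
        StudyDesign(
            "STUDY-A",
            n(239),
            dose_mg=(50.0, 100.0, 200.0, 400.0, 600.0, 800.0),
            interval_days=28.0,
            sampling_days=(0.0, 7.0, 14.0, 28.0, 35.0, 42.0, 56.0, 63.0, 70.0, 84.0),
        ),
        StudyDesign(
            "STUDY-B",
            n(116),
            dose_mg=(200.0,),
            interval_days=14.0,
            loading_dose_mg=400.0,
            sampling_days=(7.0, 14.0, 28.0, 42.0, 56.0, 84.0, 112.0),
        ),
        StudyDesign(
            "STUDY-C",
            n(111),
            dose_mg=(400.0,),
            interval_days=28.0,
            sampling_days=(7.0, 14.0, 28.0, 56.0, 84.0, 112.0, 140.0, 147.0, 154.0, 168.0),
        ),
        StudyDesign(
            "STUDY-D",
            n(124),
            dose_mg=(400.0,),
            interval_days=28.0,
            sampling_days=(7.0, 14.0, 28.0, 56.0, 84.0, 112.0, 140.0, 168.0),
        ),
        StudyDesign(
            "STUDY-E",
            n(239),
            dose_mg=(100.0, 200.0, 400.0),
            interval_days=14.0,
            loading_dose_mg=400.0,
            sampling_days=(7.0, 14.0, 28.0, 42.0, 56.0, 84.0, 168.0),
        ),
        StudyDesign(
            "STUDY-F",
            n(16),
            dose_mg=(400.0,),
            interval_days=None,
            ada_measured=False,
            sampling_days=(0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0, 13.0, 20.0, 27.0, 34.0, 41.0, 48.0, 55.0),
        ),
    ]


@dataclass
class ADAGenerativeParams:
    """Data-generating assumptions for the hidden ADA process."""

    pi12_true: float = 0.03  # per-record S_NOADA -> S_ADA probability
    pi21_true: float = 0.003  # per-record S_ADA -> S_NOADA probability
    ada_mu_noada: float = 0.6  # U/mL, assay mode without production
    ada_mu_ada: float = 2.4  # U/mL, assay mode under production
    ada_sd: float = float(np.sqrt(1.6))  # U/mL
    cl_inflation_ada: float = 2.0  # CL/F multiplier while in S_ADA
    lloq_ada: float = ADA_LLOQ
    clinical_threshold: float = 2.4
    lognormal_ada: bool = False  # heavy-tailed assay alternative

    def __post_init__(self) -> None:
        if not (0.0 <= self.pi12_true < 1.0 and 0.0 <= self.pi21_true < 1.0):
            raise ValueError("transition probabilities must be in [0, 1)")
        if self.cl_inflation_ada < 1.0:
            raise ValueError("cl_inflation_ada must be >= 1")
        if self.clinical_threshold <= self.lloq_ada:
            raise ValueError("clinical threshold must exceed the ADA LLOQ")


# ---------------------------------------------------------------------------
# Pure-MHMM sampling


def _simulate_chains(pi12, pi21, n_subjects, n_records, rng) -> np.ndarray:
    """Hidden chains (n_subjects, n_records), all starting in S_NOADA."""
    states = np.zeros((n_subjects, n_records), dtype=int)
    u = rng.random((n_subjects, max(n_records - 1, 0)))
    for t in range(1, n_records):
        prev = states[:, t - 1]
        move = np.where(prev == S_NOADA, pi12, pi21)
        states[:, t] = np.where(u[:, t - 1] < move, 1 - prev, prev)
    return states


def sample_mhmm(
    em: EmissionParams,
    tp: TransitionParams,
    n_subjects: int,
    n_records: int,
    random_state=None,
    floor_ada: bool = False,
):
    """Draw a cohort from the hidden-Markov model itself.

    Subject-level random effects are drawn whenever the corresponding
    IIV variances in ``em``/``tp`` are positive.  Returns
    ``(X, lengths, states)`` where ``X`` is the stacked ``(pk residual,
    ADA)`` record array accepted by :class:`~adahmm.estimation.MixedHMM`
    and ``states`` the true hidden sequence per record.  With
    ``floor_ada`` the assay floor ``max(y, 0.6)`` is applied.
    """
    rng = np.random.default_rng(random_state)
    eta12 = (
        rng.normal(0.0, np.sqrt(tp.omega2_pi12), n_subjects) if tp.omega2_pi12 > 0 else 0.0
    )
    eta21 = (
        rng.normal(0.0, np.sqrt(tp.omega2_pi21), n_subjects) if tp.omega2_pi21 > 0 else 0.0
    )
    from scipy.special import expit

    pi12 = expit(tp.logit_pi12 + np.asarray(eta12))
    pi21 = expit(tp.logit_pi21 + np.asarray(eta21))
    states = _simulate_chains(
        np.broadcast_to(pi12, (n_subjects,)),
        np.broadcast_to(pi21, (n_subjects,)),
        n_subjects,
        n_records,
        rng,
    )

    shift_pk = (
        rng.normal(0.0, np.sqrt(em.omega2_mu_pkres), n_subjects)
        if em.omega2_mu_pkres > 0
        else np.zeros(n_subjects)
    )
    shift_ada = (
        rng.normal(0.0, np.sqrt(em.omega2_mu_ada), n_subjects)
        if em.omega2_mu_ada > 0
        else np.zeros(n_subjects)
    )

    mu_pk = np.where(states == S_NOADA, em.mu_pkres_noada, em.mu_pkres_ada) + shift_pk[:, None]
    mu_ada = np.where(states == S_NOADA, em.mu_ada_noada, em.mu_ada_ada) + shift_ada[:, None]
    rho = np.where(states == S_NOADA, em.rho_noada, em.rho_ada)
    s1 = np.sqrt(em.sigma2_pkres)
    s2 = np.sqrt(em.sigma2_ada)

    z1 = rng.standard_normal(states.shape)
    z2 = rng.standard_normal(states.shape)
    y_pk = mu_pk + s1 * z1
    y_ada = mu_ada + s2 * (rho * z1 + np.sqrt(1.0 - rho**2) * z2)
    if floor_ada:
        y_ada = np.maximum(y_ada, ADA_LLOQ)

    X = np.stack([y_pk.ravel(), y_ada.ravel()], axis=1)
    lengths = np.full(n_subjects, n_records, dtype=int)
    return X, lengths, states.ravel()


# ---------------------------------------------------------------------------
# Full cohort simulation (long format)


def simulate_cohort(
    designs: list[StudyDesign] | None = None,
    pk: PKModelParams | None = None,
    ada: ADAGenerativeParams | None = None,
    seed=0,
):
    """Simulate a multi-study cohort into the long-format dataset.

    Returns ``(dataset, truth)``: the long-format DataFrame (see
    :mod:`adahmm.io`) and a hidden-truth table with one row per sampling
    record (``subject_id, time, state``) plus the individual PK
    parameters.  Reproducible: the same seed yields an identical
    dataset; per-subject sub-streams are derived deterministically.
    """
    designs = designs if designs is not None else default_designs()
    pk = pk or PKModelParams()
    ada = ada or ADAGenerativeParams()
    root = np.random.SeedSequence(seed)
    rows = []
    truth_rows = []
    sid_counter = 0
    for design, ss in zip(designs, root.spawn(len(designs))):
        streams = ss.spawn(design.n_subjects)
        for j in range(design.n_subjects):
            rng = np.random.default_rng(streams[j])
            sid_counter += 1
            sid = f"{design.name}-{sid_counter:04d}"
            wt = float(
                np.exp(rng.normal(np.log(design.weight_median), design.weight_cv))
            )
            jp = bool(rng.random() < design.japanese_fraction)
            maintenance = float(rng.choice(design.dose_mg))
            doses = design.dose_schedule(maintenance)

            cl_i = pk.typical_cl(wt, jp) * np.exp(rng.normal(0.0, np.sqrt(pk.omega2_cl)))
            v_i = pk.typical_v(jp) * np.exp(rng.normal(0.0, np.sqrt(pk.omega2_v)))

            for t_d, amt, occ in doses:
                rows.append((sid, design.name, t_d, 1, amt, np.nan, np.nan, 0, occ, wt, int(jp)))

            days = np.asarray(design.sampling_days, dtype=float)
            n_rec = len(days)
            state = S_NOADA
            for k, t in enumerate(days):
                if k > 0:
                    move = ada.pi12_true if state == S_NOADA else ada.pi21_true
                    if rng.random() < move:
                        state = 1 - state
                truth_rows.append((sid, t, state, cl_i, v_i))
                occ = max(1, int(np.searchsorted([d[0] for d in doses], t, side="right")))

                cl_now = cl_i * (ada.cl_inflation_ada if state == S_ADA else 1.0)
                conc = predict_concentration(pk, (cl_now, v_i), doses, t)
                if conc > 0:  # pre-first-dose samples carry no PK observation
                    obs = conc * (1.0 + rng.normal(0.0, pk.sigma_prop))
                    if obs < PK_LLOQ:
                        rows.append((sid, design.name, t, 0, np.nan, 1, PK_LLOQ, 1, occ, wt, int(jp)))
                    else:
                        rows.append((sid, design.name, t, 0, np.nan, 1, obs, 0, occ, wt, int(jp)))

                if design.ada_measured:
                    mu = ada.ada_mu_noada if state == S_NOADA else ada.ada_mu_ada
                    if ada.lognormal_ada:
                        val = float(
                            np.exp(rng.normal(np.log(mu), ada.ada_sd / mu))
                        )
                    else:
                        val = float(rng.normal(mu, ada.ada_sd))
                    if val < ada.lloq_ada:
                        rows.append(
                            (sid, design.name, t, 0, np.nan, 2, ada.lloq_ada, 1, occ, wt, int(jp))
                        )
                    else:
                        rows.append((sid, design.name, t, 0, np.nan, 2, val, 0, occ, wt, int(jp)))

    dataset = pd.DataFrame(
        rows,
        columns=[
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
        ],
    ).sort_values(["subject_id", "time", "evid", "dvid"], kind="stable", ignore_index=True)
    truth = pd.DataFrame(
        truth_rows, columns=["subject_id", "time", "state", "cl_i", "v_i"]
    )
    return dataset, truth


# ---------------------------------------------------------------------------
# Posterior-predictive simulation from a fitted model


def simulate_observed_from_fit(
    em: EmissionParams,
    tp: TransitionParams,
    lengths,
    n_sim: int = 100,
    seed=0,
    times=None,
) -> pd.DataFrame:
    """Replicate the observed variables from fitted MHMM parameters.

    ``lengths`` gives the number of records per subject (the skeleton);
    ``times`` optionally the record times, concatenated like the rows of
    a fit dataset.  Simulated ADA measurements below 0.6 U/mL are set to
    0.6 (assay LOQ rule).  Returns a long table with columns
    ``replicate, subject, record, time, y_pkres, y_ada``.
    """
    lengths = np.asarray(lengths, dtype=int)
    n_subj = len(lengths)
    rng = np.random.default_rng(seed)
    frames = []
    rec_idx = np.concatenate([np.arange(L) for L in lengths])
    subj_idx = np.repeat(np.arange(n_subj), lengths)
    if times is None:
        times = rec_idx.astype(float)
    times = np.asarray(times, dtype=float)
    Tmax = int(lengths.max())
    for r in range(n_sim):
        X, _, _ = sample_mhmm(
            em, tp, n_subj, Tmax, random_state=rng, floor_ada=True
        )
        Xr = X.reshape(n_subj, Tmax, 2)
        y = Xr[subj_idx, rec_idx]
        frames.append(
            pd.DataFrame(
                {
                    "replicate": r,
                    "subject": subj_idx,
                    "record": rec_idx,
                    "time": times,
                    "y_pkres": y[:, 0],
                    "y_ada": y[:, 1],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
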