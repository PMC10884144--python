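"""One-compartment population-PK stage producing weighted residuals.

The drug (a subcutaneously dosed PEGylated antibody fragment with a
half-life of roughly two weeks) is described by a one-compartment model
with first-order absorption and first-order elimination, parameterised
by apparent clearance CL/F, apparent central volume V/F and a single
absorption rate constant ka.  Covariates enter as standard
pharmacometric forms: a power of body weight (reference 70 kg) on CL/F
and proportional Japanese-ethnicity shifts on CL/F and V/F.
Inter-individual variability is log-normal on CL/F and V/F and the
residual error is proportional.

The model is fitted to first-dosing-occasion data only — patients are
drug-naive there, so anti-drug antibodies cannot yet have altered the
disposition — by maximising a Laplace-approximated marginal likelihood.
Empirical-Bayes individual parameters from that fit then predict all
later occasions, and the individually weighted residuals

    IWRES = (DV - IPRED) / (sigma * IPRED)

become the first observed variable of the downstream hidden-Markov
model: near zero with unit spread while the model holds, systematically
negative once ADA accelerate clearance and the ADA-blind model starts
over-predicting.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from sklearn.base import BaseEstimator, TransformerMixin

PK_LLOQ = 0.41  # µg/mL
ADA_LLOQ = 0.6  # U/mL
REFERENCE_WEIGHT = 70.0  # kg

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Domain types


@dataclass
class PKModelParams:
    """Population parameters of the one-compartment covariate model."""

    cl_pop: float = 0.35  # L/day, apparent clearance at 70 kg, non-Japanese
    v_pop: float = 7.0  # L, apparent central volume
    ka: float = 0.35  # 1/day, first-order absorption rate
    theta_wt_cl: float = 0.75  # power of (weight/70) on CL/F
    theta_jp_cl: float = -0.15  # proportional Japanese effect on CL/F
    theta_jp_v: float = -0.15  # proportional Japanese effect on V/F
    omega2_cl: float = 0.09  # IIV variance of log CL/F
    omega2_v: float = 0.09  # IIV variance of log V/F
    sigma_prop: float = 0.15  # proportional residual SD

    def __post_init__(self) -> None:
        if min(self.cl_pop, self.v_pop, self.ka) <= 0:
            raise ValueError("cl_pop, v_pop and ka must be positive")
        if self.omega2_cl < 0 or self.omega2_v < 0:
            raise ValueError("IIV variances must be non-negative")
        if self.sigma_prop <= 0:
            raise ValueError("sigma_prop must be positive")

    def typical_cl(self, weight: float, japanese) -> float:
        return (
            self.cl_pop
            * (weight / REFERENCE_WEIGHT) ** self.theta_wt_cl
            * (1.0 + self.theta_jp_cl * float(japanese))
        )

    def typical_v(self, japanese) -> float:
        return self.v_pop * (1.0 + self.theta_jp_v * float(japanese))


@dataclass
class Observation:
    """One sampling record; ``nan`` marks an absent measurement."""

    time: float
    pk: float = np.nan
    ada: float = np.nan
    pk_blq: bool = False
    ada_blq: bool = False


@dataclass
class SubjectSeries:
    """One subject's dose history, observations and covariates.

    ``dose_events`` are ``(time_days, amount_mg, occasion)`` with
    occasions starting at 1; observation times must be non-decreasing
    and every observation must carry at least one measurement.
    """

    subject_id: str
    dose_events: list = field(default_factory=list)
    observations: list = field(default_factory=list)
    weight: float = REFERENCE_WEIGHT
    japanese: bool = False
    study: str = ""

    def __post_init__(self) -> None:
        times = [o.time for o in self.observations]
        if any(b > a for a, b in zip(times[1:], times)):
            raise ValueError(f"subject {self.subject_id}: observation times decrease")
        for o in self.observations:
            if np.isnan(o.pk) and np.isnan(o.ada):
                raise ValueError(
                    f"subject {self.subject_id}: observation at t={o.time} has no value"
                )

    @property
    def dose_times(self) -> list[float]:
        return sorted({t for t, _, _ in self.dose_events})

    def first_occasion_cutoff(self) -> float:
        """Time of the second distinct dose; occasion 1 is everything
        strictly before it (a single-dose subject is entirely occasion 1)."""
        dt = self.dose_times
        return dt[1] if len(dt) > 1 else np.inf

    def occasion_of(self, t: float) -> int:
        """1-based index of the latest dose at or before ``t`` (1 for
        pre-first-dose samples)."""
        dt = self.dose_times
        return max(1, int(np.searchsorted(np.asarray(dt), t, side="right")))


@dataclass
class EBESet:
    """Empirical-Bayes individual parameters, one row per subject."""

    table: pd.DataFrame  # columns: subject_id, cl_i, v_i, eta_cl, eta_v

    def lookup(self, subject_id) -> tuple[float, float]:
        row = self.table.loc[self.table["subject_id"] == subject_id]
        if row.empty:
            raise KeyError(subject_id)
        return float(row["cl_i"].iloc[0]), float(row["v_i"].iloc[0])


# ---------------------------------------------------------------------------
# Concentration prediction


def predict_concentration(params: PKModelParams, individual, dose_events, t):
    """Concentration (µg/mL) under first-order absorption superposition.

    ``individual`` is ``(cl_i, v_i)`` on the natural scale; all doses
    with event time <= t contribute.  The flip-flop degenerate case
    ka == CL/V uses the analytic limit ``D*ka*tau*exp(-ka*tau)/V``.
    """
    cl_i, v_i = individual
    if cl_i <= 0 or v_i <= 0:
        raise ValueError("individual CL and V must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    ka = params.ka
    ke = cl_i / v_i
    c = np.zeros_like(t, dtype=float)
    for ev in dose_events:
        td, amt = ev[0], ev[1]
        tau = t - td
        on = tau >= 0
        tau = np.where(on, tau, 0.0)
        if abs(ka - ke) < 1e-10 * ka:
            term = amt * ka * tau * np.exp(-ka * tau) / v_i
        else:
            term = amt * ka / (v_i * (ka - ke)) * (np.exp(-ke * tau) - np.exp(-ka * tau))
        c += np.where(on, term, 0.0)
    return c if c.ndim else float(c)


def _conc_batch(cl, v, ka, dose_t, dose_a, dmask, tobs):
    """Vectorised superposition: subjects stacked on axis 0.

    cl, v: (n,); dose_t/dose_a/dmask: (n, k); tobs: (n, m) -> (n, m).
    """
    ke = (cl / v)[:, None, None]
    v3 = v[:, None, None]
    tau = tobs[:, None, :] - dose_t[:, :, None]
    on = (tau >= 0) & dmask[:, :, None]
    tau = np.where(on, tau, 0.0)
    amt = dose_a[:, :, None]
    flip = np.abs(ka - ke) < 1e-10 * ka
    denom = np.where(flip, 1.0, ka - ke)
    normal = amt * ka / (v3 * denom) * (np.exp(-ke * tau) - np.exp(-ka * tau))
    limit = amt * ka * tau * np.exp(-ka * tau) / v3
    return np.where(on, np.where(flip, limit, normal), 0.0).sum(axis=1)


# ---------------------------------------------------------------------------
# Fit data (padded arrays)


class _PKFitData:
    """Occasion-1 PK observations padded across subjects.

    Pre-first-dose samples (individual prediction exactly zero under the
    model) carry no information under a proportional error and are
    dropped here.
    """

    def __init__(self, subjects, occasion1_only: bool = True):
        kept, self.excluded = [], []
        rows = []
        for s in subjects:
            cutoff = s.first_occasion_cutoff() if occasion1_only else np.inf
            first_dose = s.dose_times[0] if s.dose_times else np.inf
            obs = [
                o
                for o in s.observations
                if not np.isnan(o.pk) and o.time < cutoff and o.time > first_dose
            ]
            if not obs:
                self.excluded.append(s.subject_id)
                continue
            doses = [(t, a) for t, a, *_ in s.dose_events if t < cutoff]
            rows.append((s, obs, doses))
            kept.append(s.subject_id)
        if not rows:
            raise ValueError("no subjects with usable occasion-1 PK data")
        self.ids = kept
        n = len(rows)
        m = max(len(obs) for _, obs, _ in rows)
        k = max(len(d) for _, _, d in rows)
        self.tobs = np.zeros((n, m))
        self.y = np.ones((n, m))
        self.omask = np.zeros((n, m), dtype=bool)
        self.dose_t = np.zeros((n, k))
        self.dose_a = np.zeros((n, k))
        self.dmask = np.zeros((n, k), dtype=bool)
        self.wt = np.empty(n)
        self.jp = np.empty(n)
        for i, (s, obs, doses) in enumerate(rows):
            self.tobs[i, : len(obs)] = [o.time for o in obs]
            self.y[i, : len(obs)] = [o.pk for o in obs]
            self.omask[i, : len(obs)] = True
            self.dose_t[i, : len(doses)] = [t for t, _ in doses]
            self.dose_a[i, : len(doses)] = [a for _, a in doses]
            self.dmask[i, : len(doses)] = True
            self.wt[i] = s.weight
            self.jp[i] = float(s.japanese)
        self.n = n


def _neg_joint(data: _PKFitData, p: PKModelParams, eta: np.ndarray) -> np.ndarray:
    """-(conditional log-likelihood + random-effect log prior) per subject."""
    base_cl = (
        p.cl_pop * (data.wt / REFERENCE_WEIGHT) ** p.theta_wt_cl * (1.0 + p.theta_jp_cl * data.jp)
    )
    base_v = p.v_pop * (1.0 + p.theta_jp_v * data.jp)
    eta = np.clip(eta, -40.0, 40.0)
    cl = base_cl * np.exp(eta[:, 0])
    v = base_v * np.exp(eta[:, 1])
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        f = _conc_batch(cl, v, p.ka, data.dose_t, data.dose_a, data.dmask, data.tobs)
        safe = f > 1e-300
        fs = np.where(safe, f, 1.0)
        z2 = np.where(safe, np.minimum(((data.y - f) / (p.sigma_prop * fs)) ** 2, 1e10), 1e10)
        logvar = np.where(safe, np.log(p.sigma_prop**2 * fs**2), 0.0)
        nll = 0.5 * np.sum(data.omask * (z2 + logvar + _LOG2PI), axis=1)
    for d, om2 in enumerate((p.omega2_cl, p.omega2_v)):
        if om2 > 0:
            nll += 0.5 * (eta[:, d] ** 2 / om2 + np.log(2.0 * np.pi * om2))
    return nll


def _map_etas(data, p: PKModelParams, eta0=None):
    """Vectorised damped-Newton MAP of the random effects per subject.

    Returns (eta, H, obj): the per-subject modes, the finite-difference
    Hessians of the negative joint over the active dimensions at the
    modes (None when no dimension is active), and the objective values.
    """
    idx = np.flatnonzero(np.array([p.omega2_cl, p.omega2_v]) > 0)
    d = len(idx)
    eta = np.zeros((data.n, 2)) if eta0 is None else eta0.copy()
    eta[:, [i for i in (0, 1) if i not in idx]] = 0.0
    if d == 0:
        return eta, None, _neg_joint(data, p, eta)

    h = 1e-4

    def F(e):
        return _neg_joint(data, p, e)

    def grad_hess(e):
        f0 = F(e)
        g = np.zeros((data.n, d))
        H = np.zeros((data.n, d, d))
        shifts = []
        for a_i, a in enumerate(idx):
            ea = np.zeros_like(e)
            ea[:, a] = h
            fp, fm = F(e + ea), F(e - ea)
            g[:, a_i] = (fp - fm) / (2.0 * h)
            H[:, a_i, a_i] = (fp - 2.0 * f0 + fm) / h**2
            shifts.append(ea)
        if d == 2:
            e0, e1 = shifts
            cross = (
                F(e + e0 + e1) - F(e + e0 - e1) - F(e - e0 + e1) + F(e - e0 - e1)
            ) / (4.0 * h**2)
            H[:, 0, 1] = H[:, 1, 0] = cross
        return f0, g, H

    f0 = F(eta)
    for _ in range(30):
        f0, g, H = grad_hess(eta)
        if np.max(np.abs(g)) < 1e-7:
            break
        # modified Newton: flip/floor eigenvalues so the step is always
        # a descent direction even where the joint is locally indefinite
        w, V = np.linalg.eigh(H)
        w = np.maximum(np.abs(w), 1e-8)
        step = -np.einsum("nab,nb->na", V, np.einsum("nab,na->nb", V, g) / w)
        lam = np.ones(data.n)
        for _ in range(12):
            trial = eta.copy()
            trial[:, idx] += lam[:, None] * step
            ft = F(trial)
            worse = ft > f0 + 1e-12
            if not worse.any():
                break
            lam = np.where(worse, lam / 2.0, lam)
        improved = ft <= f0 + 1e-12
        if not improved.any():
            break
        eta = np.where(improved[:, None], trial, eta)
    f0, g, H = grad_hess(eta)
    return eta, H, f0


def _laplace_loglik(data, p: PKModelParams, eta0=None):
    """Laplace-approximated marginal log-likelihood (summed) and modes."""
    eta, H, obj = _map_etas(data, p, eta0)
    if H is None:
        return float(-obj.sum()), eta
    d = H.shape[1]
    if d == 1:
        logdet = np.log(np.maximum(H[:, 0, 0], 1e-12))
    else:
        det = H[:, 0, 0] * H[:, 1, 1] - H[:, 0, 1] ** 2
        logdet = np.log(np.maximum(det, 1e-12))
    ll = -obj + 0.5 * d * _LOG2PI - 0.5 * logdet
    return float(ll.sum()), eta


# ---------------------------------------------------------------------------
# Population fit


_PK_PARAM_NAMES = (
    "cl_pop",
    "v_pop",
    "ka",
    "theta_wt_cl",
    "theta_jp_cl",
    "theta_jp_v",
    "omega2_cl",
    "omega2_v",
    "sigma_prop",
)
_PK_LOG_SCALE = {"cl_pop", "v_pop", "ka", "omega2_cl", "omega2_v", "sigma_prop"}


def fit_first_occasion(
    subjects,
    init: PKModelParams | None = None,
    fixed: tuple = (),
    max_iter: int = 300,
    tol: float = 1e-8,
):
    """Fit the population model to occasion-1 PK data by Laplace ML.

    ``fixed`` names parameters held at their ``init`` values (e.g. an
    unidentifiable covariate exponent, or IIV variances fixed to zero —
    the latter reduces the fit to pooled nonlinear least squares on the
    proportional-error log-likelihood).  Subjects without occasion-1 PK
    observations are excluded with a warning.

    Returns ``(params, info)`` where ``info`` carries ``loglik``,
    ``converged``, ``n_function_evals`` and ``excluded``.
    """
    init = init or PKModelParams()
    for f in fixed:
        if f not in _PK_PARAM_NAMES:
            raise ValueError(f"unknown parameter {f!r}")
    data = _PKFitData(subjects)
    if data.excluded:
        warnings.warn(
            f"{len(data.excluded)} subject(s) without occasion-1 PK data excluded: "
            f"{data.excluded}",
            UserWarning,
            stacklevel=2,
        )
    free = [n for n in _PK_PARAM_NAMES if n not in fixed]
    for n in ("omega2_cl", "omega2_v"):
        if n in free and getattr(init, n) == 0.0:
            free.remove(n)  # zero variance cannot move on the log scale

    def pack(p):
        return np.array(
            [np.log(getattr(p, n)) if n in _PK_LOG_SCALE else getattr(p, n) for n in free]
        )

    def unpack(x):
        if np.any(np.abs(x) > 50):
            raise OverflowError("parameter out of range")
        kw = {
            n: (float(np.exp(u)) if n in _PK_LOG_SCALE else float(u))
            for n, u in zip(free, x)
        }
        return dataclasses.replace(init, **kw)

    warm = {"eta": None}
    n_evals = [0]

    def objective(x):
        n_evals[0] += 1
        try:
            p = unpack(x)
        except (ValueError, OverflowError):
            return 1e12
        ll, eta = _laplace_loglik(data, p, warm["eta"])
        warm["eta"] = eta
        return -ll if np.isfinite(ll) else 1e12

    res = minimize(
        objective,
        pack(init),
        method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": tol},
    )
    params = unpack(res.x)
    if not res.success:
        warnings.warn(
            f"population PK fit did not converge: {res.message}", UserWarning, stacklevel=2
        )
    info = {
        "loglik": float(-res.fun),
        "converged": bool(res.success),
        "n_function_evals": n_evals[0],
        "excluded": list(data.excluded),
    }
    return params, info


def compute_ebes(params: PKModelParams, subjects) -> EBESet:
    """MAP individual (CL/F, V/F) from occasion-1 data under ``params``.

    Subjects without occasion-1 PK data (or with zero IIV) shrink fully
    to their covariate-adjusted typical values.
    """
    rows = {}
    try:
        data = _PKFitData(subjects)
    except ValueError:
        data = None
    if data is not None:
        eta, _, _ = _map_etas(data, params)
        for i, sid in enumerate(data.ids):
            base_cl = params.typical_cl(data.wt[i], data.jp[i])
            base_v = params.typical_v(data.jp[i])
            rows[sid] = (
                base_cl * np.exp(eta[i, 0]),
                base_v * np.exp(eta[i, 1]),
                eta[i, 0],
                eta[i, 1],
            )
    out = []
    for s in subjects:
        if s.subject_id in rows:
            cl_i, v_i, e1, e2 = rows[s.subject_id]
        else:
            cl_i = params.typical_cl(s.weight, s.japanese)
            v_i = params.typical_v(s.japanese)
            e1 = e2 = 0.0
        out.append((s.subject_id, cl_i, v_i, e1, e2))
    return EBESet(
        pd.DataFrame(out, columns=["subject_id", "cl_i", "v_i", "eta_cl", "eta_v"])
    )


def compute_iwres(params: PKModelParams, ebes: EBESet, subjects) -> pd.DataFrame:
    """Individually weighted residuals at every PK observation.

    Predictions use the empirical-Bayes individual parameters over all
    dosing occasions.  Records whose individual prediction is zero
    (pre-first-dose samples) have no defined residual: they are kept
    with ``iwres`` = NaN and ``flagged`` = True so the downstream model
    treats the PK component as missing.
    """
    rows = []
    for s in subjects:
        cl_i, v_i = ebes.lookup(s.subject_id)
        for o in s.observations:
            if np.isnan(o.pk):
                continue
            ipred = predict_concentration(params, (cl_i, v_i), s.dose_events, o.time)
            if ipred > 0:
                iwres = (o.pk - ipred) / (params.sigma_prop * ipred)
                flagged = False
            else:
                iwres = np.nan
                flagged = True
            rows.append((s.subject_id, o.time, s.occasion_of(o.time), ipred, iwres, flagged))
    return pd.DataFrame(
        rows, columns=["subject_id", "time", "occasion", "ipred", "iwres", "flagged"]
    )


class PopPKModel(BaseEstimator, TransformerMixin):
    """Scikit-learn style wrapper around the population-PK stage.

    ``fit`` runs the occasion-1 Laplace ML fit and computes
    empirical-Bayes individual parameters; ``transform`` returns the
    IWRES table over all occasions for the given subjects.

    Attributes
    ----------
    params_ : PKModelParams
    ebes_ : EBESet
    loglik_ : float
    converged_ : bool
    excluded_ : list of subject ids without occasion-1 PK data
    """

    def __init__(self, init=None, fixed=(), max_iter=300, tol=1e-8):
        self.init = init
        self.fixed = fixed
        self.max_iter = max_iter
        self.tol = tol

    def fit(self, X, y=None):
        """``X`` is a list of :class:`SubjectSeries`."""
        params, info = fit_first_occasion(
            X, init=self.init, fixed=tuple(self.fixed), max_iter=self.max_iter, tol=self.tol
        )
        self.params_ = params
        self.loglik_ = info["loglik"]
        self.converged_ = info["converged"]
        self.excluded_ = info["excluded"]
        self.ebes_ = compute_ebes(params, X)
        return self

    def transform(self, X) -> pd.DataFrame:
        """IWRES table for ``X`` (list of :class:`SubjectSeries`)."""
        if not hasattr(self, "params_"):
            raise RuntimeError("PopPKModel is not fitted yet")
        ebes = compute_ebes(self.params_, X)
        return compute_iwres(self.params_, ebes, X)

    def predict(self, subject: SubjectSeries, times) -> np.ndarray:
        """Individual concentration prediction at ``times`` (days)."""
        if not hasattr(self, "params_"):
            raise RuntimeError("PopPKModel is not fitted yet")
        ebes = compute_ebes(self.params_, [subject])
        return predict_concentration(
            self.params_, ebes.lookup(subject.subject_id), subject.dose_events, times
        )
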