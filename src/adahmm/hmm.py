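"""Two-state hidden-Markov machinery for anti-drug-antibody (ADA) inference.

The hidden chain has two states: ``S_NOADA`` (no ADA production, index 0)
and ``S_ADA`` (ADA production, index 1).  Each observation record carries
up to two continuous measurements — an individually weighted population-PK
residual and an ADA assay measurement (U/mL) — whose joint density
conditional on the hidden state is a bivariate Gaussian with
state-specific modes, a state-specific correlation, and per-variable
variances shared across the two states.  When one component of a record
is missing, the exact Gaussian marginal of the present component is used.

Transitions are time-homogeneous with the two off-diagonal probabilities
parameterised on the logit scale, so that subject-level random effects
added to the logit keep individual probabilities inside (0, 1).

All subjects are assumed drug-naive: the chain starts in ``S_NOADA`` and
the first record contributes its emission density under that state alone.
Later records follow a scaled forward recursion whose per-record
normalisers accumulate into the log-likelihood; no unnormalised products
are ever formed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit, logit as _logit_fn

S_NOADA = 0
S_ADA = 1
STATE_LABELS = ("S_NOADA", "S_ADA")

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass
class EmissionParams:
    """State-conditional bivariate Gaussian emission parameters.

    Modes are state specific; the two variances are shared across states
    (a single residual term per observed variable); the correlation
    between the PK residual and the ADA measurement is state specific.
    ``omega2_mu_*`` are optional variances of subject-level random
    effects that shift the modes of one observed variable jointly in
    both states.
    """

    mu_pkres_noada: float = 0.0
    mu_pkres_ada: float = -1.0
    mu_ada_noada: float = 0.6
    mu_ada_ada: float = 2.4
    sigma2_pkres: float = 1.0
    sigma2_ada: float = 2.0
    rho_noada: float = 0.0
    rho_ada: float = 0.0
    omega2_mu_pkres: float = 0.0
    omega2_mu_ada: float = 0.0

    def __post_init__(self) -> None:
        if not (self.sigma2_pkres > 0 and self.sigma2_ada > 0):
            raise ValueError("emission variances must be strictly positive")
        for r in (self.rho_noada, self.rho_ada):
            if not -1.0 < r < 1.0:
                raise ValueError(f"correlation {r} outside (-1, 1)")
        if self.omega2_mu_pkres < 0 or self.omega2_mu_ada < 0:
            raise ValueError("IIV variances must be non-negative")

    def mode(self, state: int) -> tuple[float, float]:
        """(PK-residual mode, ADA mode) for ``state``."""
        if state == S_NOADA:
            return self.mu_pkres_noada, self.mu_ada_noada
        return self.mu_pkres_ada, self.mu_ada_ada

    def rho(self, state: int) -> float:
        return self.rho_noada if state == S_NOADA else self.rho_ada


@dataclass
class TransitionParams:
    """Logit-scale transition parameters of the two-state chain.

    ``logit_pi12`` is the logit of the probability of moving from
    ``S_NOADA`` to ``S_ADA`` between consecutive records; ``logit_pi21``
    the reverse move.  ``omega2_pi*`` are optional variances of additive
    subject-level random effects on the logits.
    """

    logit_pi12: float = _logit_fn(0.05)
    logit_pi21: float = _logit_fn(0.01)
    omega2_pi12: float = 0.0
    omega2_pi21: float = 0.0

    def __post_init__(self) -> None:
        if self.omega2_pi12 < 0 or self.omega2_pi21 < 0:
            raise ValueError("IIV variances must be non-negative")

    @property
    def pi12(self) -> float:
        return float(expit(self.logit_pi12))

    @property
    def pi21(self) -> float:
        return float(expit(self.logit_pi21))

    @classmethod
    def from_probs(
        cls,
        pi12: float,
        pi21: float,
        omega2_pi12: float = 0.0,
        omega2_pi21: float = 0.0,
    ) -> "TransitionParams":
        if not (0.0 < pi12 < 1.0 and 0.0 < pi21 < 1.0):
            raise ValueError("transition probabilities must lie in (0, 1)")
        return cls(
            float(_logit_fn(pi12)), float(_logit_fn(pi21)), omega2_pi12, omega2_pi21
        )


@dataclass
class ObservationRecord:
    """One record of the observed bivariate series; ``nan`` marks a
    missing component."""

    y_pkres: float = np.nan
    y_ada: float = np.nan
    time: float = np.nan


@dataclass
class FilteredTrajectory:
    """Scaled-forward output: filtered state probabilities, per-record
    log normalisers (their sum is the log-likelihood)."""

    phi: np.ndarray  # (T, 2) filtered P(state | records up to t)
    log_scale: np.ndarray  # (T,) per-record log normaliser
    loglik: float


@dataclass
class StatePath:
    """Most probable hidden-state sequence and its joint log-probability."""

    states: np.ndarray  # (T,) ints in {0, 1}
    log_prob: float
    labels: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        self.labels = tuple(STATE_LABELS[s] for s in self.states)


# ---------------------------------------------------------------------------
# Emission density


def _pair_loglik(y1, y2, mu1, mu2, sigma2_1, sigma2_2, rho):
    """Vectorised log-density of (y1, y2); nan components integrated out.

    Records with both components missing contribute log 1 = 0.
    """
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    p1 = ~np.isnan(y1)
    p2 = ~np.isnan(y2)
    s1 = np.sqrt(sigma2_1)
    s2 = np.sqrt(sigma2_2)
    z1 = np.where(p1, (np.nan_to_num(y1) - mu1) / s1, 0.0)
    z2 = np.where(p2, (np.nan_to_num(y2) - mu2) / s2, 0.0)

    one_m_r2 = 1.0 - rho**2
    ll_both = (
        -_LOG2PI
        - 0.5 * np.log(sigma2_1 * sigma2_2 * one_m_r2)
        - (z1**2 - 2.0 * rho * z1 * z2 + z2**2) / (2.0 * one_m_r2)
    )
    ll_1 = -0.5 * (_LOG2PI + np.log(sigma2_1) + z1**2)
    ll_2 = -0.5 * (_LOG2PI + np.log(sigma2_2) + z2**2)

    out = np.where(
        p1 & p2, ll_both, np.where(p1, ll_1, np.where(p2, ll_2, 0.0))
    )
    return out


def emission_logpdf(
    rec: ObservationRecord | tuple | np.ndarray,
    state: int,
    em: EmissionParams,
    shift_pkres: float = 0.0,
    shift_ada: float = 0.0,
) -> float:
    """Log emission density of one record conditional on ``state``.

    ``shift_pkres`` / ``shift_ada`` are subject-level deviations of the
    modes (random effects), applied jointly to both states' modes of the
    respective variable.  Missing components (nan) use the exact
    Gaussian marginal of the present component; a fully missing record
    contributes 0.
    """
    if state not in (S_NOADA, S_ADA):
        raise ValueError(f"unknown state {state}")
    if isinstance(rec, ObservationRecord):
        y1, y2 = rec.y_pkres, rec.y_ada
    else:
        y1, y2 = float(rec[0]), float(rec[1])
    mu1, mu2 = em.mode(state)
    return float(
        _pair_loglik(
            y1,
            y2,
            mu1 + shift_pkres,
            mu2 + shift_ada,
            em.sigma2_pkres,
            em.sigma2_ada,
            em.rho(state),
        )
    )


def emission_loglik_matrix(
    Y: np.ndarray,
    em: EmissionParams,
    shift_pkres=0.0,
    shift_ada=0.0,
) -> np.ndarray:
    """Log emission densities for an array of records.

    Parameters
    ----------
    Y : (..., 2) array with nan for missing components.
    shift_pkres, shift_ada : scalars or arrays broadcastable to ``Y[..., 0]``.

    Returns
    -------
    (..., 2) array: last axis indexes the hidden state.
    """
    Y = np.asarray(Y, dtype=float)
    y1, y2 = Y[..., 0], Y[..., 1]
    out = np.empty(Y.shape[:-1] + (2,), dtype=float)
    for s in (S_NOADA, S_ADA):
        mu1, mu2 = em.mode(s)
        out[..., s] = _pair_loglik(
            y1,
            y2,
            mu1 + shift_pkres,
            mu2 + shift_ada,
            em.sigma2_pkres,
            em.sigma2_ada,
            em.rho(s),
        )
    return out


# ---------------------------------------------------------------------------
# Transitions


def transition_matrix(
    tp: TransitionParams, eta12: float = 0.0, eta21: float = 0.0
) -> np.ndarray:
    """Row-stochastic 2x2 transition matrix for one subject.

    ``eta12`` / ``eta21`` are subject-level random effects added to the
    logits; rows sum to 1 exactly because the diagonal entries are
    computed as complements.
    """
    p12 = expit(tp.logit_pi12 + eta12)
    p21 = expit(tp.logit_pi21 + eta21)
    return np.array([[1.0 - p12, p12], [p21, 1.0 - p21]], dtype=float)


# ---------------------------------------------------------------------------
# Forward recursion and Viterbi


def as_observation_array(records) -> np.ndarray:
    """Coerce a record sequence to a (T, 2) float array (nan = missing)."""
    if isinstance(records, np.ndarray):
        Y = np.asarray(records, dtype=float)
        if Y.ndim != 2 or Y.shape[1] != 2:
            raise ValueError("observation array must have shape (T, 2)")
        return Y
    rows = []
    for r in records:
        if isinstance(r, ObservationRecord):
            rows.append((r.y_pkres, r.y_ada))
        else:
            rows.append((float(r[0]), float(r[1])))
    if not rows:
        raise ValueError("at least one record is required")
    return np.asarray(rows, dtype=float)


def forward_filter(
    records,
    em: EmissionParams,
    tp: TransitionParams,
    eta12: float = 0.0,
    eta21: float = 0.0,
    shift_pkres: float = 0.0,
    shift_ada: float = 0.0,
) -> FilteredTrajectory:
    """Scaled forward recursion for one subject.

    Record 1 carries no transition: its likelihood is the emission
    density under ``S_NOADA`` alone (drug-naive start).  Each later
    record propagates the filtered probabilities through the transition
    matrix, multiplies by the emission densities, and renormalises; the
    per-record normalisers accumulate into the log-likelihood.  A record
    with both components missing is propagated by the transition alone
    and contributes log 1.
    """
    Y = as_observation_array(records)
    T = Y.shape[0]
    logB = emission_loglik_matrix(Y, em, shift_pkres, shift_ada)
    P = transition_matrix(tp, eta12, eta21)

    phi = np.zeros((T, 2))
    log_scale = np.zeros(T)

    # record 1: everyone starts in S_NOADA
    log_scale[0] = logB[0, S_NOADA]
    phi[0] = (1.0, 0.0)

    for t in range(1, T):
        prior = phi[t - 1] @ P
        m = logB[t].max()
        w = prior * np.exp(logB[t] - m)
        c = w.sum()
        phi[t] = w / c
        log_scale[t] = np.log(c) + m

    return FilteredTrajectory(phi=phi, log_scale=log_scale, loglik=float(log_scale.sum()))


def forward_loglik(records, em, tp, eta12=0.0, eta21=0.0, shift_pkres=0.0, shift_ada=0.0) -> float:
    """Log-likelihood of one subject's record series (scaled forward)."""
    return forward_filter(records, em, tp, eta12, eta21, shift_pkres, shift_ada).loglik


def viterbi_decode(
    records,
    em: EmissionParams,
    tp: TransitionParams,
    eta12: float = 0.0,
    eta21: float = 0.0,
    shift_pkres: float = 0.0,
    shift_ada: float = 0.0,
) -> StatePath:
    """Most probable hidden-state sequence for one subject.

    Uses the same drug-naive initialisation as the forward recursion
    (record 1 in ``S_NOADA``).  Ties are broken toward ``S_NOADA``,
    which is conservative (fewer ADA calls) and deterministic.
    """
    Y = as_observation_array(records)
    T = Y.shape[0]
    logB = emission_loglik_matrix(Y, em, shift_pkres, shift_ada)
    with np.errstate(divide="ignore"):
        logP = np.log(transition_matrix(tp, eta12, eta21))

    delta = np.full((T, 2), -np.inf)
    psi = np.zeros((T, 2), dtype=int)
    delta[0, S_NOADA] = logB[0, S_NOADA]

    for t in range(1, T):
        for s in (S_NOADA, S_ADA):
            cand = delta[t - 1] + logP[:, s]
            # argmax prefers index 0 == S_NOADA on ties
            j = int(np.argmax(cand))
            psi[t, s] = j
            delta[t, s] = cand[j] + logB[t, s]

    states = np.zeros(T, dtype=int)
    states[-1] = int(np.argmax(delta[-1]))
    for t in range(T - 2, -1, -1):
        states[t] = psi[t + 1, states[t + 1]]
    return StatePath(states=states, log_prob=float(delta[-1, states[-1]]))
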