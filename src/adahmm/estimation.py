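"""Population maximum-likelihood estimation of the ADA mixed hidden-Markov model.

Six nested model variants are supported, differing in whether the ADA
assay modes are estimated or fixed to the clinically anchored values
(0.6 U/mL at the assay LLOQ for the no-production state, 2.4 U/mL at
the clinical positivity threshold for the production state), and in
whether subject-level random effects (IIV) are placed on the emission
modes and/or the transition-probability logits:

======= ============== =============== ====================
variant ADA modes      IIV on modes    IIV on transitions
======= ============== =============== ====================
1       estimated      yes             yes
2       fixed          yes             yes
3       estimated      no              yes
4       fixed          no              yes
5       estimated      no              no
6       fixed          no              no
======= ============== =============== ====================

The population log-likelihood is the sum over subjects of the scaled
forward log-likelihood; when random effects are present each subject's
contribution is marginalised over the (diagonal-covariance) random
effects by adaptive Gauss-Hermite quadrature.  Estimation maximises
this marginal likelihood directly with a quasi-Newton optimiser on an
unconstrained parameterisation (log variances, logit probabilities,
atanh correlations), optionally from several jittered starting points.
Standard errors come from a central-finite-difference Hessian of the
negative log-likelihood in the unconstrained space, delta-method mapped
to the natural scale.

The user-facing surface is the scikit-learn style :class:`MixedHMM`
estimator, taking observations hmmlearn-style as an ``(n_records, 2)``
array (columns: PK residual, ADA measurement; ``nan`` = missing) plus
per-subject ``lengths``.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logsumexp
from sklearn.base import BaseEstimator

from .hmm import (
    S_ADA,
    S_NOADA,
    EmissionParams,
    TransitionParams,
    emission_loglik_matrix,
    forward_filter,
    transition_matrix,
    viterbi_decode,
)

_BAD_LOGLIK = -1e12
_BOUNDARY_TOL = 1e-6


# ---------------------------------------------------------------------------
# Variant configuration


@dataclass(frozen=True)
class VariantConfig:
    """Which parameters a model variant estimates and where IIV sits."""

    variant_id: int
    ada_modes_fixed: bool
    iiv_on_modes: bool
    iiv_on_transitions: bool
    univariate: str | None = None  # None | "pk" | "ada"

    @classmethod
    def from_variant(cls, variant_id: int) -> "VariantConfig":
        table = {
            1: (False, True, True),
            2: (True, True, True),
            3: (False, False, True),
            4: (True, False, True),
            5: (False, False, False),
            6: (True, False, False),
        }
        if variant_id not in table:
            raise ValueError(f"variant must be 1..6, got {variant_id!r}")
        fixed, iiv_m, iiv_t = table[variant_id]
        return cls(variant_id, fixed, iiv_m, iiv_t)

    @property
    def label(self) -> str:
        if self.univariate:
            return f"model {self.variant_id} (univariate {self.univariate})"
        return f"model {self.variant_id}"


def decouple_univariate(cfg: VariantConfig, which: str) -> VariantConfig:
    """Reduce a bivariate configuration to a single observed variable.

    The chosen variable keeps its (univariate normal) emission; the
    correlations and the other variable's parameters drop out; the
    transition structure is unchanged.  The returned configuration can
    be refit on the same records.
    """
    if which not in ("pk", "ada"):
        raise ValueError("which must be 'pk' or 'ada'")
    return dataclasses.replace(cfg, univariate=which)


def free_param_names(cfg: VariantConfig) -> list[str]:
    """Names of the parameters estimated under ``cfg`` (attribute names
    on :class:`EmissionParams` / :class:`TransitionParams`)."""
    uv = cfg.univariate
    names: list[str] = []
    if uv != "ada":
        names += ["mu_pkres_noada", "mu_pkres_ada"]
    if uv != "pk" and not cfg.ada_modes_fixed:
        names += ["mu_ada_noada", "mu_ada_ada"]
    if uv != "ada":
        names += ["sigma2_pkres"]
    if uv != "pk":
        names += ["sigma2_ada"]
    if uv is None:
        names += ["rho_noada", "rho_ada"]
    names += ["logit_pi12", "logit_pi21"]
    if cfg.iiv_on_modes:
        if uv != "ada":
            names += ["omega2_mu_pkres"]
        if uv != "pk" and not cfg.ada_modes_fixed:
            names += ["omega2_mu_ada"]
    if cfg.iiv_on_transitions:
        names += ["omega2_pi12", "omega2_pi21"]
    return names


# ---------------------------------------------------------------------------
# Packing between natural parameters and an unconstrained vector


def _to_unconstrained(name: str, value: float) -> float:
    if name.startswith(("sigma2", "omega2")):
        if value <= 0:
            raise ValueError(f"{name} must be > 0 to be estimated, got {value}")
        return float(np.log(value))
    if name.startswith("rho"):
        if not -1.0 < value < 1.0:
            raise ValueError(f"{name} outside (-1, 1)")
        return float(np.arctanh(value))
    return float(value)  # modes and logits


def _from_unconstrained(name: str, u: float) -> float:
    if name.startswith(("sigma2", "omega2")):
        return float(np.exp(u))
    if name.startswith("rho"):
        return float(np.tanh(u))
    return float(u)


def _get(em: EmissionParams, tp: TransitionParams, name: str) -> float:
    owner = tp if name.startswith(("logit_", "omega2_pi")) else em
    return getattr(owner, name)


def pack_params(em: EmissionParams, tp: TransitionParams, cfg: VariantConfig) -> np.ndarray:
    """Map the free parameters under ``cfg`` to an unconstrained vector."""
    return np.array(
        [_to_unconstrained(n, _get(em, tp, n)) for n in free_param_names(cfg)]
    )


def unpack_params(
    x: np.ndarray,
    cfg: VariantConfig,
    em0: EmissionParams,
    tp0: TransitionParams,
) -> tuple[EmissionParams, TransitionParams]:
    """Inverse of :func:`pack_params`; non-free parameters are taken
    from the templates ``em0`` / ``tp0``."""
    names = free_param_names(cfg)
    if len(x) != len(names):
        raise ValueError(f"expected vector of length {len(names)}, got {len(x)}")
    em_kw, tp_kw = {}, {}
    for n, u in zip(names, x):
        v = _from_unconstrained(n, float(u))
        if n.startswith(("logit_", "omega2_pi")):
            tp_kw[n] = v
        else:
            em_kw[n] = v
    return dataclasses.replace(em0, **em_kw), dataclasses.replace(tp0, **tp_kw)


# ---------------------------------------------------------------------------
# Dataset preparation (padded arrays for the batched forward pass)


class _PaddedData:
    """Subjects padded to a common record count for vectorised forward
    recursions; ``mask`` marks real records."""

    def __init__(self, Y: np.ndarray, lengths: np.ndarray):
        lengths = np.asarray(lengths, dtype=int)
        if lengths.sum() != Y.shape[0]:
            raise ValueError("sum of lengths must equal number of rows in X")
        if (lengths < 1).any():
            raise ValueError("every subject needs at least one record")
        n, T = len(lengths), int(lengths.max())
        self.Y = np.full((n, T, 2), np.nan)
        self.mask = np.zeros((n, T), dtype=bool)
        start = 0
        for i, L in enumerate(lengths):
            self.Y[i, :L] = Y[start : start + L]
            self.mask[i, :L] = True
            start += L
        self.lengths = lengths
        self.n_subjects = n
        self.n_records = int(lengths.sum())

    def subject(self, i: int) -> np.ndarray:
        return self.Y[i, : self.lengths[i]]

    def masked_channels(self, cfg: VariantConfig) -> "_PaddedData":
        """Copy with the channel excluded by a univariate config set to
        missing (its exact marginalisation)."""
        if cfg.univariate is None:
            return self
        out = object.__new__(_PaddedData)
        out.Y = self.Y.copy()
        out.mask = self.mask
        out.lengths = self.lengths
        out.n_subjects = self.n_subjects
        out.n_records = self.n_records
        out.Y[..., 1 if cfg.univariate == "pk" else 0] = np.nan
        return out


def _validate_X(X, lengths) -> tuple[np.ndarray, np.ndarray]:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise ValueError("X must be (n_records, 2): [pk residual, ADA value]")
    if lengths is None:
        lengths = np.array([X.shape[0]])
    return X, np.asarray(lengths, dtype=int)


# ---------------------------------------------------------------------------
# Batched forward log-likelihood


def _batch_forward_loglik(
    data: _PaddedData,
    em: EmissionParams,
    tp: TransitionParams,
    shift_pkres=0.0,
    shift_ada=0.0,
    eta12=0.0,
    eta21=0.0,
) -> np.ndarray:
    """Per-subject forward log-likelihoods, vectorised over subjects.

    The shift/eta arguments may be scalars or per-subject arrays, which
    is how subject-level random effects enter.
    """
    n, T = data.mask.shape
    sp = np.broadcast_to(np.asarray(shift_pkres, dtype=float), (n,))[:, None]
    sa = np.broadcast_to(np.asarray(shift_ada, dtype=float), (n,))[:, None]
    logB = emission_loglik_matrix(data.Y, em, sp, sa)  # (n, T, 2)

    p12 = np.broadcast_to(expit(tp.logit_pi12 + np.asarray(eta12, dtype=float)), (n,))
    p21 = np.broadcast_to(expit(tp.logit_pi21 + np.asarray(eta21, dtype=float)), (n,))
    P = np.empty((n, 2, 2))
    P[:, 0, 0] = 1.0 - p12
    P[:, 0, 1] = p12
    P[:, 1, 0] = p21
    P[:, 1, 1] = 1.0 - p21

    phi = np.zeros((n, 2))
    phi[:, S_NOADA] = 1.0
    ll = logB[:, 0, S_NOADA].copy()  # drug-naive start, no transition

    for t in range(1, T):
        prior = np.einsum("ns,nst->nt", phi, P)
        m = logB[:, t].max(axis=1)
        w = prior * np.exp(logB[:, t] - m[:, None])
        c = w.sum(axis=1)
        live = data.mask[:, t]
        phi = np.where(live[:, None], w / c[:, None], phi)
        ll += np.where(live, np.log(c) + m, 0.0)
    return ll


# ---------------------------------------------------------------------------
# Random-effect integration (adaptive Gauss-Hermite quadrature)


def _active_eta_dims(
    cfg: VariantConfig, em: EmissionParams, tp: TransitionParams
) -> list[tuple[str, float]]:
    """(name, omega2) for random-effect dimensions with positive variance.

    Mode IIV is one eta per observed variable, shifting both states'
    modes of that variable jointly; when the ADA modes are fixed to the
    clinical anchors mode IIV applies to the PK-residual modes only.
    """
    dims: list[tuple[str, float]] = []
    if cfg.iiv_on_modes:
        if cfg.univariate != "ada" and em.omega2_mu_pkres > 0:
            dims.append(("mu_pkres", em.omega2_mu_pkres))
        if cfg.univariate != "pk" and not cfg.ada_modes_fixed and em.omega2_mu_ada > 0:
            dims.append(("mu_ada", em.omega2_mu_ada))
    if cfg.iiv_on_transitions:
        if tp.omega2_pi12 > 0:
            dims.append(("pi12", tp.omega2_pi12))
        if tp.omega2_pi21 > 0:
            dims.append(("pi21", tp.omega2_pi21))
    return dims


_ETA_KEY = {"mu_pkres": "shift_pkres", "mu_ada": "shift_ada", "pi12": "eta12", "pi21": "eta21"}


def _batch_neg_joint(data, em, tp, dims, E) -> np.ndarray:
    """Per-subject -(conditional loglik + random-effect log prior);
    ``E`` is the (n_subjects, d) matrix of random effects."""
    kw = {}
    for j, (name, _) in enumerate(dims):
        kw[_ETA_KEY[name]] = E[:, j]
    ll = _batch_forward_loglik(data, em, tp, **kw)
    om2 = np.array([om for _, om in dims])
    prior = 0.5 * np.sum(np.log(2.0 * np.pi * om2) + E**2 / om2, axis=1)
    return -ll + prior


def _batch_map_etas(data, em, tp, dims, E0=None):
    """Vectorised damped-Newton joint modes of the random effects.

    Returns ``(E, H, f)``: per-subject modes (n, d), finite-difference
    Hessians of the negative joint at the modes (n, d, d) and the
    objective values (n,).
    """
    n, d = data.n_subjects, len(dims)
    E = np.zeros((n, d)) if E0 is None else E0.copy()
    h = 1e-3

    def F(e):
        return _batch_neg_joint(data, em, tp, dims, e)

    def grad_hess(e):
        f0 = F(e)
        g = np.zeros((n, d))
        H = np.zeros((n, d, d))
        shifts = []
        for a in range(d):
            ea = np.zeros_like(e)
            ea[:, a] = h
            fp, fm = F(e + ea), F(e - ea)
            g[:, a] = (fp - fm) / (2.0 * h)
            H[:, a, a] = (fp - 2.0 * f0 + fm) / h**2
            shifts.append(ea)
        for a in range(d):
            for b in range(a + 1, d):
                ea, eb = shifts[a], shifts[b]
                H[:, a, b] = H[:, b, a] = (
                    F(e + ea + eb) - F(e + ea - eb) - F(e - ea + eb) + F(e - ea - eb)
                ) / (4.0 * h**2)
        return f0, g, H

    f0 = F(E)
    for _ in range(30):
        f0, g, H = grad_hess(E)
        if np.max(np.abs(g)) < 1e-7:
            break
        w, V = np.linalg.eigh(H)
        w = np.maximum(np.abs(w), 1e-6)
        step = -np.einsum("nab,nb->na", V, np.einsum("nab,na->nb", V, g) / w)
        lam = np.ones(n)
        for _ in range(12):
            trial = E + lam[:, None] * step
            ft = F(trial)
            worse = ft > f0 + 1e-12
            if not worse.any():
                break
            lam = np.where(worse, lam / 2.0, lam)
        improved = ft <= f0 + 1e-12
        if not improved.any():
            break
        E = np.where(improved[:, None], trial, E)
    f0, g, H = grad_hess(E)
    return E, H, f0


def _population_loglik_iiv(data, em, tp, cfg, dims, n_nodes, warm=None):
    """Batched adaptive Gauss-Hermite marginal log-likelihood.

    Each subject's integrand is re-centred at its joint random-effect
    mode and re-scaled by the local curvature; a product Hermite grid
    with ``n_nodes`` per dimension is evaluated with the vectorised
    forward pass.
    """
    d = len(dims)
    E, H, _ = _batch_map_etas(data, em, tp, dims, warm)
    if warm is not None:
        warm[:] = E
    w_eig, V = np.linalg.eigh(H)
    w_eig = np.clip(w_eig, 1e-8, None)
    # L L^T = H^{-1}; logdet L = -0.5 sum log eigenvalues
    L = V / np.sqrt(w_eig)[:, None, :]
    logdetL = -0.5 * np.log(w_eig).sum(axis=1)

    x, wts = np.polynomial.hermite.hermgauss(n_nodes)
    grids = np.meshgrid(*([x] * d), indexing="ij")
    Z = np.stack([g.ravel() for g in grids], axis=1)  # (K, d)
    grids_w = np.meshgrid(*([np.log(wts)] * d), indexing="ij")
    logW = np.sum([g.ravel() for g in grids_w], axis=0)  # (K,)

    K = Z.shape[0]
    vals = np.empty((K, data.n_subjects))
    for k in range(K):
        eta_k = E + np.sqrt(2.0) * np.einsum("nab,b->na", L, Z[k])
        vals[k] = -_batch_neg_joint(data, em, tp, dims, eta_k)
    log_int = (
        0.5 * d * np.log(2.0)
        + logdetL
        + logsumexp(vals + (logW + (Z**2).sum(axis=1))[:, None], axis=0)
    )
    return float(log_int.sum())


def _subject_loglik_eta(Yi, em, tp, dims, eta) -> float:
    kw = dict(shift_pkres=0.0, shift_ada=0.0, eta12=0.0, eta21=0.0)
    key = {"mu_pkres": "shift_pkres", "mu_ada": "shift_ada", "pi12": "eta12", "pi21": "eta21"}
    for (name, _), e in zip(dims, eta):
        kw[key[name]] = float(e)
    return forward_filter(Yi, em, tp, **kw).loglik


def _subject_joint_neg(Yi, em, tp, dims, eta) -> float:
    """-(conditional loglik + random-effect log prior) for one subject."""
    lp = 0.0
    for (name, om2), e in zip(dims, eta):
        lp += -0.5 * (np.log(2.0 * np.pi * om2) + e * e / om2)
    return -(_subject_loglik_eta(Yi, em, tp, dims, eta) + lp)


def population_loglik(
    X,
    lengths,
    em: EmissionParams,
    tp: TransitionParams,
    cfg: VariantConfig,
    n_nodes: int = 9,
) -> float:
    """Population marginal log-likelihood of the dataset under ``cfg``.

    Without random effects (or with all IIV variances zero) this is the
    plain sum of per-subject forward log-likelihoods; otherwise each
    subject is integrated over its random effects by adaptive
    Gauss-Hermite quadrature with ``n_nodes`` nodes per dimension.
    """
    X, lengths = _validate_X(X, lengths)
    data = _PaddedData(X, lengths).masked_channels(cfg)
    return _population_loglik_prepared(data, em, tp, cfg, n_nodes)


def _population_loglik_prepared(
    data: _PaddedData,
    em: EmissionParams,
    tp: TransitionParams,
    cfg: VariantConfig,
    n_nodes: int,
    warm=None,
) -> float:
    dims = _active_eta_dims(cfg, em, tp)
    if not dims:
        return float(_batch_forward_loglik(data, em, tp).sum())
    return _population_loglik_iiv(data, em, tp, cfg, dims, n_nodes, warm=warm)


# ---------------------------------------------------------------------------
# Fit result container


@dataclass
class FitResult:
    """Natural-scale estimates and diagnostics of one variant fit."""

    variant: str
    estimates: dict[str, float]
    fixed: dict[str, float]
    se: dict[str, float]
    rse_percent: dict[str, float]
    loglik: float
    converged: bool
    n_function_evals: int
    boundary_flags: list[str] = field(default_factory=list)
    seed: int | None = None
    n_subjects: int = 0
    n_records: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FitResult":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "FitResult":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _natural_name(name: str) -> str:
    return {"logit_pi12": "pi12", "logit_pi21": "pi21"}.get(name, name)


def _natural_value(name: str, em: EmissionParams, tp: TransitionParams) -> float:
    if name == "logit_pi12":
        return tp.pi12
    if name == "logit_pi21":
        return tp.pi21
    return _get(em, tp, name)


def _natural_deriv(name: str, em: EmissionParams, tp: TransitionParams) -> float:
    """d(natural)/d(unconstrained) for the delta method."""
    if name.startswith(("sigma2", "omega2")):
        return _get(em, tp, name)
    if name.startswith("rho"):
        return 1.0 - _get(em, tp, name) ** 2
    if name == "logit_pi12":
        p = tp.pi12
        return p * (1.0 - p)
    if name == "logit_pi21":
        p = tp.pi21
        return p * (1.0 - p)
    return 1.0


# ---------------------------------------------------------------------------
# Estimator


class MixedHMM(BaseEstimator):
    """Two-state mixed hidden-Markov model for ADA-production inference.

    Parameters
    ----------
    variant : int, default=6
        Model variant 1-6 (see module docstring).
    univariate : {None, "pk", "ada"}, default=None
        Decouple the bivariate model to a single observed variable.
    n_nodes : int, default=9
        Gauss-Hermite nodes per random-effect dimension.
    n_multistart : int, default=3
        Number of optimisation starts; the first uses ``init`` values,
        the rest jitter them by +/-50% on the natural scale.
    init : dict, optional
        Overrides for initial natural-scale parameter values, keyed by
        :class:`EmissionParams`/:class:`TransitionParams` attribute
        names plus ``pi12``/``pi21``.
    compute_se : bool, default=True
        Attempt a finite-difference Hessian for standard errors.
    max_iter : int, default=500
        Optimiser iteration cap per start.
    tol : float, default=1e-9
        Relative objective-change tolerance of the optimiser.
    random_state : int or numpy Generator, optional
        Seeds multistart jitter and :meth:`sample`.

    Attributes
    ----------
    emission_ : EmissionParams
    transition_ : TransitionParams
    config_ : VariantConfig
    loglik_ : float
    converged_ : bool
    boundary_flags_ : list of str
    result_ : FitResult
    """

    def __init__(
        self,
        variant: int = 6,
        univariate: str | None = None,
        n_nodes: int = 9,
        n_multistart: int = 3,
        init: dict | None = None,
        compute_se: bool = True,
        max_iter: int = 500,
        tol: float = 1e-9,
        random_state=None,
    ):
        self.variant = variant
        self.univariate = univariate
        self.n_nodes = n_nodes
        self.n_multistart = n_multistart
        self.init = init
        self.compute_se = compute_se
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- initial values ----------------------------------------------------

    _DEFAULT_INIT = {
        "mu_pkres_noada": 0.0,
        "mu_pkres_ada": -1.0,
        "mu_ada_noada": 0.6,
        "mu_ada_ada": 2.4,
        "sigma2_pkres": 1.0,
        "sigma2_ada": 2.0,
        "rho_noada": 0.0,
        "rho_ada": 0.0,
        "pi12": 0.05,
        "pi21": 0.01,
        "omega2_mu_pkres": 0.1,
        "omega2_mu_ada": 0.1,
        "omega2_pi12": 0.5,
        "omega2_pi21": 0.5,
    }

    def _initial_params(self, cfg: VariantConfig) -> tuple[EmissionParams, TransitionParams]:
        vals = dict(self._DEFAULT_INIT)
        if self.init:
            unknown = set(self.init) - set(vals)
            if unknown:
                raise ValueError(f"unknown init parameter(s): {sorted(unknown)}")
            vals.update(self.init)
        em = EmissionParams(
            mu_pkres_noada=vals["mu_pkres_noada"],
            mu_pkres_ada=vals["mu_pkres_ada"],
            mu_ada_noada=vals["mu_ada_noada"],
            mu_ada_ada=vals["mu_ada_ada"],
            sigma2_pkres=vals["sigma2_pkres"],
            sigma2_ada=vals["sigma2_ada"],
            rho_noada=vals["rho_noada"],
            rho_ada=vals["rho_ada"],
            omega2_mu_pkres=vals["omega2_mu_pkres"] if cfg.iiv_on_modes else 0.0,
            omega2_mu_ada=vals["omega2_mu_ada"] if cfg.iiv_on_modes else 0.0,
        )
        tp = TransitionParams.from_probs(
            vals["pi12"],
            vals["pi21"],
            vals["omega2_pi12"] if cfg.iiv_on_transitions else 0.0,
            vals["omega2_pi21"] if cfg.iiv_on_transitions else 0.0,
        )
        return em, tp

    def _config(self) -> VariantConfig:
        cfg = VariantConfig.from_variant(self.variant)
        if self.univariate is not None:
            cfg = decouple_univariate(cfg, self.univariate)
        return cfg

    def _jitter_start(self, x0: np.ndarray, names: list[str], rng) -> np.ndarray:
        """Jitter an unconstrained start by +/-50% on the natural scale."""
        out = np.empty_like(x0)
        for k, (n, u) in enumerate(zip(names, x0)):
            v = _from_unconstrained(n, u)
            f = 1.0 + rng.uniform(-0.5, 0.5)
            if n.startswith("logit_"):
                p = np.clip(expit(u) * f, 1e-4, 0.5)
                out[k] = np.log(p / (1.0 - p))
            elif n.startswith("rho"):
                out[k] = np.arctanh(np.clip(v * f, -0.9, 0.9))
            elif n.startswith(("sigma2", "omega2")):
                out[k] = np.log(max(v * f, 1e-6))
            else:
                # modes: additive jitter so a zero mode still moves
                out[k] = v * f + rng.uniform(-0.25, 0.25)
        return out

    # -- fitting -----------------------------------------------------------

    def fit(self, X, lengths=None):
        """Fit the variant by maximum (marginal) likelihood.

        Parameters
        ----------
        X : array-like of shape (n_records, 2)
            Stacked per-subject records, columns ``[pk residual, ADA]``,
            ``nan`` marking a missing component.
        lengths : array-like of int, optional
            Records per subject; defaults to one subject.
        """
        X, lengths = _validate_X(X, lengths)
        cfg = self._config()
        data = _PaddedData(X, lengths).masked_channels(cfg)
        em0, tp0 = self._initial_params(cfg)
        names = free_param_names(cfg)
        x0 = pack_params(em0, tp0, cfg)
        rng = np.random.default_rng(
            self.random_state if not isinstance(self.random_state, np.random.Generator)
            else self.random_state.integers(2**31)
        )

        n_evals = [0]
        d_iiv = len(_active_eta_dims(cfg, em0, tp0))
        warm = np.zeros((data.n_subjects, d_iiv)) if d_iiv else None

        def objective(x: np.ndarray) -> float:
            n_evals[0] += 1
            try:
                em, tp = unpack_params(x, cfg, em0, tp0)
            except (ValueError, OverflowError):
                return -_BAD_LOGLIK
            ll = _population_loglik_prepared(data, em, tp, cfg, self.n_nodes, warm=warm)
            if not np.isfinite(ll):
                return -_BAD_LOGLIK
            return -ll

        starts = [x0] + [
            self._jitter_start(x0, names, rng) for _ in range(max(0, self.n_multistart - 1))
        ]
        best = None
        for s in starts:
            res = minimize(
                objective,
                s,
                method="L-BFGS-B",
                options={
                    "maxiter": self.max_iter,
                    "ftol": self.tol,
                    "gtol": 1e-7,
                },
            )
            if np.isfinite(res.fun) and (best is None or res.fun < best.fun):
                best = res
        if best is None:  # pragma: no cover - defensive
            raise RuntimeError("all optimisation starts failed")

        em, tp = unpack_params(best.x, cfg, em0, tp0)
        self.config_ = cfg
        self.emission_ = em
        self.transition_ = tp
        self.loglik_ = float(-best.fun)
        self.converged_ = bool(best.success)
        self.n_function_evals_ = n_evals[0]

        self.boundary_flags_ = []
        for nm, p in (("pi12", tp.pi12), ("pi21", tp.pi21)):
            if p < _BOUNDARY_TOL or p > 1.0 - _BOUNDARY_TOL:
                self.boundary_flags_.append(nm)

        se: dict[str, float] = {}
        rse: dict[str, float] = {}
        if self.compute_se and self.converged_:
            se, rse = self._standard_errors(objective, best.x, names, em, tp)

        estimates = {
            _natural_name(n): _natural_value(n, em, tp) for n in names
        }
        all_fixed = {
            "mu_ada_noada": em.mu_ada_noada,
            "mu_ada_ada": em.mu_ada_ada,
        }
        fixed = (
            {}
            if not cfg.ada_modes_fixed or cfg.univariate == "pk"
            else all_fixed
        )
        seed = self.random_state if isinstance(self.random_state, (int, np.integer)) else None
        self.result_ = FitResult(
            variant=cfg.label,
            estimates=estimates,
            fixed=fixed,
            se=se,
            rse_percent=rse,
            loglik=self.loglik_,
            converged=self.converged_,
            n_function_evals=self.n_function_evals_,
            boundary_flags=list(self.boundary_flags_),
            seed=None if seed is None else int(seed),
            n_subjects=data.n_subjects,
            n_records=data.n_records,
        )
        self.se_ = se
        self.rse_percent_ = rse
        return self

    def _standard_errors(self, objective, x, names, em, tp):
        """Delta-method SEs from a central-FD Hessian of -loglik.

        A non-positive-definite Hessian (e.g. at a boundary estimate)
        yields no SEs, mirroring a failed covariance step.
        """
        k = len(x)
        h = 1e-4 * (1.0 + np.abs(x))
        H = np.empty((k, k))
        f0 = objective(x)

        def fx(dx):
            return objective(x + dx)

        for a in range(k):
            ea = np.zeros(k)
            ea[a] = h[a]
            H[a, a] = (fx(ea) - 2.0 * f0 + fx(-ea)) / h[a] ** 2
            for b in range(a + 1, k):
                eb = np.zeros(k)
                eb[b] = h[b]
                H[a, b] = H[b, a] = (
                    fx(ea + eb) - fx(ea - eb) - fx(-ea + eb) + fx(-ea - eb)
                ) / (4.0 * h[a] * h[b])
        try:
            cov = np.linalg.inv(H)
            if np.any(np.diag(cov) <= 0):
                raise np.linalg.LinAlgError("non-PD Hessian")
        except np.linalg.LinAlgError:
            warnings.warn(
                "Hessian not positive definite; standard errors unavailable",
                RuntimeWarning,
                stacklevel=2,
            )
            return {}, {}
        se, rse = {}, {}
        for n, var_u in zip(names, np.diag(cov)):
            nat = _natural_value(n, em, tp)
            s = abs(_natural_deriv(n, em, tp)) * float(np.sqrt(var_u))
            key = _natural_name(n)
            se[key] = s
            rse[key] = 100.0 * s / abs(nat) if nat != 0 else float("inf")
        return se, rse

    # -- inference ---------------------------------------------------------

    def _check_fitted(self):
        if not hasattr(self, "emission_"):
            raise RuntimeError("this MixedHMM instance is not fitted yet")

    def score(self, X, lengths=None) -> float:
        """Population marginal log-likelihood at the fitted parameters."""
        self._check_fitted()
        return population_loglik(
            X, lengths, self.emission_, self.transition_, self.config_, self.n_nodes
        )

    def _subject_etas(self, Yi) -> dict:
        """Empirical-Bayes (MAP) random effects for one subject, as
        keyword shifts for the decoding routines."""
        dims = _active_eta_dims(self.config_, self.emission_, self.transition_)
        kw = dict(shift_pkres=0.0, shift_ada=0.0, eta12=0.0, eta21=0.0)
        if not dims:
            return kw
        res = minimize(
            lambda e: _subject_joint_neg(Yi, self.emission_, self.transition_, dims, e),
            np.zeros(len(dims)),
            method="BFGS",
            options={"gtol": 1e-6},
        )
        key = {"mu_pkres": "shift_pkres", "mu_ada": "shift_ada", "pi12": "eta12", "pi21": "eta21"}
        for (name, _), e in zip(dims, res.x):
            kw[key[name]] = float(e)
        return kw

    def decode(self, X, lengths=None) -> tuple[float, np.ndarray]:
        """Viterbi decoding of every subject at the fitted parameters.

        For variants with random effects the subject's MAP etas are
        plugged in first (post-hoc step).  Returns the summed path
        log-probability and the per-record state sequence (0 =
        ``S_NOADA``, 1 = ``S_ADA``) aligned with the rows of ``X``.
        """
        self._check_fitted()
        X, lengths = _validate_X(X, lengths)
        data = _PaddedData(X, lengths).masked_channels(self.config_)
        states = np.empty(X.shape[0], dtype=int)
        logp = 0.0
        start = 0
        for i in range(data.n_subjects):
            Yi = data.subject(i)
            kw = self._subject_etas(Yi)
            path = viterbi_decode(Yi, self.emission_, self.transition_, **kw)
            states[start : start + len(Yi)] = path.states
            logp += path.log_prob
            start += len(Yi)
        return logp, states

    def predict(self, X, lengths=None) -> np.ndarray:
        """Viterbi state sequence (see :meth:`decode`)."""
        return self.decode(X, lengths)[1]

    def predict_proba(self, X, lengths=None) -> np.ndarray:
        """Filtered state probabilities per record, shape (n_records, 2)."""
        self._check_fitted()
        X, lengths = _validate_X(X, lengths)
        data = _PaddedData(X, lengths).masked_channels(self.config_)
        out = np.empty((X.shape[0], 2))
        start = 0
        for i in range(data.n_subjects):
            Yi = data.subject(i)
            kw = self._subject_etas(Yi)
            out[start : start + len(Yi)] = forward_filter(
                Yi, self.emission_, self.transition_, **kw
            ).phi
            start += len(Yi)
        return out

    def sample(self, n_subjects, n_records, random_state=None, floor_ada=False):
        """Draw a synthetic dataset from the (fitted or initial) model.

        Returns ``(X, lengths, states)`` in the same layout ``fit``
        expects; see :func:`adahmm.simulate.sample_mhmm`.
        """
        from .simulate import sample_mhmm

        if hasattr(self, "emission_"):
            em, tp = self.emission_, self.transition_
        else:
            em, tp = self._initial_params(self._config())
        rs = self.random_state if random_state is None else random_state
        return sample_mhmm(em, tp, n_subjects, n_records, rs, floor_ada=floor_ada)


def fit_mhmm(X, lengths=None, variant: int = 6, **kwargs) -> MixedHMM:
    """Functional wrapper: fit :class:`MixedHMM` and return the estimator."""
    return MixedHMM(variant=variant, **kwargs).fit(X, lengths)
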