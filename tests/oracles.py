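"""Independent reference implementations used only to check the package.

Everything here deliberately avoids the package's own numerics: emission
densities come from scipy.stats, sequence likelihoods from brute-force
path enumeration, marginal likelihoods from dense trapezoid grids, and
concentrations from an ODE integrator.
"""

import itertools

import numpy as np
from scipy.integrate import solve_ivp
from scipy.stats import multivariate_normal, norm


def emission_pdf_scipy(y, state, em):
    """Bivariate/marginal Gaussian emission density via scipy.stats."""
    mu = (
        [em.mu_pkres_noada, em.mu_ada_noada]
        if state == 0
        else [em.mu_pkres_ada, em.mu_ada_ada]
    )
    rho = em.rho_noada if state == 0 else em.rho_ada
    c = rho * np.sqrt(em.sigma2_pkres * em.sigma2_ada)
    y1, y2 = y
    if np.isnan(y1) and np.isnan(y2):
        return 1.0
    if np.isnan(y1):
        return norm(mu[1], np.sqrt(em.sigma2_ada)).pdf(y2)
    if np.isnan(y2):
        return norm(mu[0], np.sqrt(em.sigma2_pkres)).pdf(y1)
    cov = np.array([[em.sigma2_pkres, c], [c, em.sigma2_ada]])
    return multivariate_normal(mu, cov).pdf([y1, y2])


def enumerate_loglik(Y, em, pi12, pi21):
    """Exact sequence log-likelihood by summing over all 2^T paths that
    start in state 0."""
    T = len(Y)
    P = np.array([[1 - pi12, pi12], [pi21, 1 - pi21]])
    total = 0.0
    for path in itertools.product([0, 1], repeat=T):
        if path[0] != 0:
            continue
        p = emission_pdf_scipy(Y[0], 0, em)
        for t in range(1, T):
            p *= P[path[t - 1], path[t]] * emission_pdf_scipy(Y[t], path[t], em)
        total += p
    return np.log(total)


def enumerate_viterbi(Y, em, pi12, pi21):
    """Exact most-probable path by enumeration (ties toward state 0
    via lexicographic order of the product iterator)."""
    T = len(Y)
    P = np.array([[1 - pi12, pi12], [pi21, 1 - pi21]])
    best_lp, best_path = -np.inf, None
    for path in itertools.product([0, 1], repeat=T):
        if path[0] != 0:
            continue
        p = emission_pdf_scipy(Y[0], 0, em)
        for t in range(1, T):
            p *= P[path[t - 1], path[t]] * emission_pdf_scipy(Y[t], path[t], em)
        lp = np.log(p) if p > 0 else -np.inf
        if lp > best_lp:
            best_lp, best_path = lp, path
    return best_lp, best_path


def ode_concentration(dose_events, cl, v, ka, t_eval):
    """One-compartment first-order absorption concentration by stiff ODE
    integration with bolus depot inputs."""
    ke = cl / v
    t_eval = np.atleast_1d(np.asarray(t_eval, dtype=float))
    events = sorted((td, amt) for td, amt, *_ in dose_events)
    out = np.zeros_like(t_eval)
    state = np.array([0.0, 0.0])  # depot, central amounts
    t_now = 0.0
    points = sorted(set([td for td, _ in events]) | set(t_eval.tolist()))
    for tp in points:
        if tp > t_now:
            sol = solve_ivp(
                lambda t, yy: [-ka * yy[0], ka * yy[0] - ke * yy[1]],
                (t_now, tp),
                state,
                rtol=1e-10,
                atol=1e-12,
            )
            state = sol.y[:, -1]
            t_now = tp
        for td, amt in events:
            if td == tp:
                state = state + np.array([amt, 0.0])
        hit = np.isclose(t_eval, tp)
        # dose at exactly a sampling time: sample is pre-absorption
        out[hit] = state[1] / v
    return out if out.size > 1 else float(out[0])
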