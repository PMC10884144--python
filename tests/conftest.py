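import numpy as np
import pytest

from adahmm import EmissionParams, TransitionParams

# Final-model parameter values used as generating truth throughout the
# suite: PK-residual modes 0.3 / -1.6, ADA modes anchored at the assay
# LLOQ (0.6 U/mL) and the clinical threshold (2.4 U/mL), shared
# variances 0.8 / 1.6, correlations -0.1 / -0.07, per-record transition
# probabilities 0.03 (onset) and 0.003 (reversion).
GEN_EMISSION = dict(
    mu_pkres_noada=0.3,
    mu_pkres_ada=-1.6,
    mu_ada_noada=0.6,
    mu_ada_ada=2.4,
    sigma2_pkres=0.8,
    sigma2_ada=1.6,
    rho_noada=-0.1,
    rho_ada=-0.07,
)
GEN_PI12 = 0.03
GEN_PI21 = 0.003


@pytest.fixture(scope="session")
def gen_emission() -> EmissionParams:
    return EmissionParams(**GEN_EMISSION)


@pytest.fixture(scope="session")
def gen_transition() -> TransitionParams:
    return TransitionParams.from_probs(GEN_PI12, GEN_PI21)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20230911)
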