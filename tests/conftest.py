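"""Shared fixtures: the default model (session-scoped; its construction is
deterministic) and a small one-filter model for cheap oracle tests."""

import numpy as np
import pytest

from eisampler.parameters import (
    GaborBankSpec,
    GSMParams,
    NetworkParams,
    build_gabor_bank,
    build_mass_matrix,
    build_prior_covariance,
    default_model,
)


@pytest.fixture(scope="session")
def model():
    """(gsm, net) with all defaults: 15 filters, 24 px, tau 10 ms, tau_L 150 ms."""
    return default_model()


@pytest.fixture(scope="session")
def small_model():
    """A one-filter model on a 12 px patch: cheap, same code paths."""
    spec = GaborBankSpec(
        image_side=12,
        orientations=(0.0,),
        locations=((0.5, 0.5),),
        major_axis_sds=(0.3,),
    )
    A = build_gabor_bank(spec)
    C = build_prior_covariance(A, 0.1)
    gsm = GSMParams(A=A, C=C, sigma_x_sq=0.1)
    net = NetworkParams.from_mass(build_mass_matrix(A))
    return gsm, net


@pytest.fixture
def rng():
    return np.random.default_rng(0)
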