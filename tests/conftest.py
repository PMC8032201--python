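"""Shared fixtures: limit cycles and PRCs are expensive, so they are located
once per session and reused across test modules."""

import numpy as np
import pytest

import slowphase as sp
from slowphase.models import MODEL_DEFAULTS


@pytest.fixture(scope="session")
def phenomenor():
    return sp.get_model("phenomenor")


@pytest.fixture(scope="session")
def phenomenor_lc(phenomenor):
    d = MODEL_DEFAULTS["phenomenor"]
    return sp.find_limit_cycle(
        phenomenor, sp.PoincareSection(*d["section"]), d["guess"]
    )


@pytest.fixture(scope="session")
def epileptor_p0():
    return sp.get_model("epileptor", "P0")


@pytest.fixture(scope="session")
def epileptor_p0_lc(epileptor_p0):
    d = MODEL_DEFAULTS["epileptor"]
    return sp.find_limit_cycle(
        epileptor_p0, sp.PoincareSection(*d["section"]), d["guess"]
    )


@pytest.fixture(scope="session")
def fixture_osc():
    return sp.make_fixture_oscillator(20.0)


@pytest.fixture(scope="session")
def fixture_lc(fixture_osc):
    d = MODEL_DEFAULTS["fixture"]
    return sp.find_limit_cycle(
        fixture_osc, sp.PoincareSection(*d["section"]), d["guess"]
    )


@pytest.fixture(scope="session")
def pheno_iprc(phenomenor, phenomenor_lc):
    return sp.compute_iprc(phenomenor_lc, phenomenor, n_theta=32)


@pytest.fixture(scope="session")
def pheno_prc_025(phenomenor, phenomenor_lc):
    """Phenomenor PRC at A = 0.25 on 64 phases (shared by several checks)."""
    return sp.prc_continuation(
        phenomenor_lc, phenomenor, 0.25, n_theta=64, delta_A=0.25 / 8,
        int_tol=1e-11, refine_near_discontinuity=6,
    )


@pytest.fixture(scope="session")
def p0_prc_05(epileptor_p0, epileptor_p0_lc):
    """Reduced-epileptor P0 PRC at A = 0.5 on 64 phases."""
    return sp.prc_continuation(
        epileptor_p0_lc, epileptor_p0, 0.5, n_theta=64, delta_A=0.5 / 8,
        int_tol=1e-11, refine_near_discontinuity=6,
    )
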