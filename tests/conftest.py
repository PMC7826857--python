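"""Shared fixtures: a reduced-size cell for fast stochastic runs and a
small parameter set for event-level reference tests."""

from __future__ import annotations

import numpy as np
import pytest

from stocellator import (
    CellState,
    ConstructDesign,
    ModelParameters,
    test_scale_config,
)


@pytest.fixture(scope="session")
def test_cfg():
    """The packaged reduced-size cell used for all simulation-level tests."""
    return test_scale_config()


@pytest.fixture()
def mini_params():
    """A tiny cell for pure-Python event stepping (small counts, short
    transcripts) — not a realistic operating point, just fast."""
    return ModelParameters(
        n=20.0, s_ext=1e4,
        w={"R": 0.5, "ET": 0.5, "EM": 0.5, "Q": 1.0, "H": 0.5},
        theta={c: 10.0 for c in ("R", "ET", "EM", "Q", "H")},
        b={c: 0.02 for c in ("R", "ET", "EM", "Q", "H")},
        length={"R": 12, "ET": 6, "EM": 6, "Q": 6, "H": 6},
        K_q=200.0, h_q=2.0, d_m=0.1, gamma_max=30.0, K_gamma=20.0,
        v_t=0.5, K_t=1000.0, v_m=0.5, K_m=100.0, M=5000.0,
    )


@pytest.fixture()
def mini_design(mini_params):
    return ConstructDesign(
        promH=1.0, RBSH=1.0,
        codon_profile=np.ones(mini_params.length["H"]))


@pytest.fixture()
def mini_state(mini_params):
    return CellState(
        s_i=50, a=500, r_free=30,
        m_free={"R": 2, "ET": 2, "EM": 2, "Q": 4, "H": 2},
        p={"R": 30, "ET": 40, "EM": 40, "Q": 120, "H": 10},
    )


class GammaStub:
    """Parameter stub giving gamma(a) == 1 for a == 1 (unit hop rate)."""

    gamma_max = 2.0
    K_gamma = 1.0


@pytest.fixture()
def unit_gamma():
    return GammaStub()
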