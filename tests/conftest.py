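"""Shared fixtures: the four full aggregation runs used across the suite.

The runs use the study conditions (L = 6, T = 25, h = 0.01, dt_outer = 0.01,
41 inner substeps, F = 1, r = 1, a = 1, uniform initial density 5) and are
session-scoped because each takes a few seconds.
"""

import numpy as np
import pytest

from adhesim.macro import MacroConfig, solve_ibvp


def _table_run(D0, delta, chi0, theta):
    cfg = MacroConfig(D0=D0, delta=delta, chi0=chi0, theta=theta, T=25.0,
                      mode="parabolic")
    return solve_ibvp(cfg, snapshot_stride=10)


@pytest.fixture(scope="session")
def run_weak_diffusion():
    """D0=0.15, delta=0, chi0=0.5, theta=1: the three-aggregate regime."""
    return _table_run(0.15, 0.0, 0.5, 1)


@pytest.fixture(scope="session")
def run_weak_diffusion_strong_adhesion():
    """D0=0.15, delta=0, chi0=1, theta=1: doubled adhesion sensitivity."""
    return _table_run(0.15, 0.0, 1.0, 1)


@pytest.fixture(scope="session")
def run_moderate_diffusion():
    """D0=3, delta=0, chi0=0.5, theta=1."""
    return _table_run(3.0, 0.0, 0.5, 1)


@pytest.fixture(scope="session")
def run_heterogeneous_diffusion():
    """D0=3, delta=1, chi0=0.5, theta=1: symmetry-breaking diffusion gradient."""
    return _table_run(3.0, 1.0, 0.5, 1)
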