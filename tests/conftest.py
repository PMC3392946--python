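"""Shared fixtures.

The long current-clamp runs (4 s burn-in + 5 s step) are session-scoped and
shared between the analysis, buffering and acceptance tests; everything is
deterministic so sharing is safe.
"""

import warnings

import pytest

from fsneuron import (BufferScheme, ModelParameters, default_rates,
                      equilibrate, run_plateau_protocol)


@pytest.fixture(scope="session")
def params():
    return ModelParameters()


@pytest.fixture(scope="session")
def rates():
    return default_rates()


def _plateau(params, scheme):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return run_plateau_protocol(params, scheme, amplitude=100.0,
                                    duration=5000.0)


@pytest.fixture(scope="session")
def pv1000_run(params):
    """5 s, 100 pA step with PV at 1000 uM -> (trajectory, spikes)."""
    return _plateau(params, BufferScheme.pv(1000.0))


@pytest.fixture(scope="session")
def pv50_run(params):
    """5 s, 100 pA step with PV at 50 uM."""
    return _plateau(params, BufferScheme.pv(50.0))


@pytest.fixture(scope="session")
def bt0_run(params):
    """5 s, 100 pA step without buffer."""
    return _plateau(params, BufferScheme.none())


@pytest.fixture(scope="session")
def pv1500_run(params):
    """5 s, 100 pA step with PV at 1500 uM."""
    return _plateau(params, BufferScheme.pv(1500.0))


@pytest.fixture(scope="session")
def rest_state(params):
    """State after the standard 4 s stimulus-free burn-in (PV 1000 uM)."""
    return equilibrate(params, BufferScheme.pv(1000.0))
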