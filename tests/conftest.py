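"""Shared fixtures: small synthetic sessions reused across test modules."""

from __future__ import annotations

import dataclasses

import pytest

from leechdendro.synth import SimulatorConfig, simulate_session


@pytest.fixture(scope="session")
def repertoire_session():
    """A 1200 s session mixing crawling, swimming and rest (seed 11)."""
    cfg = SimulatorConfig(session_duration=1200.0, seed=11)
    return simulate_session(
        cfg, {"crawling": 0.35, "swimming": 0.2, "stationary": 0.45}
    )


@pytest.fixture(scope="session")
def plain_config():
    """Config with the doubly-stochastic envelopes disabled: spike trains
    are then homogeneous Poisson within each behavior phase."""
    return SimulatorConfig(
        session_duration=600.0,
        seed=7,
        movement_envelope_sd=0.0,
        movement_tonic_rate=0.0,
        rest_envelope_sd=0.0,
        rest_drift_sd=0.0,
    )


@pytest.fixture(scope="session")
def plain_crawl_session(plain_config):
    return simulate_session(plain_config, {"crawling": 0.5, "stationary": 0.5})


def replace_config(config, **kwargs):
    return dataclasses.replace(config, **kwargs)
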