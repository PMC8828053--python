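"""Shared fixtures: small simulated cohorts reused across test modules."""

import numpy as np
import pytest

from cosmofret.kinetics import simulate_experiment
from cosmofret.params import ExperimentDesign, FrameTiming, KineticParams
from cosmofret.pipeline import RunConfig, cmd_analyze, cmd_simulate


@pytest.fixture(scope="session")
def fig1_small():
    """A 150-DNA baseline OM-reporter run with analyses and events."""
    cfg = RunConfig.from_preset("fig1", n_dna=150, seed=42, bleaching=False)
    ts = cmd_simulate(cfg)
    analyses, events = cmd_analyze(ts, cfg)
    return cfg, ts, analyses, events


@pytest.fixture(scope="session")
def wt_trajectories():
    """Kinetics-only wild-type cohort (no rendering) for invariant checks."""
    params = KineticParams()
    design = ExperimentDesign(n_dna=400)
    return params, design, simulate_experiment(params, design, rng_seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture()
def timing():
    return FrameTiming()
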