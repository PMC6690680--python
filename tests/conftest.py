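"""Shared fixtures.

The expensive study artifacts (scaled population, feature table, trained
networks, baseline reference cables) are session-scoped so the acceptance
tests share one computation.
"""

import numpy as np
import pytest

from epom.cell_model import (
    IschemiaSpec,
    PacingProtocol,
    ParameterSet,
    pace_cell,
    steady_state,
)
from epom.pipeline import (
    RunConfig,
    build_feature_table,
    cable_biomarkers,
    region_size_sweep,
    train_networks,
)
from epom.population import build_control_epom

#: reduced-scale study conditions used by the acceptance suite
SCALED_N = 2000
SCALED_MODELS = 150
SEED = 123


@pytest.fixture(scope="session")
def baseline():
    return ParameterSet.baseline()


@pytest.fixture(scope="session")
def baseline_trace_600(baseline):
    return pace_cell(baseline, IschemiaSpec.control(),
                     PacingProtocol(cl=600.0, n_beats=200))


@pytest.fixture(scope="session")
def baseline_trace_430(baseline):
    return pace_cell(baseline, IschemiaSpec.control(),
                     PacingProtocol(cl=430.0, n_beats=200))


@pytest.fixture(scope="session")
def scaled_config(tmp_path_factory):
    return RunConfig(
        n_samples=SCALED_N, seed=SEED, max_models=SCALED_MODELS,
        warm_start=True, cable_beats=3, cable_dt=0.05,
        ann_epochs=8000, ann_seed=SEED,
        out_dir=str(tmp_path_factory.mktemp("study")),
    )


@pytest.fixture(scope="session")
def scaled_population(scaled_config):
    return build_control_epom(scaled_config.n_samples, seed=scaled_config.seed,
                              convention=scaled_config.convention)


@pytest.fixture(scope="session")
def feature_table(scaled_population, scaled_config):
    return build_feature_table(scaled_population, scaled_config)


@pytest.fixture(scope="session")
def ml_results(feature_table, scaled_config):
    return train_networks(feature_table, scaled_config)


@pytest.fixture(scope="session")
def baseline_cables(baseline):
    """Cold-start 30-beat reference cables of the baseline model."""
    cold = RunConfig(warm_start=False, cable_beats=30, cable_dt=0.02)
    return {
        label: cable_biomarkers(baseline, IschemiaSpec.preset(label),
                                2.0, cold)
        for label in ("control", "mild", "severe")
    }


@pytest.fixture(scope="session")
def baseline_sweep(baseline):
    """Region-size sweep of the baseline model (warm scaled protocol)."""
    cfg = RunConfig(warm_start=True, cable_beats=3, cable_dt=0.05)
    ss = steady_state(baseline, IschemiaSpec.control(),
                      PacingProtocol(cl=600.0, n_beats=200), dt=0.1)
    return region_size_sweep(baseline, cfg, zones=(0.5, 1.0, 1.5, 2.0),
                             control_state=ss)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
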