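import numpy as np
import pytest

import interbrain as ib


@pytest.fixture(scope="session")
def grid_small():
    """Compact grid for fast transform tests (dt = 1 s)."""
    return ib.build_scale_grid(0.02, 0.2, 6, dt=1.0)


@pytest.fixture(scope="session")
def grid_study():
    """The study grid: 12 voices/octave over 3.9-289.4 mHz at TR 1.5 s."""
    return ib.build_scale_grid(0.0039, 0.2894, 12, dt=1.5)


@pytest.fixture(scope="session")
def tiny_config():
    """Desk-scale cohort: 4 dyads, 3 ROIs, short runs, coupling in one cell."""
    return ib.SimulationConfig(
        n_dyads=4,
        n_rois=3,
        n_volumes_per_run=240,
        trial_count_per_block=4,
        coupling=(
            ib.CouplingSpec(
                rois=(1,),
                conditions=("cooperation",),
                band=(0.08, 0.15),
                amplitude=1.5,
            ),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return ib.simulate_cohort(tiny_config)


@pytest.fixture(scope="session")
def tiny_result(tiny_cohort):
    dyads, events, _ = tiny_cohort
    analysis = ib.AnalysisConfig(band_override=(0.08, 0.15), seed=7)
    return ib.analyze_cohort(dyads, events, analysis)
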