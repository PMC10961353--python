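import numpy as np
import pytest

from hdnirs.montage import (
    build_default_montage,
    default_geometry_config,
    reduced_geometry_config,
)
from hdnirs.synth import ScheduleSpec, generate_schedule, simulate_session


@pytest.fixture(scope="session")
def default_montage():
    return build_default_montage()


@pytest.fixture(scope="session")
def reduced_montage():
    """One tile per hemisphere (48 wavelength-resolved channels <= 50 mm)."""
    return build_default_montage(reduced_geometry_config())


@pytest.fixture(scope="session")
def small_montage():
    """Two tiles per hemisphere stacked vertically: has intra-hemisphere
    channels above 25 mm while staying desk-scale."""
    return build_default_montage(default_geometry_config(n_tile_cols=1,
                                                         n_tile_rows=2))


@pytest.fixture(scope="session")
def short_spec():
    """Desk-scale schedule: 2 blocks x 10 trials, 1-min baseline."""
    return ScheduleSpec(n_blocks=2, trials_per_block=10, baseline_s=60.0)


@pytest.fixture(scope="session")
def make_session(reduced_montage, short_spec):
    """Factory for short simulated sessions on the reduced montage."""

    def _make(seed=0, session_number=2, montage=None, spec=None, **kwargs):
        montage = montage if montage is not None else reduced_montage
        spec = spec or short_spec
        markers = generate_schedule(spec, session_number, seed)
        return simulate_session(montage, markers, seed=seed + 10_000,
                                session_number=session_number, **kwargs)

    return _make
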