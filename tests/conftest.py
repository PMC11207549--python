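import numpy as np
import pytest

from coactmap import (
    Direction,
    Effort,
    EmgRecording,
    Knee,
    Montage,
    Muscle,
    TrialMeta,
    gm_grid,
)


@pytest.fixture
def gm():
    return gm_grid()


@pytest.fixture
def meta_antag():
    return TrialMeta("S01", Muscle.GM, Knee.FLEXED_90, Effort.SUBMAX_30, Direction.DORSIFLEXION)


@pytest.fixture
def meta_mvc():
    return TrialMeta("S01", Muscle.GM, Knee.FLEXED_90, Effort.MAX_100, Direction.PLANTARFLEXION)


def make_recording(grid, samples, meta, fs_hz=2048.0, montage=Montage.MONOPOLAR):
    """Build a recording with validity derived from the grid's missing set."""
    valid = np.ones(grid.n_positions, dtype=bool)
    for r, c in grid.missing:
        valid[grid.channel_index(r, c)] = False
    return EmgRecording(
        grid=grid, samples=samples, fs_hz=fs_hz, montage=montage, valid=valid, meta=meta
    )


@pytest.fixture
def make_rec():
    return make_recording
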