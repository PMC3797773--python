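import warnings

import numpy as np
import pytest

from palmcell import synthetic as syn

warnings.filterwarnings("ignore", category=UserWarning)
warnings.filterwarnings("ignore", message=".*Covariance of the parameters.*")


@pytest.fixture(scope="session")
def three_cell_scene():
    """One cell per cell-cycle stage, rendered once for the whole session."""
    specs = [
        syn.CellSpec(length_nm=3100, width_nm=800, septum_rel_pos=0.2, septum_openness=0.3),
        syn.CellSpec(length_nm=4000, width_nm=800, septum_rel_pos=0.5, septum_openness=0.3),
        syn.CellSpec(length_nm=2500, width_nm=800),
    ]
    return syn.gen_cell_scene(specs, seed=11)


@pytest.fixture(scope="session")
def demo_field():
    """The canonical two-cluster localization field."""
    return syn.gen_demo_field(seed=3)


@pytest.fixture(scope="session")
def homogeneous_beads():
    """7 fiducials with a common 200 nm drift and 5 nm noise, 2000 frames."""
    return syn.gen_bead_tracks(
        7, 2000, {"mode": "homogeneous", "total_drift_nm": 200.0}, noise_nm=5.0, seed=7
    )


def rng(seed=0):
    return np.random.default_rng(seed)
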