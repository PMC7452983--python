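import numpy as np
import pytest

from linguavol.geometry import LandmarkSet
from linguavol.phantoms import GroundTruth, PhantomSpec, make_oral_phantom, simulate_scan

#: coarse spacing used for fast end-to-end tests; measurement tolerances
#: are relaxed accordingly (the protocol spacing of 0.2/0.4 mm is used only
#: in the dedicated acceptance tests)
COARSE_SPACING = 0.8
COARSE_BLUR = 0.4


@pytest.fixture(scope="session")
def flat_landmarks() -> LandmarkSet:
    """Hand-placed landmark set with the occlusal plane at z = 0."""
    return LandmarkSet({
        "lower_first_molar_central_cusp_left": [20.0, 0.0, 0.0],
        "lower_first_molar_central_cusp_right": [-20.0, 0.0, 0.0],
        "incisal_edge_lower_right_central_incisor": [0.0, 35.0, 0.0],
        "upper_second_molar_distal_cusp_left": [25.0, -40.0, 2.0],
        "upper_second_molar_distal_cusp_right": [-25.0, -40.0, 2.0],
        "lingual_frenulum": [0.0, 20.0, -12.0],
    })


@pytest.fixture(scope="session")
def oral_phantom():
    """Default oral phantom at coarse spacing: (grid, landmarks, truth)."""
    spec = PhantomSpec(kind="oral", spacing_mm=COARSE_SPACING)
    return make_oral_phantom(spec, seed=101)


@pytest.fixture(scope="session")
def oral_scan(oral_phantom):
    """The same phantom after simulated scanning (blur + 5% noise)."""
    grid, landmarks, truth = oral_phantom
    scanned = simulate_scan(grid, COARSE_BLUR, 5.0, seed=202)
    return scanned, landmarks, truth


def random_landmarks(rng: np.random.Generator) -> LandmarkSet:
    """Random but anatomically-ordered landmark set for property tests."""
    while True:
        pts = {
            "lower_first_molar_central_cusp_left": rng.uniform([10, -10, -3], [25, 10, 3]),
            "lower_first_molar_central_cusp_right": rng.uniform([-25, -10, -3], [-10, 10, 3]),
            "incisal_edge_lower_right_central_incisor": rng.uniform([-5, 25, -3], [5, 45, 3]),
            "upper_second_molar_distal_cusp_left": rng.uniform([10, -45, -2], [28, -30, 6]),
            "upper_second_molar_distal_cusp_right": rng.uniform([-28, -45, -2], [-10, -30, 6]),
            "lingual_frenulum": rng.uniform([-5, 10, -20], [5, 25, -8]),
        }
        lm = LandmarkSet(pts)
        a = lm["lower_first_molar_central_cusp_left"]
        b = lm["lower_first_molar_central_cusp_right"]
        c = lm["incisal_edge_lower_right_central_incisor"]
        if np.linalg.norm(np.cross(b - a, c - a)) > 1.0:
            return lm
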