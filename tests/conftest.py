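import numpy as np
import pytest

from papvrscore import Landmark, LandmarkName, PatientAnatomy


def make_anatomy(pv, svd, azygos, patient_id="p1"):
    return PatientAnatomy(
        patient_id=patient_id,
        landmarks=(
            Landmark(LandmarkName.PV_CRANIAL_SUPERIOR_RIM, pv),
            Landmark(LandmarkName.SVD_SUPERIOR_RIM, svd),
            Landmark(LandmarkName.AZYGOS_INFERIOR_RIM, azygos),
        ),
    )


@pytest.fixture
def triangle_anatomy():
    """PV at origin, SVD 5 mm away (3-4-5 triangle), azygos 10 mm away."""
    return make_anatomy([0, 0, 0], [3, 4, 0], [0, 0, 10])


@pytest.fixture
def annotation_text():
    return (
        "# synthetic landmark annotation\n"
        "patient_id p1\n"
        "landmark PV_CRANIAL_SUPERIOR_RIM 0 0 0\n"
        "landmark SVD_SUPERIOR_RIM 0 0 10\n"
        "landmark AZYGOS_INFERIOR_RIM 0 0 25\n"
    )


def random_anatomy(rng, scale=30.0, patient_id="r1"):
    pts = rng.uniform(-scale, scale, size=(3, 3))
    while min(
        np.linalg.norm(pts[0] - pts[1]),
        np.linalg.norm(pts[0] - pts[2]),
        np.linalg.norm(pts[1] - pts[2]),
    ) < 1e-3:
        pts = rng.uniform(-scale, scale, size=(3, 3))
    return make_anatomy(pts[0], pts[1], pts[2], patient_id=patient_id)
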