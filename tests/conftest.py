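import numpy as np
import pytest

from kneealign.geometry import LandmarkSet, RigidTransform, random_transform
from kneealign.phantom import PhantomSpec, simulate_case


@pytest.fixture(scope="session")
def still_case():
    """Zero-noise phantom with no CT-frame offset (the identity path)."""
    spec = PhantomSpec(seed=2, noise_sd=0.0, fiducial_noise_sd=0.0,
                       ct_offset=RigidTransform.identity())
    return simulate_case(spec)


@pytest.fixture(scope="session")
def offset_case():
    """Zero-noise phantom with the default 10 deg / 20 mm CT offset."""
    spec = PhantomSpec(seed=3, noise_sd=0.0, fiducial_noise_sd=0.0)
    return simulate_case(spec)


@pytest.fixture(scope="session")
def noisy_case():
    """Default study conditions: 0.3 mm vertex / 0.2 mm fiducial noise."""
    return simulate_case(PhantomSpec(seed=1))


def canonical_femur_landmarks(side: str = "right") -> LandmarkSet:
    s = 1.0 if side == "right" else -1.0
    return LandmarkSet("femur", side, {
        "hip_centre": (0.0, 0.0, 400.0),
        "knee_centre": (0.0, 0.0, 0.0),
        "medial_sulcus": (-40.0 * s, 0.0, 0.0),
        "lateral_epicondyle": (40.0 * s, 0.0, 0.0),
    })


def canonical_tibia_landmarks(side: str = "right") -> LandmarkSet:
    s = 1.0 if side == "right" else -1.0
    return LandmarkSet("tibia", side, {
        "medial_malleolus": (-20.0 * s, 0.0, -350.0),
        "lateral_malleolus": (20.0 * s, 0.0, -350.0),
        "tubercle_medial_third": (0.0, 30.0, 2.0),
        "pcl_insertion": (0.0, -30.0, -2.0),
        "plateau_centre": (0.0, 0.0, 0.0),
    })


def random_landmarks(rng: np.random.Generator, bone: str, side: str) -> LandmarkSet:
    """A random valid landmark set: canonical geometry under a random
    rigid transform plus small independent jitter."""
    base = canonical_femur_landmarks(side) if bone == "femur" else canonical_tibia_landmarks(side)
    t = random_transform(rng)
    return LandmarkSet(bone, side, {
        k: t.apply(v) + rng.normal(0, 2.0, 3) for k, v in base.landmarks.items()
    })


def report_errors(report, ground_truth):
    """(max angle, max translation, max resection) absolute errors of a
    pipeline report against phantom ground truth."""
    ea = et = 0.0
    for comp in ("femoral", "tibial"):
        m = report.components[comp]
        ea = max(ea, np.max(np.abs(np.array([m.fe, m.vv, m.ie])
                                   - np.array(ground_truth.angles[comp]))))
        et = max(et, np.max(np.abs(np.array([m.ap, m.ml, m.si])
                                   - np.array(ground_truth.translations[comp]))))
    er = max(abs(report.resections[k] - ground_truth.resections[k])
             for k in ground_truth.resections)
    return ea, et, er
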