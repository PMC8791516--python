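import numpy as np
import pytest

from capnet.simulate import (
    DEFAULT_PRESETS,
    CohortConfig,
    NoiseModel,
    VesselNetworkTruth,
    generate_capillary_network,
    generate_cohort,
    rasterize_angiogram,
)

SIDE = 128  # small field keeps image tests fast; geometry scales with side


@pytest.fixture(scope="session")
def control_preset():
    return DEFAULT_PRESETS["control"]


@pytest.fixture(scope="session")
def small_truth(control_preset):
    return generate_capillary_network(SIDE, control_preset, seed=11)


@pytest.fixture(scope="session")
def small_render(small_truth):
    img, mask, skel = rasterize_angiogram(small_truth, seed=11)
    return img, mask, skel


@pytest.fixture(scope="session")
def noiseless_render(small_truth):
    img, mask, skel = rasterize_angiogram(small_truth, NoiseModel(0.0, 0.0), seed=11)
    return img, mask, skel


@pytest.fixture(scope="session")
def cohort1_df():
    df = generate_cohort(CohortConfig.cohort1(seed=42))
    df["male"] = (df["sex"] == "M").astype(int)
    return df


def bar_truth(side=245, width=3.0, row=60):
    """Single straight horizontal vessel spanning the field."""
    return VesselNetworkTruth(
        segments=[[np.array([row, 0.0]), np.array([row, side - 1.0])]],
        widths=[width],
        faz_radius=0.0,
        image_side=side,
        true_skeleton_pixels=side,
        true_mean_width=width,
    )
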