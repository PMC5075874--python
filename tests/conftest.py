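import numpy as np
import pytest

from wormchip.segmentation import extract_components, fit_area_model, mask_worms
from wormchip.synthetic import ClusterSpec, SceneSpec, render_scene


@pytest.fixture(scope="session")
def pair_scene():
    """A side-touching pair plus five isolated worms, with ground truth."""
    spec = SceneSpec(
        n_worms=7, seed=23,
        cluster_plan=(ClusterSpec((0, 1), "side_touch"),),
    )
    bf, fl, gt = render_scene(spec)
    return spec, bf, fl, gt


@pytest.fixture(scope="session")
def calibrated_pair_scene(pair_scene):
    """The pair scene with mask, components and fitted area model."""
    spec, bf, fl, gt = pair_scene
    mask = mask_worms(bf)
    comps = extract_components(mask, bf.darkness)
    model = fit_area_model(comps)
    return spec, bf, gt, mask, comps, model


def iou(a: np.ndarray, b: np.ndarray) -> float:
    inter = np.logical_and(a, b).sum()
    union = np.logical_or(a, b).sum()
    return inter / union if union else 0.0


@pytest.fixture
def rod_mask():
    """A 100x10 horizontal rod with rounded ends, in a 140x60 canvas."""
    mask = np.zeros((60, 140), dtype=bool)
    rr, cc = np.mgrid[0:60, 0:140]
    for x in np.linspace(25, 115, 91):
        mask |= (rr - 30) ** 2 + (cc - x) ** 2 <= 25
    return mask
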