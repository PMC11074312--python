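import numpy as np
import pytest

from switchquant import synth


@pytest.fixture(scope="session")
def colony_fixture():
    """One tight-mode colony image with 100 nuclei and its ground truth."""
    colony = synth.ColonyParams(
        n_colonies=5, nuclei_per_colony=(20, 0), packing_mode="tight", seed=7
    )
    expr = synth.ExpressionParams(seed=7)
    stack, truth = synth.generate_colony_image(colony, expr)
    return colony, expr, stack, truth


@pytest.fixture(scope="session")
def fish_fixture():
    """A large-nucleus label image plus a 20-spots-per-cell stack at SNR 10."""
    colony = synth.ColonyParams(
        n_colonies=1,
        nuclei_per_colony=(10, 0),
        nucleus_radius_px=(28, 2),
        image_shape_px=(640, 640),
        seed=2,
    )
    _, truth = synth.generate_colony_image(colony, synth.ExpressionParams(seed=2))
    labels = synth.ground_truth_labels(truth, colony.image_shape_px)
    spots = synth.SpotParams(n_spots_per_cell=(20, 0), seed=2)
    stack, spot_truth = synth.generate_spot_stack(labels, spots)
    return labels, stack, spot_truth


def match_spots(detected: np.ndarray, true: np.ndarray, radius: float = 2.0) -> int:
    """Number of one-to-one detected/true pairs within the match radius."""
    from scipy.optimize import linear_sum_assignment

    if len(detected) == 0 or len(true) == 0:
        return 0
    dist = np.linalg.norm(detected[:, None, :] - true[None, :, :], axis=2)
    ri, ci = linear_sum_assignment(dist)
    return int((dist[ri, ci] <= radius).sum())
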