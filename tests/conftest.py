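import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from stalktraits import synthgen


@pytest.fixture(scope="session")
def default_image():
    """One rendered cross-section at the default study conditions."""
    spec = synthgen.ImageSpec(seed=7)
    image, truth = synthgen.render_section_image(spec)
    return spec, image, truth


@pytest.fixture(scope="session")
def noiseless_image():
    spec = synthgen.ImageSpec(seed=3, noise_sd=0.0)
    image, truth = synthgen.render_section_image(spec)
    return spec, image, truth


def match_bundles(truth, fits, tol_cm=0.05):
    """One-to-one assignment of converged fits to ground-truth bundles.

    Returns (recall, precision, per-match relative area errors at the
    FWHM rim).
    """
    converged = [f for f in fits if f.converged]
    true_centers = truth.bundle_centers()
    if not converged or len(true_centers) == 0:
        return 0.0, 0.0, []
    det_centers = np.array([f.center_cm for f in converged])
    det_areas = np.array([f.area_cm2 for f in converged])
    true_areas = truth.bundle_areas_cm2(converged[0].rim_fraction)
    dist = np.sqrt(
        ((det_centers[:, None, :] - true_centers[None, :, :]) ** 2).sum(-1)
    )
    rows, cols = linear_sum_assignment(dist)
    pairs = [(i, j) for i, j in zip(rows, cols) if dist[i, j] <= tol_cm]
    recall = len(pairs) / len(true_centers)
    precision = len(pairs) / len(converged)
    area_errors = [abs(det_areas[i] - true_areas[j]) / true_areas[j] for i, j in pairs]
    return recall, precision, area_errors
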