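"""Shared fixtures: small synthetic scenes used across test modules."""

import numpy as np
import pytest

from synei import fdt, synthetic as sy


@pytest.fixture(scope="session")
def separated_scene():
    """A well-separated high-SNR two-channel scene with known ground truth."""
    bright = sy.IntensityModel(mode=165.0, spread=8.0)
    spec = sy.FdtSceneSpec(shape=(14, 192, 192), n_puncta=50, n_blobs=0,
                           min_separation_factor=1.5, noise_sd=5.0,
                           exc_intensity=bright, inh_intensity=bright)
    stack, truth = sy.gen_fdt_stack(spec, 11)
    return spec, stack, truth


@pytest.fixture(scope="session")
def detected_separated(separated_scene):
    _, stack, truth = separated_scene
    norm = fdt.normalize_background(stack)
    pset = fdt.detect_puncta(norm)
    return pset, truth


def match_centroids(detected_um: np.ndarray, truth_um: np.ndarray,
                    tol_um: float) -> int:
    """Number of true objects with a detection within ``tol_um``."""
    from scipy.spatial import cKDTree
    if len(detected_um) == 0:
        return 0
    d, _ = cKDTree(detected_um).query(truth_um)
    return int((d < tol_um).sum())
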