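import logging

import numpy as np
import pytest

import dtpa

# the per-frame "no valid voxels" notices on the all-zero baseline frame are
# expected; keep test output readable
logging.getLogger("dtpa.toi_stats").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def small_series():
    """A small noise-free series with one off-center lesion, fast to analyze."""
    cfg = dtpa.PhantomConfig(
        grid=(1, 32, 32),
        tissues={
            "NAWM": dtpa.TissueParams(),
            "EL": dtpa.TissueParams(texture_sd=30.0, t0=6.5, leakage=600.0),
        },
        lesions=[((0, 20, 20), 4, "EL")],
        noise_sigma=0.0,
        seed=7,
    )
    return dtpa.simulate_phantom(cfg)


@pytest.fixture(scope="session")
def effect_run():
    """One full pipeline run on the effect phantom, shared across tests."""
    series, truth = dtpa.simulate_phantom(dtpa.effect_phantom_config(seed=11))
    result = dtpa.run_workflow(
        dtpa.RunConfig(), series=series, tois=truth.tois + [truth.reference_toi]
    )
    return series, truth, result


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def brute_force_moments(image: np.ndarray, w: int):
    """Naive per-voxel double loop over kernel windows (test oracle)."""
    h = (w - 1) // 2
    nr, nc = image.shape
    mean = np.zeros_like(image)
    m2 = np.zeros_like(image)
    m3 = np.zeros_like(image)
    m4 = np.zeros_like(image)
    valid = np.zeros(image.shape, dtype=bool)
    for r in range(h, nr - h):
        for c in range(h, nc - h):
            win = image[r - h : r + h + 1, c - h : c + h + 1].ravel()
            mu = win.mean()
            d = win - mu
            mean[r, c] = mu
            m2[r, c] = (d**2).mean()
            m3[r, c] = (d**3).mean()
            m4[r, c] = (d**4).mean()
            valid[r, c] = True
    return mean, m2, m3, m4, valid
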