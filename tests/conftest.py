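import numpy as np
import pytest

from mesochoice import axes as ax
from mesochoice import decompose as dc
from mesochoice import synth


@pytest.fixture(scope="session")
def atlas():
    return synth.make_atlas(shape=(32, 32), seed=0)


@pytest.fixture(scope="session")
def session_params():
    return synth.SessionParams()


@pytest.fixture(scope="session")
def session(atlas, session_params):
    """A small but full-featured synthetic session, shared across tests."""
    tensor, table = synth.simulate_session(
        atlas, synth.default_signal_spec(), session_params, 200, seed=11
    )
    return tensor, table


@pytest.fixture(scope="session")
def decomposition(atlas, session):
    tensor, _ = session
    n_trials = tensor.n_trials
    x = np.moveaxis(
        tensor.data.reshape(n_trials, -1, tensor.n_frames), 0, 1
    ).reshape(np.prod(atlas.shape), -1)
    masks = dc.make_seed_masks(atlas)
    with np.errstate(all="ignore"):
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            decomp = dc.loca_nmf(x, masks, atlas, n_trials, max_per_area=2, seed=0)
    return decomp, masks, x


def planted_blob_data(atlas, n_frames=120, noise_sd=0.0, seed=0):
    """Ten one-per-area planted spatial-temporal blobs, the NMF recovery fixture.

    Each area's spatial map is its (unit-normalized) mask; temporal courses
    are smooth positive-variance signals, independent across areas.
    """
    rng = np.random.default_rng(seed)
    n_pix = int(np.prod(atlas.shape))
    a_true = np.zeros((n_pix, atlas.n_areas))
    c_true = np.zeros((atlas.n_areas, n_frames))
    for k in range(atlas.n_areas):
        m = atlas.area_mask(k + 1).ravel().astype(float)
        a_true[:, k] = m / np.linalg.norm(m)
        raw = rng.normal(0.0, 1.0, n_frames)
        kern = np.ones(7) / 7.0
        c_true[k] = np.convolve(raw, kern, mode="same") + 2.0
    x = a_true @ c_true
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, x.shape)
    return x, a_true, c_true


@pytest.fixture(scope="session")
def blob_data(atlas):
    return planted_blob_data(atlas)
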