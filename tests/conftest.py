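import numpy as np
import pytest

import cadffnet as cf


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_synth_arrays(n, mode, seed, side=64, noise=0.02, label_range=(5.0, 95.0)):
    """Render n pairs straight to NCHW arrays (no PNG round trip)."""
    params = cf.LeafRenderParams(side_px=side, noise_sd=noise, mode=mode)
    rng = np.random.default_rng(seed)
    lo, hi = label_range
    front = np.empty((n, 3, side, side), np.float32)
    back = np.empty((n, 3, side, side), np.float32)
    labels = np.empty(n, np.float32)
    for i in range(n):
        if mode == "split":
            lf = rng.uniform(lo / 100, hi / 100)
            lb = rng.uniform(lo / 100, hi / 100)
            label = 50.0 * (lf + lb)
            sample = cf.render_pair(label, params, int(rng.integers(2**31)),
                                    latents=(lf, lb))
        else:
            label = rng.uniform(lo, hi)
            sample = cf.render_pair(label, params, int(rng.integers(2**31)))
        front[i] = sample.front.transpose(2, 0, 1)
        back[i] = sample.back.transpose(2, 0, 1)
        labels[i] = label
    return front, back, labels


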