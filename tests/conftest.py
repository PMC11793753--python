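import numpy as np
import pytest

import nucwrap as nw
from nucwrap import _kernels as K


@pytest.fixture
def dna_params():
    return nw.DNAParams()


@pytest.fixture
def hist_params():
    return nw.HistoneParams()


def random_chain(n, seed, displacement=0.5, twist=0.25):
    """Random perturbed chain with self-consistent transported frames."""
    rng = np.random.default_rng(seed)
    ch = nw.build_straight_chain(n, nw.DNAParams())
    ch.vertices = ch.vertices + rng.normal(scale=displacement,
                                           size=ch.vertices.shape)
    s = np.empty((n, 3))
    slen = np.empty(n)
    e = np.empty((n, 3))
    K.chain_tangents(ch.vertices, s, slen, e)
    K.transport_frames(ch.frames, e)
    for i in range(n):
        K.rotate_frame_about_e(ch.frames, i, rng.normal(scale=twist))
    return ch


def perturb_with_transport(chain, k, axis, h):
    """Move vertex k by h along axis, co-moving the material frames by
    parallel transport (the convention under which analytic forces are the
    energy gradient)."""
    n = chain.n_segments
    out = chain.copy()
    out.vertices[k, axis] += h
    s = np.empty((n, 3))
    slen = np.empty(n)
    e = np.empty((n, 3))
    K.chain_tangents(out.vertices, s, slen, e)
    K.transport_frames(out.frames, e)
    return out
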