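import numpy as np
import pytest

from spade_stp.fca import FormalContext
from spade_stp.spikes import SpikeTrainSet


def make_context(rows, n_attributes, K=None, n_neurons=1):
    """Build a FormalContext from per-object attribute-id lists."""
    indptr = np.concatenate([[0], np.cumsum([len(r) for r in rows])]).astype(np.int64)
    indices = (np.concatenate([sorted(r) for r in rows]).astype(np.int32)
               if any(len(r) for r in rows) else np.empty(0, dtype=np.int32))
    return FormalContext(indptr, indices, len(rows), n_attributes,
                         K=K or n_attributes, dt=1.0, n_neurons=n_neurons)


def random_context(rng, n_obj=8, n_attr=12, density=0.3):
    mat = rng.random((n_obj, n_attr)) < density
    rows = [list(np.nonzero(mat[t])[0]) for t in range(n_obj)]
    return make_context(rows, n_attr)


@pytest.fixture
def toy_context():
    """The 3-object context 1:{a,b}, 2:{a,b}, 3:{a,c} with a,b,c = 0,1,2."""
    return make_context([[0, 1], [0, 1], [0, 2]], 3)


@pytest.fixture
def worked_example():
    """Three-neuron spike data whose window t_A carries the full incidence
    set F, with the pattern H = first-neuron-at-0 / third-at-3 /
    second-at-6 occurring in windows t_A = 5 and t_B = 20, plus its
    one-bin-shifted copy Q in windows 4 and 19."""
    trains = SpikeTrainSet(
        [np.array([5.3, 7.3, 12.3, 20.3]),
         np.array([6.3, 9.3, 11.3, 22.3, 26.3]),
         np.array([5.3, 8.3, 11.3, 23.3])],
        t_start=0.0, t_stop=28.0)
    K = 8
    t_A, t_B = 5, 20
    F = {(0, 0), (0, 2), (0, 7), (1, 1), (1, 4), (1, 6), (2, 0), (2, 3), (2, 6)}
    H = {(0, 0), (1, 6), (2, 3)}
    Q = {(0, 1), (1, 7), (2, 4)}
    return dict(trains=trains, K=K, t_A=t_A, t_B=t_B, F=F, H=H, Q=Q)


def attr_ids(pairs, K):
    return tuple(sorted(n * K + o for n, o in pairs))
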