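"""The formal-context machinery on a tiny hand-checkable example.

Three windows with contents {a,b}, {a,b}, {a,c} give three non-trivial
concepts; the stability values below can be verified by enumerating subsets
by hand.
"""

import numpy as np

from spade_stp.fca import Concept, FormalContext
from spade_stp.mining import MiningConfig, brute_force_closed, mine_closed_frequent
from spade_stp.stability import stability_exact

indptr = np.array([0, 2, 4, 6])
indices = np.array([0, 1, 0, 1, 0, 2], dtype=np.int32)   # a,b | a,b | a,c
ctx = FormalContext(indptr, indices, n_objects=3, n_attributes=3,
                    K=3, dt=1.0, n_neurons=1)

cfg = MiningConfig(min_support=1, min_size=1, z_min=1, c_min=1)
for cc in mine_closed_frequent(ctx, cfg):
    si = stability_exact(ctx, cc, "intensional").value
    print(f"concept extent={cc.extent} intent={cc.intent} "
          f"(z={cc.z}, c={cc.c})  sigma_int={si}")
# ({0,1},{a,b}): 3 of 4 extent subsets re-derive the intent -> 0.75
# ({0,1,2},{a}): 3 of 8 -> 0.375 (singletons derive their full window)

assert mine_closed_frequent(ctx, cfg) == brute_force_closed(ctx)
print("miner output equals the exhaustive closure oracle")
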