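"""A small corner of the FP/FN validation matrix.

For each injected signature (z, c) the harness runs seeded realizations of
background + injection through the full pipeline and scores the output
strictly against ground truth (a sub- or super-pattern of the injected one
counts as a false positive).
"""

from spade_stp import RateModel, SpadeConfig
from spade_stp.validate import fp_fn_matrices

config = SpadeConfig(method="psf-psr", n_surrogates=100)
mats = fp_fn_matrices(RateModel(kind="stationary", rate=25.0), config,
                      z_range=[6, 10], c_range=[6, 10], R=3,
                      n_neurons=30, master_seed=0)
print("rows: occurrences c in", list(mats.c_values),
      " columns: size z in", list(mats.z_values))
print("FP rate (fraction of realizations with any spurious pattern):")
print(mats.fp_rate)
print("FN rate (fraction of realizations missing the injected pattern):")
print(mats.fn_rate)
# strong signatures (large z and c) should sit at 0/0
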