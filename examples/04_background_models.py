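"""The four background rate models used for validation.

Each model is a set of independent inhomogeneous Poisson processes
replicating a firing-rate feature of cortical data that tends to generate
false positives in correlation analysis.
"""

import numpy as np

from spade_stp import RateModel, generate_background

rng = np.random.default_rng(3)
models = {
    "stationary 25 Hz": RateModel(kind="stationary", rate=25.0),
    "coherent step (10->60 Hz in [600,700) ms)": RateModel(kind="coherent_step"),
    "heterogeneous (5..25 Hz across neurons)": RateModel(kind="heterogeneous"),
    "propagating 5 ms jumps (14->100 Hz)": RateModel(kind="propagation"),
}
for name, model in models.items():
    tr = generate_background(model, n_neurons=100, duration=1000.0, rng=rng)
    counts = tr.spike_counts()
    print(f"{name}: {tr.total_spikes()} spikes, "
          f"per-neuron mean {counts.mean():.1f} (min {counts.min()}, "
          f"max {counts.max()})")
# the mean count per neuron equals the integral of its rate profile:
# 25 for stationary 25 Hz, 0.9*10 + 0.1*60 = 15 for the coherent step
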