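"""Ground-truth data generation: Poisson backgrounds and STP injection.

Four families of background models are provided, chosen to replicate the
statistical features of cortical recordings that are notorious false-positive
generators for correlation analysis:

* ``stationary`` — N independent homogeneous Poisson processes at rate r
  (defaults r in {15, 20, 25} Hz, N = 100, T = 1 s);
* ``coherent_step`` — a sudden rate jump coherent across all neurons
  (10 Hz on [0, 600) and [700, 1000) ms, 60 Hz on [600, 700) ms);
* ``heterogeneous`` — stationary but different rates across neurons,
  5 Hz to 25 Hz in steps of 0.2 Hz;
* ``propagation`` — 20 groups of 5 neurons; each group jumps from 14 Hz
  baseline to 100 Hz for 5 ms, groups firing in sequence, with sweep onsets
  at 50 ms and 550 ms.

Injected spatio-temporal patterns are sequences of z spikes with a constant
inter-spike lag (default 5 ms) placed at c uniformly drawn onsets; the ground
truth (neurons, lags, onsets) is returned alongside the data so detection can
be scored strictly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spikes import SpikeTrainSet

__all__ = [
    "RateModel",
    "InjectionSpec",
    "GroundTruth",
    "generate_background",
    "inject_stp",
    "inject_multiple",
]


@dataclass
class RateModel:
    """Piecewise-constant firing-rate model for independent Poisson trains.

    ``profiles(N, T)`` expands the model into per-neuron segment lists
    ``[(t0, t1, rate_hz), ...]`` covering [0, T) ms.
    """

    kind: str = "stationary"
    rate: float = 25.0          # stationary: constant rate (Hz)
    step_rates: tuple = (10.0, 60.0)       # coherent_step: base, jump (Hz)
    step_interval: tuple = (600.0, 700.0)  # coherent_step: jump interval (ms)
    hetero_range: tuple = (5.0, 0.2)       # heterogeneous: start (Hz), step (Hz)
    prop_baseline: float = 14.0   # propagation: baseline rate (Hz)
    prop_peak: float = 100.0      # propagation: jump rate (Hz)
    prop_group_size: int = 5
    prop_jump_ms: float = 5.0
    prop_onsets: tuple = (50.0, 550.0)

    def profiles(self, n_neurons: int, duration: float) -> list[list[tuple]]:
        T = duration
        if self.kind == "stationary":
            if self.rate < 0:
                raise ValueError("rate must be >= 0")
            return [[(0.0, T, self.rate)] for _ in range(n_neurons)]
        if self.kind == "coherent_step":
            a, b = self.step_interval
            if not (0 <= a <= b <= T):
                raise ValueError("step interval outside [0, T]")
            base, jump = self.step_rates
            segs = [(0.0, a, base), (a, b, jump), (b, T, base)]
            return [list(segs) for _ in range(n_neurons)]
        if self.kind == "heterogeneous":
            start, step = self.hetero_range
            return [[(0.0, T, start + step * i)] for i in range(n_neurons)]
        if self.kind == "propagation":
            gs = self.prop_group_size
            n_groups = n_neurons // gs
            out = []
            for i in range(n_neurons):
                group = min(i // gs, n_groups - 1)
                jumps = []
                for onset in self.prop_onsets:
                    j0 = onset + group * self.prop_jump_ms
                    j1 = j0 + self.prop_jump_ms
                    if j0 < T:
                        jumps.append((j0, min(j1, T)))
                segs, t = [], 0.0
                for j0, j1 in sorted(jumps):
                    if j0 > t:
                        segs.append((t, j0, self.prop_baseline))
                    segs.append((j0, j1, self.prop_peak))
                    t = j1
                if t < T:
                    segs.append((t, T, self.prop_baseline))
                out.append(segs)
            return out
        raise ValueError(f"unknown rate model kind {self.kind!r}")


def generate_background(
    model: RateModel,
    n_neurons: int = 100,
    duration: float = 1000.0,
    rng: np.random.Generator | None = None,
) -> SpikeTrainSet:
    """Independent (inhomogeneous) Poisson trains realizing ``model``.

    Piecewise-constant rates are simulated exactly: per segment, the spike
    count is Poisson(r * seg_len) and spike times are uniform in the segment.
    """
    if rng is None:
        rng = np.random.default_rng()
    profiles = model.profiles(n_neurons, duration)
    trains = []
    for segs in profiles:
        parts = []
        for t0, t1, r_hz in segs:
            if t1 <= t0:
                continue
            lam = r_hz * (t1 - t0) / 1000.0
            n = rng.poisson(lam)
            if n:
                parts.append(rng.uniform(t0, t1, size=n))
        times = np.sort(np.concatenate(parts)) if parts else np.empty(0)
        trains.append(times)
    return SpikeTrainSet(trains, 0.0, duration)


@dataclass
class InjectionSpec:
    """Parameters of an injected STP: z spikes, c occurrences, fixed lag (ms)."""

    z: int = 10
    c: int = 10
    lag: float = 5.0
    neuron_choice: str = "first"  # "first" -> neurons 0..z-1, "random" -> drawn
    neurons: tuple | None = None  # explicit neuron assignment (overrides choice)

    def __post_init__(self) -> None:
        if self.z < 1 or self.c < 1 or self.lag < 0:
            raise ValueError("invalid injection spec")


@dataclass
class GroundTruth:
    """Injected-pattern record: participating neurons, lags (ms) and onsets."""

    neurons: tuple
    lags: tuple           # per-spike lag from the occurrence onset, ms
    onsets: np.ndarray    # occurrence onset times, ms

    @property
    def z(self) -> int:
        return len(self.neurons)

    @property
    def c(self) -> int:
        return len(self.onsets)

    def key(self, dt: float = 1.0) -> tuple:
        """Canonical (neuron, lag-in-bins) composition, for strict scoring."""
        return tuple(sorted((n, int(round(l / dt))) for n, l in zip(self.neurons, self.lags)))


def _choose_neurons(spec: InjectionSpec, n_neurons: int, rng: np.random.Generator):
    if spec.neurons is not None:
        neurons = tuple(spec.neurons)
    elif spec.neuron_choice == "first":
        neurons = tuple(range(spec.z))
    elif spec.neuron_choice == "random":
        neurons = tuple(rng.choice(n_neurons, size=spec.z, replace=False))
    else:
        raise ValueError(f"unknown neuron_choice {spec.neuron_choice!r}")
    if len(neurons) != spec.z or max(neurons) >= n_neurons:
        raise ValueError("injection neurons out of range")
    return neurons


def inject_stp(
    trains: SpikeTrainSet,
    spec: InjectionSpec,
    rng: np.random.Generator | None = None,
    onsets: np.ndarray | None = None,
) -> tuple[SpikeTrainSet, GroundTruth]:
    """Superimpose c occurrences of a lagged spike sequence on ``trains``.

    Occurrence onsets are drawn uniformly on ``[t_start, t_stop - (z-1)*lag)``
    so every occurrence fits inside the recording; spike i of an occurrence at
    onset t0 lands at ``t0 + i*lag`` on the i-th participating neuron.
    Occurrences may overlap each other; collisions with background spikes in
    the same bin are resolved later by the binning clip rule.
    """
    if rng is None:
        rng = np.random.default_rng()
    neurons = _choose_neurons(spec, trains.n_neurons, rng)
    span = (spec.z - 1) * spec.lag
    hi = trains.t_stop - span
    if hi <= trains.t_start:
        raise ValueError("recording too short to place the pattern")
    if onsets is None:
        onsets = rng.uniform(trains.t_start, hi, size=spec.c)
    else:
        onsets = np.asarray(onsets, dtype=np.float64)
        if onsets.size != spec.c or onsets.min() < trains.t_start or onsets.max() >= hi:
            raise ValueError("invalid forced onsets")
    onsets = np.sort(onsets)
    new_trains = [tr.copy() for tr in trains.trains]
    lags = tuple(i * spec.lag for i in range(spec.z))
    for i, n in enumerate(neurons):
        new_trains[n] = np.sort(np.concatenate([new_trains[n], onsets + lags[i]]))
    out = SpikeTrainSet(new_trains, trains.t_start, trains.t_stop)
    return out, GroundTruth(neurons=neurons, lags=lags, onsets=onsets)


def inject_multiple(
    trains: SpikeTrainSet,
    specs: list[InjectionSpec],
    rng: np.random.Generator | None = None,
    max_tries: int = 1000,
) -> tuple[SpikeTrainSet, list[GroundTruth]]:
    """Inject several STPs with pairwise-distinct neuron sets enforced.

    Partially overlapping neuron sets are allowed (and recorded); identical
    sets are rejected and redrawn, mirroring the two-pattern validation setup.
    """
    if len(specs) < 2:
        raise ValueError("inject_multiple expects at least 2 specs")
    if rng is None:
        rng = np.random.default_rng()
    for _ in range(max_tries):
        neuron_sets = [frozenset(_choose_neurons(s, trains.n_neurons, rng)) for s in specs]
        if len(set(neuron_sets)) == len(neuron_sets):
            break
    else:
        raise ValueError("could not draw distinct neuron sets")
    out = trains
    truths = []
    for spec, ns in zip(specs, neuron_sets):
        fixed = InjectionSpec(z=spec.z, c=spec.c, lag=spec.lag, neurons=tuple(sorted(ns)))
        out, gt = inject_stp(out, fixed, rng)
        truths.append(gt)
    return out, truths
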