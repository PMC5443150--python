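"""Spike-train containers, discretization, dither surrogates and file I/O.

All times are in milliseconds. A :class:`SpikeTrainSet` holds one spike-time
array per neuron over the half-open recording interval ``[t_start, t_stop)``;
:func:`bin_spikes` turns it into a binary occupancy matrix (at most one spike
per neuron per bin, duplicates are clipped), which is the substrate for the
sliding-window formal context used by the pattern miner.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrainSet",
    "BinnedSpikes",
    "bin_spikes",
    "dither_spikes",
    "read_spike_trains",
    "write_spike_trains",
]


@dataclass
class SpikeTrainSet:
    """Parallel spike trains: one sorted array of spike times (ms) per neuron.

    Invariants: every spike time ``t`` satisfies ``t_start <= t < t_stop`` and
    each neuron's times are sorted ascending.
    """

    trains: list[np.ndarray]
    t_start: float = 0.0
    t_stop: float = 1000.0

    def __post_init__(self) -> None:
        if not self.t_stop >= self.t_start:
            raise ValueError("t_stop must be >= t_start")
        clean = []
        for i, tr in enumerate(self.trains):
            arr = np.asarray(tr, dtype=np.float64)
            if arr.ndim != 1:
                raise ValueError(f"neuron {i}: spike times must be 1-D")
            if arr.size and not np.all(np.isfinite(arr)):
                raise ValueError(f"neuron {i}: non-finite spike times")
            if arr.size and (arr.min() < self.t_start or arr.max() >= self.t_stop):
                raise ValueError(
                    f"neuron {i}: spike times outside [{self.t_start}, {self.t_stop})"
                )
            if arr.size and np.any(np.diff(arr) < 0):
                arr = np.sort(arr)
            clean.append(arr)
        self.trains = clean

    @property
    def n_neurons(self) -> int:
        return len(self.trains)

    @property
    def duration(self) -> float:
        """Recording length T in ms."""
        return self.t_stop - self.t_start

    def spike_counts(self) -> np.ndarray:
        return np.array([len(tr) for tr in self.trains], dtype=np.int64)

    def total_spikes(self) -> int:
        return int(self.spike_counts().sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeTrainSet):
            return NotImplemented
        return (
            self.t_start == other.t_start
            and self.t_stop == other.t_stop
            and len(self.trains) == len(other.trains)
            and all(np.array_equal(a, b) for a, b in zip(self.trains, other.trains))
        )


@dataclass
class BinnedSpikes:
    """Binary occupancy matrix, ``n_neurons x n_bins``, bin width ``dt`` ms."""

    matrix: np.ndarray
    dt: float = 1.0
    t_start: float = 0.0
    n_clipped: int = 0  # same-bin duplicate spikes collapsed to one

    @property
    def n_neurons(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_bins(self) -> int:
        return self.matrix.shape[1]


def bin_spikes(trains: SpikeTrainSet, dt: float = 1.0) -> BinnedSpikes:
    """Discretize spike trains into a binary matrix with bin width ``dt`` ms.

    A spike at time ``t`` maps to bin ``floor((t - t_start)/dt)`` (half-open
    bins ``[k*dt, (k+1)*dt)``). Several spikes of one neuron falling into the
    same bin are clipped to a single entry; the clip count is recorded.
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    n_bins = int(np.ceil(trains.duration / dt)) if trains.duration > 0 else 0
    mat = np.zeros((trains.n_neurons, n_bins), dtype=np.uint8)
    n_clipped = 0
    for i, tr in enumerate(trains.trains):
        if tr.size == 0:
            continue
        idx = np.floor((tr - trains.t_start) / dt).astype(np.int64)
        # floating point at the upper edge: clip into the last bin
        idx = np.minimum(idx, n_bins - 1)
        uniq = np.unique(idx)
        n_clipped += idx.size - uniq.size
        mat[i, uniq] = 1
    return BinnedSpikes(matrix=mat, dt=dt, t_start=trains.t_start, n_clipped=n_clipped)


def dither_spikes(
    trains: SpikeTrainSet,
    halfwidth: float = 5.0,
    rng: np.random.Generator | None = None,
) -> SpikeTrainSet:
    """Uniform spike dithering: the standard surrogate for destroying STPs.

    Each spike is independently displaced by a uniform draw in
    ``[-halfwidth, +halfwidth]``; draws landing outside ``[t_start, t_stop)``
    are redrawn, so per-neuron spike counts are preserved exactly.  Firing
    rate profiles (defined on a coarser time scale than the dither width) are
    essentially unchanged, while millisecond-precise patterns are destroyed.
    """
    if halfwidth < 0:
        raise ValueError("halfwidth must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    if halfwidth == 0:
        return SpikeTrainSet([tr.copy() for tr in trains.trains], trains.t_start, trains.t_stop)
    out = []
    for tr in trains.trains:
        new = tr + rng.uniform(-halfwidth, halfwidth, size=tr.size)
        bad = (new < trains.t_start) | (new >= trains.t_stop)
        while np.any(bad):
            new[bad] = tr[bad] + rng.uniform(-halfwidth, halfwidth, size=int(bad.sum()))
            bad = (new < trains.t_start) | (new >= trains.t_stop)
        out.append(np.sort(new))
    return SpikeTrainSet(out, trains.t_start, trains.t_stop)


def write_spike_trains(
    trains: SpikeTrainSet, path, dialect: str = "rows"
) -> None:
    """Write spike trains as plain text.

    ``dialect="rows"``: one line per neuron, whitespace-delimited times.
    ``dialect="pairs"``: two columns ``neuron_id time`` (0-based neuron ids).
    A header comment declares units and the recording interval.
    """
    with open(path, "w") as fh:
        fh.write("# units: ms\n")
        fh.write(f"# t_start: {trains.t_start!r} t_stop: {trains.t_stop!r} "
                 f"n_neurons: {trains.n_neurons}\n")
        if dialect == "rows":
            for tr in trains.trains:
                fh.write(" ".join(repr(float(t)) for t in tr) + "\n")
        elif dialect == "pairs":
            for i, tr in enumerate(trains.trains):
                for t in tr:
                    fh.write(f"{i} {float(t)!r}\n")
        else:
            raise ValueError(f"unknown dialect {dialect!r}")


def read_spike_trains(path, dialect: str = "rows") -> SpikeTrainSet:
    """Read spike trains written by :func:`write_spike_trains`.

    Unsorted times are auto-sorted with a warning; malformed lines raise a
    parse error naming the line number.
    """
    t_start, t_stop, n_neurons = 0.0, None, None
    rows: list[list[float]] = []
    pairs: list[tuple[int, float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if s.startswith("#"):
                if "t_start:" in s:
                    toks = s.split()
                    t_start = float(toks[toks.index("t_start:") + 1])
                    t_stop = float(toks[toks.index("t_stop:") + 1])
                    n_neurons = int(toks[toks.index("n_neurons:") + 1])
                continue
            if dialect == "rows":
                try:
                    rows.append([float(x) for x in s.split()])
                except ValueError as e:
                    raise ValueError(f"{path}: parse error on line {lineno}: {e}") from None
            elif dialect == "pairs":
                if not s:
                    continue
                toks = s.split()
                if len(toks) != 2:
                    raise ValueError(f"{path}: parse error on line {lineno}: "
                                     f"expected 2 columns, got {len(toks)}")
                try:
                    pairs.append((int(toks[0]), float(toks[1])))
                except ValueError as e:
                    raise ValueError(f"{path}: parse error on line {lineno}: {e}") from None
            else:
                raise ValueError(f"unknown dialect {dialect!r}")
    if dialect == "pairs":
        n = (max(i for i, _ in pairs) + 1) if pairs else 0
        if n_neurons is not None:
            n = max(n, n_neurons)
        rows = [[] for _ in range(n)]
        for i, t in pairs:
            rows[i].append(t)
    elif n_neurons is not None and len(rows) < n_neurons:
        rows.extend([[] for _ in range(n_neurons - len(rows))])
    arrs = []
    for i, r in enumerate(rows):
        a = np.array(r, dtype=np.float64)
        if a.size and np.any(np.diff(a) < 0):
            warnings.warn(f"neuron {i}: unsorted spike times auto-sorted")
            a = np.sort(a)
        arrs.append(a)
    if t_stop is None:
        t_stop = max((a.max() for a in arrs if a.size), default=0.0) + 1.0
    return SpikeTrainSet(arrs, t_start, t_stop)
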