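"""Sliding-window formal context and FCA derivation operators.

The binned data are scanned with a window of K bins sliding in steps of one
bin.  Each window start is a formal object; each pair ``(neuron, offset)``
with ``offset in [0, K)`` is a formal attribute, encoded as the integer
``neuron * K + offset``.  Object t carries attribute ``(n, o)`` exactly when
neuron n has a spike in bin ``t + o``.  A formal concept is a pair
(extent A of windows, intent B of attributes) closed under the two derivation
operators; its intent is a candidate spatio-temporal pattern and its extent
the set of windows the pattern occurs in.

Because every shifted copy of a pattern is itself an intent, concepts are
grouped into shift-equivalence classes and represented by the copy whose
earliest spike sits in the first bin of the window (minimum offset 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .spikes import BinnedSpikes

__all__ = [
    "FormalContext",
    "Concept",
    "STPattern",
    "build_context",
    "derive_intent",
    "derive_extent",
    "canonicalize",
    "shift_class_key",
]


@dataclass
class FormalContext:
    """Objects x attributes incidence in CSR form (per-object sorted attrs)."""

    indptr: np.ndarray      # int64, len n_objects + 1
    indices: np.ndarray     # int32, attribute ids, sorted within each object
    n_objects: int
    n_attributes: int
    K: int                  # window length in bins
    dt: float = 1.0         # bin width, ms
    n_neurons: int = 0

    def row(self, t: int) -> np.ndarray:
        if not 0 <= t < self.n_objects:
            raise KeyError(f"unknown object {t}")
        return self.indices[self.indptr[t]:self.indptr[t + 1]]

    def attr_pair(self, attr_id: int) -> tuple[int, int]:
        """Decode an attribute id into (neuron, offset)."""
        return int(attr_id) // self.K, int(attr_id) % self.K

    def attr_id(self, neuron: int, offset: int) -> int:
        if not (0 <= offset < self.K):
            raise ValueError("offset outside window")
        return neuron * self.K + offset

    # column (attribute -> objects) access, built lazily for stability kernels
    _colptr: np.ndarray | None = field(default=None, repr=False)
    _colidx: np.ndarray | None = field(default=None, repr=False)

    def _ensure_columns(self) -> None:
        if self._colptr is None:
            counts = np.bincount(self.indices, minlength=self.n_attributes)
            self._colptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
            order = np.argsort(self.indices, kind="stable")
            self._colidx = np.repeat(
                np.arange(self.n_objects, dtype=np.int32),
                np.diff(self.indptr).astype(np.int64),
            )[order]

    def column(self, attr_id: int) -> np.ndarray:
        """Objects whose window contains ``attr_id`` (sorted)."""
        if not 0 <= attr_id < self.n_attributes:
            raise KeyError(f"unknown attribute {attr_id}")
        self._ensure_columns()
        return self._colidx[self._colptr[attr_id]:self._colptr[attr_id + 1]]

    def transactions(self) -> list[np.ndarray]:
        return [self.row(t) for t in range(self.n_objects)]

    def export_transactions(self, path) -> None:
        """One object per line, space-separated attribute ids (miner format)."""
        with open(path, "w") as fh:
            for t in range(self.n_objects):
                fh.write(" ".join(str(int(a)) for a in self.row(t)) + "\n")


@dataclass(frozen=True)
class Concept:
    """A formal concept: closed (extent, intent) pair with signature (z, c)."""

    intent: tuple        # sorted attribute ids
    extent: tuple        # sorted object ids

    @property
    def z(self) -> int:
        return len(self.intent)

    @property
    def c(self) -> int:
        return len(self.extent)

    @property
    def signature(self) -> tuple[int, int]:
        return (self.z, self.c)


@dataclass(frozen=True)
class STPattern:
    """Canonical spatio-temporal pattern: (neuron, lag) spikes, min lag 0."""

    spikes: tuple        # sorted (neuron, lag-in-bins) pairs, min lag == 0
    occurrences: tuple   # window start bins

    @property
    def z(self) -> int:
        return len(self.spikes)

    @property
    def c(self) -> int:
        return len(self.occurrences)

    @property
    def signature(self) -> tuple[int, int]:
        return (self.z, self.c)


def build_context(binned: BinnedSpikes, K: int, windows: str = "padded") -> FormalContext:
    """Construct the sliding-window formal context from binned spikes.

    ``windows="padded"`` (default) creates one object per start bin
    (``n_bins`` objects); window positions past the last bin read as empty, so
    occurrences starting in the final K-1 bins keep a canonical window.
    ``windows="valid"`` restricts to the ``n_bins - K + 1`` fully contained
    windows instead.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    n_bins = binned.n_bins
    if K > n_bins:
        raise ValueError(f"K = {K} exceeds n_bins = {n_bins}")
    if windows == "padded":
        n_obj = n_bins
    elif windows == "valid":
        n_obj = n_bins - K + 1
    else:
        raise ValueError(f"unknown windows mode {windows!r}")

    neuron_idx, bin_idx = np.nonzero(binned.matrix)
    n_spikes = neuron_idx.size
    if n_spikes == 0:
        indptr = np.zeros(n_obj + 1, dtype=np.int64)
        return FormalContext(indptr, np.empty(0, dtype=np.int32), n_obj,
                             binned.n_neurons * K, K, binned.dt, binned.n_neurons)
    # spike (n, b) appears as attribute (n, o) in window t = b - o, o in [0, K)
    offs = np.arange(K, dtype=np.int64)
    objs = bin_idx[:, None] - offs[None, :]                  # (n_spikes, K)
    attrs = (neuron_idx[:, None] * K + offs[None, :]).astype(np.int32)
    valid = (objs >= 0) & (objs < n_obj)
    objs, attrs = objs[valid], attrs[valid]
    order = np.lexsort((attrs, objs))
    objs, attrs = objs[order], attrs[order]
    indptr = np.concatenate([[0], np.cumsum(np.bincount(objs, minlength=n_obj))]).astype(np.int64)
    return FormalContext(indptr, attrs, n_obj, binned.n_neurons * K, K,
                         binned.dt, binned.n_neurons)


def derive_intent(ctx: FormalContext, object_set) -> np.ndarray:
    """A' — attributes shared by every object in ``object_set`` (sorted).

    The empty object set derives to all of M (vacuous quantifier).
    """
    objs = np.asarray(sorted(set(int(t) for t in object_set)), dtype=np.int64)
    if objs.size == 0:
        return np.arange(ctx.n_attributes, dtype=np.int32)
    common = ctx.row(int(objs[0]))
    for t in objs[1:]:
        common = np.intersect1d(common, ctx.row(int(t)), assume_unique=True)
        if common.size == 0:
            break
    return common.astype(np.int32)


def derive_extent(ctx: FormalContext, attribute_set) -> np.ndarray:
    """B' — objects containing every attribute in ``attribute_set`` (sorted).

    The empty attribute set derives to all of G.
    """
    attrs = sorted(set(int(a) for a in attribute_set))
    if len(attrs) == 0:
        return np.arange(ctx.n_objects, dtype=np.int64)
    common = ctx.column(attrs[0])
    for a in attrs[1:]:
        common = np.intersect1d(common, ctx.column(a), assume_unique=True)
        if common.size == 0:
            break
    return common.astype(np.int64)


def shift_class_key(ctx: FormalContext, intent) -> tuple:
    """Lag-normalized key identifying the shift-equivalence class of an intent."""
    pairs = [ctx.attr_pair(a) for a in intent]
    min_off = min(o for _, o in pairs)
    return tuple(sorted((n, o - min_off) for n, o in pairs))


def canonicalize(ctx: FormalContext, concept: Concept) -> STPattern | None:
    """Map a concept to its canonical STP, or ``None`` for shifted duplicates.

    A concept is the canonical representative of its shift class exactly when
    the minimum offset of its intent is 0 (first spike in the first window
    bin); all other members of the class are rejected as duplicates.
    """
    pairs = [ctx.attr_pair(a) for a in concept.intent]
    min_off = min(o for _, o in pairs)
    if min_off != 0:
        return None
    return STPattern(
        spikes=tuple(sorted(pairs)),
        occurrences=tuple(int(t) for t in concept.extent),
    )
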