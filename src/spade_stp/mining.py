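"""Closed frequent concept mining: production miner, oracle, pre-filter.

The production miner enumerates closed itemsets (concept intents) with their
full extents from the CSR transaction encoding of a formal context, using a
prefix-preserving closure-extension depth-first search.  Its contract is the
output *set*, which :func:`brute_force_closed` — exhaustive closure of every
object subset — pins down on small contexts.

The size/occurrence pre-filter keeps canonical (non-shifted) concepts with at
least ``z_min`` spikes and ``c_min`` occurrences; by default 3/3, the rule
that removes the overwhelming majority of chance patterns before any
statistics are computed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from . import _kernels
from .fca import Concept, FormalContext, derive_extent, derive_intent

__all__ = [
    "MiningConfig",
    "MiningResult",
    "mine_closed_arrays",
    "mine_closed_frequent",
    "brute_force_closed",
    "apply_pattern_filter",
]


@dataclass
class MiningConfig:
    """Mining thresholds.

    ``min_support``/``min_size`` apply at mine time; ``z_min``/``c_min`` are
    the post-filter on canonical concepts (defaults 3 spikes, 3 occurrences).
    Because closedness does not depend on the frequency threshold, mining
    directly at the effective thresholds yields the identical filtered set;
    :func:`MiningResult.filtered` relies on that.
    """

    min_support: int = 2
    min_size: int = 2
    z_min: int = 3
    c_min: int = 3

    def __post_init__(self) -> None:
        if min(self.min_support, self.min_size, self.z_min, self.c_min) < 1:
            raise ValueError("all mining thresholds must be >= 1")


@dataclass
class MiningResult:
    """Array-backed mined concepts (fast path used by the pipeline).

    ``intent_ptr``/``intents`` and ``extent_ptr``/``extents`` are CSR-style
    concatenations: concept i has intent ``intents[intent_ptr[i]:intent_ptr[i+1]]``.
    """

    ctx: FormalContext
    intent_ptr: np.ndarray
    intents: np.ndarray
    extent_ptr: np.ndarray
    extents: np.ndarray

    @property
    def n_concepts(self) -> int:
        return len(self.intent_ptr) - 1

    def sizes(self) -> np.ndarray:
        return np.diff(self.intent_ptr)

    def supports(self) -> np.ndarray:
        return np.diff(self.extent_ptr)

    def intent(self, i: int) -> np.ndarray:
        return self.intents[self.intent_ptr[i]:self.intent_ptr[i + 1]]

    def extent(self, i: int) -> np.ndarray:
        return self.extents[self.extent_ptr[i]:self.extent_ptr[i + 1]]

    def min_offsets(self) -> np.ndarray:
        """Minimum window offset of each concept's intent (shift position)."""
        if self.n_concepts == 0:
            return np.empty(0, dtype=np.int64)
        offs = self.intents.astype(np.int64) % self.ctx.K
        return np.minimum.reduceat(offs, self.intent_ptr[:-1])

    def canonical_filter(self, z_min: int, c_min: int,
                         drop_truncated: bool = True) -> np.ndarray:
        """Indices of canonical concepts (min offset 0) with z>=z_min, c>=c_min.

        ``drop_truncated`` additionally removes window-boundary artifacts:
        patterns every occurrence of which extends, by the same spike left of
        the window frame, to an occurrence of a larger pattern that still
        fits one window (see :func:`truncation_mask`).
        """
        if self.n_concepts == 0:
            return np.empty(0, dtype=np.int64)
        keep = (self.sizes() >= z_min) & (self.supports() >= c_min) \
            & (self.min_offsets() == 0)
        idx = np.nonzero(keep)[0]
        if drop_truncated and idx.size:
            idx = idx[truncation_mask(self, idx)]
        return idx

    def concept(self, i: int) -> Concept:
        return Concept(intent=tuple(int(a) for a in self.intent(i)),
                       extent=tuple(int(t) for t in self.extent(i)))


def _run_kernel(indptr, indices, colptr, colidx, n_objects, n_attributes,
                min_support, min_size, n_roots):
    nnz = int(indices.size)
    cap_int = max(4096, 4 * nnz)
    cap_ext = max(4096, 4 * nnz)
    cap_pat = max(1024, nnz)
    while True:
        out_int = np.empty(cap_int, dtype=np.int32)
        out_ext = np.empty(cap_ext, dtype=np.int64)
        out_int_ptr = np.empty(cap_pat + 1, dtype=np.int64)
        out_ext_ptr = np.empty(cap_pat + 1, dtype=np.int64)
        counters = _kernels.lcm_mine(
            indptr, indices, colptr, colidx, n_objects, n_attributes,
            min_support, min_size, n_roots,
            out_int, out_int_ptr, out_ext, out_ext_ptr)
        if counters[3] == 0:
            n = int(counters[0])
            return (out_int_ptr[:n + 1].copy(), out_int[:int(counters[1])].copy(),
                    out_ext_ptr[:n + 1].copy(), out_ext[:int(counters[2])].copy())
        cap_int *= 2
        cap_ext *= 2
        cap_pat *= 2


def _columns(indices, indptr, n_objects, n_attributes):
    counts = np.bincount(indices, minlength=n_attributes)
    colptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    order = np.argsort(indices, kind="stable")
    colidx = np.repeat(np.arange(n_objects, dtype=np.int32),
                       np.diff(indptr).astype(np.int64))[order]
    return colptr, colidx


def mine_closed_arrays(ctx: FormalContext, min_support: int, min_size: int,
                       canonical_only: bool = False) -> MiningResult:
    """Run the closed-itemset kernel; grows output buffers on overflow.

    With ``canonical_only`` the items are re-ordered so that offset-0
    attributes come first and the search is restricted to subtrees rooted at
    them: since every closed set's generating path starts at its minimum
    item, this enumerates exactly the closed sets of minimum offset 0 — the
    canonical shift-class representatives — at a fraction of the cost.  Falls
    back to the full search in the degenerate case of a non-empty root
    closure (some attribute present in every window).
    """
    ctx._ensure_columns()
    indptr = ctx.indptr.astype(np.int64)
    indices = ctx.indices.astype(np.int32)
    if canonical_only and np.all(np.diff(ctx._colptr) < ctx.n_objects):
        N, K = ctx.n_neurons, ctx.K
        a = np.arange(ctx.n_attributes, dtype=np.int64)
        n, o = a // K, a % K
        perm = np.where(o == 0, n, N + n * (K - 1) + (o - 1)).astype(np.int32)
        pind = perm[indices]
        rows = np.repeat(np.arange(ctx.n_objects, dtype=np.int64), np.diff(indptr))
        order = np.lexsort((pind, rows))
        pind = pind[order]
        colptr, colidx = _columns(pind, indptr, ctx.n_objects, ctx.n_attributes)
        int_ptr, intents, ext_ptr, extents = _run_kernel(
            indptr, pind, colptr, colidx, ctx.n_objects, ctx.n_attributes,
            min_support, min_size, N)
        # map permuted item ids back and re-sort each intent
        inv = np.empty_like(perm)
        inv[perm] = np.arange(ctx.n_attributes, dtype=np.int32)
        intents = inv[intents]
        if intents.size:
            pat = np.repeat(np.arange(len(int_ptr) - 1), np.diff(int_ptr))
            intents = intents[np.lexsort((intents, pat))]
        return MiningResult(ctx=ctx, intent_ptr=int_ptr, intents=intents,
                            extent_ptr=ext_ptr, extents=extents)
    colidx = ctx._colidx.astype(np.int32)
    int_ptr, intents, ext_ptr, extents = _run_kernel(
        indptr, indices, ctx._colptr, colidx, ctx.n_objects, ctx.n_attributes,
        min_support, min_size, ctx.n_attributes)
    return MiningResult(ctx=ctx, intent_ptr=int_ptr, intents=intents,
                        extent_ptr=ext_ptr, extents=extents)


def _offset0_occupancy(ctx: FormalContext) -> np.ndarray:
    """Boolean (n_neurons, n_objects): does neuron n spike in bin t."""
    occ = np.zeros((ctx.n_neurons, ctx.n_objects), dtype=bool)
    for n in range(ctx.n_neurons):
        occ[n, ctx.column(n * ctx.K)] = True
    return occ


def truncation_mask(mr: MiningResult, idx: np.ndarray) -> np.ndarray:
    """Keep-mask over ``idx``: False for truncated duplicates.

    A canonical pattern is a truncated duplicate when some neuron fires a
    fixed number of bins *before* the window start of every one of its
    occurrences, with the extended pattern still spanning at most K bins: the
    pattern is then not maximal in time and space — it is the sliding
    window's cut-off view of the larger pattern (which is itself mined) —
    exactly as a shifted copy is a duplicate of its canonical representative.
    """
    ctx = mr.ctx
    occ = _offset0_occupancy(ctx)
    K = ctx.K
    keep = np.ones(len(idx), dtype=bool)
    for j, i in enumerate(idx):
        L = int((mr.intent(i).astype(np.int64) % K).max())
        if L >= K - 1:
            continue  # any extension would exceed the window span
        E = mr.extent(i)
        for d in range(-1, L - K, -1):
            tt = E + d
            if tt[0] < 0:
                continue
            if occ[:, tt].all(axis=1).any():
                keep[j] = False
                break
    return keep


def _sorted_concepts(concepts: list[Concept]) -> list[Concept]:
    """Deterministic report order: desc z*c, desc z, lexicographic intent."""
    return sorted(concepts, key=lambda cc: (-cc.z * cc.c, -cc.z, cc.intent))


def mine_closed_frequent(ctx: FormalContext, cfg: MiningConfig | None = None) -> list[Concept]:
    """All closed itemsets with support >= min_support and size >= min_size.

    Returns :class:`Concept` objects with full extents, in deterministic
    order.  An empty result is valid.
    """
    if cfg is None:
        cfg = MiningConfig()
    res = mine_closed_arrays(ctx, cfg.min_support, cfg.min_size)
    return _sorted_concepts([res.concept(i) for i in range(res.n_concepts)])


def brute_force_closed(ctx: FormalContext, min_support: int = 1,
                       min_size: int = 1) -> list[Concept]:
    """Oracle: closures of all object subsets, deduplicated.

    Exponential in |G|; refuses contexts with more than 20 objects.
    """
    if ctx.n_objects > 20:
        raise ValueError(
            "brute_force_closed enumerates all object subsets and is limited "
            "to |G| <= 20; use mine_closed_frequent for larger contexts")
    seen: dict[tuple, tuple] = {}
    objects = range(ctx.n_objects)
    for r in range(1, ctx.n_objects + 1):
        for subset in combinations(objects, r):
            intent = tuple(int(a) for a in derive_intent(ctx, subset))
            if intent in seen:
                continue
            extent = tuple(int(t) for t in derive_extent(ctx, intent))
            seen[intent] = extent
    out = [Concept(intent=i, extent=e) for i, e in seen.items()
           if len(e) >= min_support and len(i) >= min_size]
    return _sorted_concepts(out)


def apply_pattern_filter(ctx: FormalContext, concepts: list[Concept],
                         z_min: int = 3, c_min: int = 3) -> list[Concept]:
    """Canonical 3/3 pre-filter.

    Shifted duplicates (intents whose minimum window offset is not 0) are
    removed first; the survivors are then required to have at least ``z_min``
    spikes and ``c_min`` occurrences.
    """
    out = []
    for cc in concepts:
        pairs = [ctx.attr_pair(a) for a in cc.intent]
        if min(o for _, o in pairs) != 0:
            continue
        if cc.z >= z_min and cc.c >= c_min:
            out.append(cc)
    return _sorted_concepts(out)
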