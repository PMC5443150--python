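"""Concept stability: exact and Monte-Carlo, thresholds, and filtering.

The intensional stability of a concept (A, B) is the fraction of subsets
C of the extent A whose derivation C' equals the intent B, over all 2^|A|
subsets (the empty subset derives to all of M and only counts when B = M).
It measures how robustly the pattern B is reproduced by sub-collections of
its occurrence windows.  Extensional stability is the dual over subsets of
the intent, and is sensitive to the pattern's size rather than its
occurrence count.

Both reduce to the same combinatorial primitive.  For the intensional case,
a subset C of A fails exactly when some attribute m outside B is common to
every window in C, i.e. when C is contained in the "spoiler" set
S_m = {t in A : m in items(t)}.  Encoding subsets of A as bit-masks, the
stability is the fraction of masks contained in no spoiler mask; the
extensional case uses spoilers D_g = B ∩ items(g) over objects g outside A.
Exact values enumerate all masks (guarded); the Monte-Carlo estimator draws
Z masks with each element included independently with probability 1/2, the
uniform distribution over the power set, so the success fraction is an
unbiased estimate of the exact value.

The stability threshold separating genuine from chance patterns is the upper
quantile, at a (by default Bonferroni-corrected) significance level, of the
null distribution of stability values obtained from patterns mined in
independent surrogate data (dithered spikes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._kernels import count_successes, count_successes_exact
from .fca import Concept, FormalContext
from .mining import MiningConfig, MiningResult, mine_closed_arrays
from .spikes import SpikeTrainSet, bin_spikes, dither_spikes
from . import fca as _fca

__all__ = [
    "StabilityEstimate",
    "StabilityThresholds",
    "AnnotatedConcept",
    "stability_exact",
    "stability_approx",
    "stability_threshold",
    "null_stability_values",
    "threshold_from_null",
    "filter_stable",
]

EXACT_GUARD = 25  # max set size for exhaustive subset enumeration


@dataclass(frozen=True)
class StabilityEstimate:
    """A stability value with its provenance (kind, mode, sample count)."""

    value: float
    kind: str            # "intensional" | "extensional"
    mode: str            # "exact" | "approx"
    n_samples: int | None = None   # Z when mode == "approx"

    def __post_init__(self) -> None:
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("stability outside [0, 1]")


@dataclass
class StabilityThresholds:
    """Surrogate-derived stability thresholds and how they were obtained."""

    theta_int: float | None = None
    theta_ext: float | None = None
    alpha: float = 0.01
    correction: str = "bonferroni"
    divisor: int = 1        # Bonferroni adjustment (2 when both kinds tested)
    n_null: int = 0         # null stability values behind the quantile


@dataclass
class AnnotatedConcept:
    concept: Concept
    sigma_int: StabilityEstimate | None = None
    sigma_ext: StabilityEstimate | None = None


def _spoiler_masks_int(ctx: FormalContext, extent: np.ndarray, intent: np.ndarray):
    """Spoiler bit-masks over extent positions, one per attribute outside B."""
    c = len(extent)
    items = []
    owners = []
    for pos, t in enumerate(extent):
        row = ctx.row(int(t))
        items.append(row)
        owners.append(np.full(row.size, pos, dtype=np.int64))
    items = np.concatenate(items) if items else np.empty(0, dtype=np.int64)
    owners = np.concatenate(owners) if owners else np.empty(0, dtype=np.int64)
    intent = np.asarray(intent)
    if intent.size:
        pos = np.minimum(np.searchsorted(intent, items), intent.size - 1)
        inside = intent[pos] == items
    else:
        inside = np.zeros(items.size, dtype=bool)
    items, owners = items[~inside], owners[~inside]
    has_outside = len(intent) < ctx.n_attributes
    return _group_masks(items, owners, c), c, has_outside


def _spoiler_masks_ext(ctx: FormalContext, extent: np.ndarray, intent: np.ndarray):
    """Spoiler bit-masks over intent positions, one per object outside A."""
    z = len(intent)
    objs = []
    owners = []
    for pos, m in enumerate(intent):
        col = ctx.column(int(m))
        objs.append(col.astype(np.int64))
        owners.append(np.full(col.size, pos, dtype=np.int64))
    objs = np.concatenate(objs) if objs else np.empty(0, dtype=np.int64)
    owners = np.concatenate(owners) if owners else np.empty(0, dtype=np.int64)
    extent = np.asarray(extent)
    if extent.size:
        pos = np.minimum(np.searchsorted(extent, objs), extent.size - 1)
        inside = extent[pos] == objs
    else:
        inside = np.zeros(objs.size, dtype=bool)
    objs, owners = objs[~inside], owners[~inside]
    has_outside = len(extent) < ctx.n_objects
    return _group_masks(objs, owners, z), z, has_outside


def _group_masks(keys: np.ndarray, bitpos: np.ndarray, width: int) -> np.ndarray:
    """OR together bits sharing a key -> (n_masks, n_words) uint64 array."""
    n_words = max(1, (width + 63) // 64)
    if keys.size == 0:
        return np.zeros((0, n_words), dtype=np.uint64)
    order = np.argsort(keys, kind="stable")
    keys, bitpos = keys[order], bitpos[order]
    starts = np.flatnonzero(np.concatenate([[True], keys[1:] != keys[:-1]]))
    if n_words == 1:
        bits = (np.uint64(1) << bitpos.astype(np.uint64))
        masks = np.bitwise_or.reduceat(bits, starts)[:, None]
    else:
        words = (bitpos // 64).astype(np.int64)
        bits = (np.uint64(1) << (bitpos % 64).astype(np.uint64))
        n_masks = starts.size
        group = np.cumsum(np.concatenate([[0], (keys[1:] != keys[:-1]).astype(np.int64)]))
        masks = np.zeros((n_masks, n_words), dtype=np.uint64)
        np.bitwise_or.at(masks, (group, words), bits)
    return np.unique(masks, axis=0)


def _prep(ctx: FormalContext, concept: Concept, kind: str):
    extent = np.asarray(concept.extent, dtype=np.int64)
    intent = np.asarray(concept.intent, dtype=np.int64)
    if kind == "intensional":
        return _spoiler_masks_int(ctx, extent, intent)
    if kind == "extensional":
        return _spoiler_masks_ext(ctx, extent, intent)
    raise ValueError(f"unknown stability kind {kind!r}")


def stability_exact(ctx: FormalContext, concept: Concept,
                    kind: str = "intensional") -> StabilityEstimate:
    """Exact stability by exhaustive subset enumeration (Eq.-level definition).

    Guarded: the enumerated set (extent for intensional, intent for
    extensional) may hold at most 25 elements; beyond that use
    :func:`stability_approx`.
    """
    spoilers, width, has_outside = _prep(ctx, concept, kind)
    if width > EXACT_GUARD:
        raise ValueError(
            f"{kind} stability_exact enumerates 2^{width} subsets; the guard "
            f"is 2^{EXACT_GUARD} — use stability_approx instead")
    n_succ = count_successes_exact(width, spoilers, has_outside)
    return StabilityEstimate(value=n_succ / (1 << width), kind=kind, mode="exact")


def stability_approx(ctx: FormalContext, concept: Concept,
                     kind: str = "intensional", Z: int = 500,
                     rng: np.random.Generator | None = None) -> StabilityEstimate:
    """Monte-Carlo stability: Z uniform power-set draws, denominator Z.

    When the power set is no larger than the sampling budget
    (``2**width <= Z``) all subsets are enumerated instead, so the returned
    value is bit-for-bit exact; sampling error only arises for concepts whose
    enumerated set exceeds log2(Z) elements.  This is why, in typical data
    where most extents are small, the approximation error is exactly zero for
    the overwhelming majority of patterns.
    """
    if Z < 1:
        raise ValueError("Z must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    spoilers, width, has_outside = _prep(ctx, concept, kind)
    if width < 63 and (1 << width) <= Z:
        n_succ = count_successes_exact(width, spoilers, has_outside)
        value = n_succ / (1 << width)
    else:
        draws = _draw_masks(rng, Z, width)
        value = count_successes(draws, spoilers, has_outside) / Z
    return StabilityEstimate(value=value, kind=kind, mode="approx", n_samples=Z)


def _draw_masks(rng: np.random.Generator, Z: int, width: int) -> np.ndarray:
    n_words = max(1, (width + 63) // 64)
    draws = rng.integers(0, 2 ** 64, size=(Z, n_words), dtype=np.uint64)
    rem = width % 64
    if rem:
        draws[:, n_words - 1] &= np.uint64((1 << rem) - 1)
    if width == 0:
        draws[:] = 0
    return draws


def batch_stabilities(mr: MiningResult, idx: np.ndarray, kind: str,
                      Z: int = 500, rng: np.random.Generator | None = None,
                      mode: str = "approx") -> np.ndarray:
    """Stability values for the concepts ``idx`` of a mining result."""
    if rng is None:
        rng = np.random.default_rng()
    out = np.empty(len(idx), dtype=np.float64)
    for k, i in enumerate(idx):
        cc = Concept(intent=tuple(int(a) for a in mr.intent(i)),
                     extent=tuple(int(t) for t in mr.extent(i)))
        if mode == "approx":
            out[k] = stability_approx(mr.ctx, cc, kind, Z, rng).value
        else:
            out[k] = stability_exact(mr.ctx, cc, kind).value
    return out


def null_stability_values(trains: SpikeTrainSet, cfg: MiningConfig,
                          kinds: tuple[str, ...] = ("intensional", "extensional"),
                          dither_halfwidth: float = 5.0,
                          n_surrogates: int = 1,
                          Z: int = 500,
                          dt: float = 1.0, K: int = 50,
                          rng: np.random.Generator | None = None,
                          dither: bool = True) -> dict[str, np.ndarray]:
    """Null distribution of approximate stabilities from surrogate data.

    Each surrogate is an independently dithered copy of ``trains`` (or the
    trains themselves when ``dither`` is off, for nulls built directly from
    independent simulations); patterns are mined and canonically 3/3 filtered
    exactly as in the real analysis, and their approximate stabilities pooled.
    """
    if rng is None:
        rng = np.random.default_rng()
    out: dict[str, list] = {k: [] for k in kinds}
    for _ in range(n_surrogates):
        surr = dither_spikes(trains, dither_halfwidth, rng) if dither else trains
        mr = mine_closed_arrays(build_ctx(surr, dt, K),
                                max(cfg.min_support, cfg.c_min),
                                max(cfg.min_size, cfg.z_min),
                                canonical_only=True)
        idx = mr.canonical_filter(cfg.z_min, cfg.c_min)
        for kind in kinds:
            out[kind].append(batch_stabilities(mr, idx, kind, Z, rng))
    return {k: (np.concatenate(v) if v else np.empty(0)) for k, v in out.items()}


def build_ctx(trains: SpikeTrainSet, dt: float, K: int) -> FormalContext:
    return _fca.build_context(bin_spikes(trains, dt), K)


def threshold_from_null(values: np.ndarray, alpha: float,
                        correction: str = "bonferroni",
                        divisor: int = 1,
                        n_tested: int | None = None) -> float:
    """Upper-quantile threshold from null stability values.

    With Bonferroni correction the level is ``alpha / (n_tested * divisor)``
    (``n_tested`` defaults to the null size); the threshold is the k-th
    largest null value with ``k = ceil(n * level)`` — the conservative
    (ceiling-rank) empirical upper quantile.
    """
    values = np.sort(np.asarray(values, dtype=np.float64))
    n = values.size
    if n == 0:
        warnings.warn("empty null distribution; threshold defaults to 1.0")
        return 1.0
    if n < 100:
        warnings.warn(f"only {n} null stability values; quantile is unreliable")
    if correction == "bonferroni":
        if n_tested is None:
            n_tested = n
        level = alpha / (n_tested * divisor)
    elif correction == "none":
        level = alpha / divisor
    else:
        raise ValueError(f"unknown correction {correction!r}")
    k = max(1, int(np.ceil(n * level)))   # k-th largest
    return float(values[n - k])


def stability_threshold(trains: SpikeTrainSet, mining_cfg: MiningConfig,
                        kind: str = "intensional", alpha: float = 0.01,
                        dither_halfwidth: float = 5.0,
                        rng: np.random.Generator | None = None,
                        Z: int = 500, dt: float = 1.0, K: int = 50,
                        correction: str = "bonferroni", divisor: int = 1,
                        n_surrogates: int = 1) -> float:
    """Surrogate-derived stability threshold for one stability kind.

    A single dithered surrogate already yields thousands of chance patterns
    in typical data and is the default; pass ``n_surrogates > 1`` to pool.
    When both kinds will be tested on the same patterns (combined filter),
    pass ``divisor=2`` to adjust the Bonferroni correction.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    null = null_stability_values(trains, mining_cfg, (kind,), dither_halfwidth,
                                 n_surrogates, Z, dt, K, rng)[kind]
    return threshold_from_null(null, alpha, correction, divisor)


def filter_stable(annotated: list[AnnotatedConcept],
                  thresholds: StabilityThresholds,
                  mode: str = "combined") -> list[AnnotatedConcept]:
    """Keep concepts whose stability strictly exceeds its threshold.

    ``intensional``/``extensional`` test one measure; ``combined`` keeps a
    concept if either measure passes (its threshold Bonferroni-adjusted by
    the caller via ``divisor=2``).  Equality with the threshold rejects.
    """
    need_int = mode in ("intensional", "combined")
    need_ext = mode in ("extensional", "combined")
    if mode not in ("intensional", "extensional", "combined"):
        raise ValueError(f"unknown mode {mode!r}")
    if need_int and thresholds.theta_int is None:
        raise ValueError("mode requires theta_int")
    if need_ext and thresholds.theta_ext is None:
        raise ValueError("mode requires theta_ext")
    out = []
    for ac in annotated:
        keep = False
        if need_int:
            if ac.sigma_int is None:
                raise ValueError("concept lacks intensional stability annotation")
            keep = keep or ac.sigma_int.value > thresholds.theta_int
        if need_ext:
            if ac.sigma_ext is None:
                raise ValueError("concept lacks extensional stability annotation")
            keep = keep or ac.sigma_ext.value > thresholds.theta_ext
        if keep:
            out.append(ac)
    return out
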