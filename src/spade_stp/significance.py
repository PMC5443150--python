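"""Surrogate-based significance: pattern spectrum filtering and set reduction.

Rather than testing each of the (typically thousands of) mined patterns
individually, significance is assessed per *signature* (z, c) — pattern size
and occurrence count.  The p-value of a signature is the fraction of
surrogate data sets (dithered copies of the original, implementing the
independence null hypothesis) that contain at least one canonical filtered
pattern instantiating that signature.  Signatures present in the original
data are tested jointly under Benjamini-Hochberg false-discovery-rate
control; patterns whose signature is significant survive pattern spectrum
filtering (PSF).

PSF controls chance patterns in independent data, but a genuine pattern
boosts the apparent significance of its chance overlaps with background
spikes.  Pattern set reduction (PSR) removes these by re-testing every
overlapping pair of PSF survivors conditionally: the larger pattern with its
size discounted by the overlap (plus correction h), the smaller one with its
occurrence count discounted by the larger one's (plus correction k), looking
the conditioned signatures up in the same significance map.  If neither
conditioned signature survives, the pattern covering more spikes (largest
z*c) is retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from statsmodels.stats.multitest import multipletests

from .fca import STPattern, canonicalize
from .mining import MiningConfig, MiningResult, mine_closed_arrays
from .spikes import SpikeTrainSet, bin_spikes, dither_spikes
from .stability import (AnnotatedConcept, StabilityEstimate, StabilityThresholds,
                        batch_stabilities, build_ctx, filter_stable,
                        null_stability_values, threshold_from_null)

__all__ = [
    "PValueSpectrum",
    "PSRConfig",
    "SpadeConfig",
    "estimate_spectrum",
    "psf",
    "psr",
    "spade_run",
]


@dataclass
class PValueSpectrum:
    """Map from pattern signature (z, c) to its Monte-Carlo p-value.

    ``counting_mode="cumulative"`` (default): a surrogate pattern with
    signature (z, c') instantiates every (z, c <= c'), so p(z, c) is
    non-increasing in c.  ``"exact"``: only (z, c') itself is instantiated.
    The resolution floor is 1/n_surrogates; signatures never observed in any
    surrogate have p = 0.
    """

    n_surrogates: int
    counting_mode: str = "cumulative"
    # cumulative: z -> sorted array of per-surrogate maximal c (one entry per
    # surrogate in which z occurred); exact: (z, c) -> surrogate count
    _max_c: dict = field(default_factory=dict)
    _counts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_surrogates < 1:
            raise ValueError("n_surrogates must be >= 1")
        if self.counting_mode not in ("cumulative", "exact"):
            raise ValueError(f"unknown counting_mode {self.counting_mode!r}")

    def p_value(self, z: int, c: int) -> float:
        if self.counting_mode == "exact":
            return self._counts.get((int(z), int(c)), 0) / self.n_surrogates
        arr = self._max_c.get(int(z))
        if arr is None:
            return 0.0
        return float(arr.size - np.searchsorted(arr, c, side="left")) / self.n_surrogates

    def entries(self, signatures) -> dict[tuple[int, int], float]:
        return {(int(z), int(c)): self.p_value(z, c) for z, c in signatures}

    def to_json(self) -> dict:
        return {
            "n_surrogates": self.n_surrogates,
            "counting_mode": self.counting_mode,
            "max_c": {str(z): arr.tolist() for z, arr in self._max_c.items()},
            "counts": {f"{z},{c}": n for (z, c), n in self._counts.items()},
        }

    @classmethod
    def from_json(cls, d: dict) -> "PValueSpectrum":
        sp = cls(n_surrogates=d["n_surrogates"], counting_mode=d["counting_mode"])
        sp._max_c = {int(z): np.asarray(v, dtype=np.int64)
                     for z, v in d.get("max_c", {}).items()}
        sp._counts = {tuple(int(x) for x in k.split(",")): v
                      for k, v in d.get("counts", {}).items()}
        return sp


def _filtered_signatures(mr: MiningResult, cfg: MiningConfig) -> np.ndarray:
    """(z, c) signatures of canonical 3/3-filtered concepts, one row each."""
    idx = mr.canonical_filter(cfg.z_min, cfg.c_min)
    if idx.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    return np.stack([mr.sizes()[idx], mr.supports()[idx]], axis=1).astype(np.int64)


def estimate_spectrum(
    trains: SpikeTrainSet,
    mining_cfg: MiningConfig,
    n_surrogates: int = 1000,
    dither_halfwidth: float = 5.0,
    rng: np.random.Generator | None = None,
    dt: float = 1.0,
    K: int = 50,
    counting_mode: str = "cumulative",
) -> PValueSpectrum:
    """Monte-Carlo p-value spectrum from dithered surrogates.

    Each surrogate gets its own deterministic child stream of ``rng`` (so the
    spectrum is independent of surrogate evaluation order), is mined and
    filtered exactly like the original data, and contributes the set of
    signatures it instantiates.
    """
    if n_surrogates < 100:
        raise ValueError("n_surrogates must be >= 100 for a usable spectrum")
    if rng is None:
        rng = np.random.default_rng()
    streams = rng.spawn(n_surrogates)
    sp = PValueSpectrum(n_surrogates=n_surrogates, counting_mode=counting_mode)
    max_c_lists: dict[int, list[int]] = {}
    counts: dict[tuple[int, int], int] = {}
    ms = max(mining_cfg.min_support, mining_cfg.c_min)
    mz = max(mining_cfg.min_size, mining_cfg.z_min)
    for child in streams:
        surr = dither_spikes(trains, dither_halfwidth, child)
        mr = mine_closed_arrays(build_ctx(surr, dt, K), ms, mz, canonical_only=True)
        sigs = _filtered_signatures(mr, mining_cfg)
        if sigs.shape[0] == 0:
            continue
        if counting_mode == "cumulative":
            for z in np.unique(sigs[:, 0]):
                cmax = int(sigs[sigs[:, 0] == z, 1].max())
                max_c_lists.setdefault(int(z), []).append(cmax)
        else:
            for z, c in {(int(z), int(c)) for z, c in sigs}:
                counts[(z, c)] = counts.get((z, c), 0) + 1
    sp._max_c = {z: np.sort(np.asarray(v, dtype=np.int64))
                 for z, v in max_c_lists.items()}
    sp._counts = counts
    return sp


@dataclass
class SignificanceMap:
    """BH-corrected significance lookup shared by PSF and PSR."""

    p_crit: float               # largest BH-rejected p-value (-1 if none)
    spectrum: PValueSpectrum
    z_min: int = 3
    c_min: int = 3

    def is_significant(self, z: int, c: int) -> bool:
        if z < self.z_min or c < self.c_min:
            # conditioned signature outside the mined support: not testable
            return False
        return self.spectrum.p_value(z, c) <= self.p_crit


def psf(concepts, spectrum: PValueSpectrum, alpha: float = 0.01,
        z_min: int = 3, c_min: int = 3):
    """Pattern spectrum filtering with FDR (Benjamini-Hochberg) correction.

    BH runs over the *distinct* signatures present in ``concepts`` (that is
    the point of signature-level testing: it shrinks the multiple-testing
    problem by orders of magnitude).  Returns the surviving concepts, the set
    of significant signatures, and the significance map reused by PSR.
    """
    sigs = sorted({cc.signature for cc in concepts})
    if not sigs:
        return [], set(), SignificanceMap(0.0, spectrum, z_min, c_min)
    pvals = np.array([spectrum.p_value(z, c) for z, c in sigs])
    reject = multipletests(pvals, alpha=alpha, method="fdr_bh")[0]
    significant = {sig for sig, r in zip(sigs, reject) if r}
    p_crit = float(pvals[reject].max()) if reject.any() else -1.0
    kept = [cc for cc in concepts if cc.signature in significant]
    return kept, significant, SignificanceMap(p_crit, spectrum, z_min, c_min)


@dataclass
class PSRConfig:
    """Pattern set reduction correction factors (defaults h=0, k=2)."""

    h: int = 0
    k: int = 2

    def __post_init__(self) -> None:
        if self.h < 0 or self.k < 0:
            raise ValueError("h and k must be >= 0")


def _template_overlap(a: STPattern, b: STPattern, K: int) -> int:
    """Largest spike overlap of the two templates over all relative shifts."""
    sa = set(a.spikes)
    best = 0
    for d in range(-(K - 1), K):
        shifted = {(n, l + d) for n, l in b.spikes}
        best = max(best, len(sa & shifted))
    return best


def psr(patterns: list[STPattern], sig_map: SignificanceMap,
        cfg: PSRConfig | None = None, K: int = 50) -> list[STPattern]:
    """Pattern set reduction: conditional re-testing of overlapping pairs.

    All unordered pairs are evaluated once against the original significance
    map; removals are collected and applied at the end (no cascading within
    the pass), which makes the outcome independent of pair order.  Disjoint
    patterns are never touched.
    """
    if cfg is None:
        cfg = PSRConfig()
    n = len(patterns)
    remove = [False] * n
    for i in range(n):
        for j in range(i + 1, n):
            A, B = patterns[i], patterns[j]
            ia, ib = i, j
            if B.z > A.z:
                A, B, ia, ib = B, A, j, i  # A is the larger pattern
            ov = _template_overlap(A, B, K)
            if ov == 0:
                continue
            if ov == B.z:
                # B is (a shifted copy of) a sub-pattern of A
                sig_a = (A.z - B.z + cfg.h, A.c)
                sig_b = (B.z, B.c - A.c + cfg.k)
            else:
                # partial overlap: both conditioned on the common part
                sig_a = (A.z - ov + cfg.h, A.c)
                sig_b = (B.z - ov + cfg.h, B.c)
            ok_a = sig_map.is_significant(*sig_a)
            ok_b = sig_map.is_significant(*sig_b)
            if ok_a and ok_b:
                continue
            if ok_a:
                remove[ib] = True
            elif ok_b:
                remove[ia] = True
            else:
                # neither conditionally significant: keep the larger z*c,
                # ties to larger z then lexicographically smaller template
                if (A.z * A.c, A.z) > (B.z * B.c, B.z):
                    remove[ib] = True
                elif (A.z * A.c, A.z) < (B.z * B.c, B.z):
                    remove[ia] = True
                elif A.spikes <= B.spikes:
                    remove[ib] = True
                else:
                    remove[ia] = True
    return [p for p, r in zip(patterns, remove) if not r]


@dataclass
class SpadeConfig:
    """Full pipeline configuration."""

    dt: float = 1.0             # bin width, ms
    K: int = 50                 # window length, bins
    mining: MiningConfig = field(default_factory=MiningConfig)
    method: str = "psf-psr"     # psf-psr | psf | stab-int | stab-ext | stab-comb
    n_surrogates: int = 1000    # PSF surrogate count
    dither: float = 5.0         # dither half-width, ms
    alpha: float = 0.01
    Z: int = 500                # stability Monte-Carlo subsets
    stability_correction: str = "bonferroni"
    n_null_surrogates: int = 1  # surrogates pooled for the stability null
    counting_mode: str = "cumulative"

    def to_json(self) -> dict:
        d = asdict(self)
        return d


_METHODS = ("psf-psr", "psf", "stab-int", "stab-ext", "stab-comb")


def spade_run(trains: SpikeTrainSet, config: SpadeConfig,
              rng: np.random.Generator | None = None,
              spectrum: PValueSpectrum | None = None,
              thresholds: StabilityThresholds | None = None) -> dict:
    """Run the full pipeline and return a JSON-serializable report.

    Stages: binning -> sliding-window context -> closed frequent mining ->
    canonical 3/3 filter -> either the stability branch (surrogate-derived
    thresholds, approximate stability, threshold filter) or the significance
    branch (spectrum estimation, PSF, PSR).  A precomputed ``spectrum`` or
    ``thresholds`` can be supplied to amortize surrogate work across
    realizations of one model (the validation harness does this).
    """
    if config.method not in _METHODS:
        raise ValueError(f"method must be one of {_METHODS}")
    if rng is None:
        rng = np.random.default_rng()
    cfg = config.mining
    ctx = build_ctx(trains, config.dt, config.K)
    ms = max(cfg.min_support, cfg.c_min)
    mz = max(cfg.min_size, cfg.z_min)
    mr = mine_closed_arrays(ctx, ms, mz, canonical_only=True)
    idx = mr.canonical_filter(cfg.z_min, cfg.c_min)
    report: dict = {
        "config": config.to_json(),
        "n_neurons": trains.n_neurons,
        "n_spikes": trains.total_spikes(),
        "stages": {"mined": int(mr.n_concepts), "filtered": int(len(idx))},
    }

    patterns: list[dict] = []
    if config.method.startswith("stab"):
        mode = {"stab-int": "intensional", "stab-ext": "extensional",
                "stab-comb": "combined"}[config.method]
        kinds = {"intensional": ("intensional",), "extensional": ("extensional",),
                 "combined": ("intensional", "extensional")}[mode]
        divisor = 2 if mode == "combined" else 1
        if thresholds is None:
            null = null_stability_values(
                trains, cfg, kinds, config.dither, config.n_null_surrogates,
                config.Z, config.dt, config.K, rng)
            thresholds = StabilityThresholds(
                alpha=config.alpha, correction=config.stability_correction,
                divisor=divisor, n_null=max((v.size for v in null.values()), default=0))
            if "intensional" in kinds:
                thresholds.theta_int = threshold_from_null(
                    null["intensional"], config.alpha, config.stability_correction, divisor)
            if "extensional" in kinds:
                thresholds.theta_ext = threshold_from_null(
                    null["extensional"], config.alpha, config.stability_correction, divisor)
        sig_int = batch_stabilities(mr, idx, "intensional", config.Z, rng) \
            if "intensional" in kinds else None
        sig_ext = batch_stabilities(mr, idx, "extensional", config.Z, rng) \
            if "extensional" in kinds else None
        annotated = []
        for k, i in enumerate(idx):
            annotated.append(AnnotatedConcept(
                concept=mr.concept(i),
                sigma_int=StabilityEstimate(float(sig_int[k]), "intensional",
                                            "approx", config.Z)
                if sig_int is not None else None,
                sigma_ext=StabilityEstimate(float(sig_ext[k]), "extensional",
                                            "approx", config.Z)
                if sig_ext is not None else None))
        kept = filter_stable(annotated, thresholds, mode)
        report["stages"]["stability_kept"] = len(kept)
        report["stages"]["final"] = len(kept)
        report["thresholds"] = {
            "theta_int": thresholds.theta_int, "theta_ext": thresholds.theta_ext,
            "alpha": thresholds.alpha, "correction": thresholds.correction,
            "divisor": thresholds.divisor, "n_null": thresholds.n_null}
        for ac in kept:
            st = canonicalize(ctx, ac.concept)
            entry = _pattern_entry(st, ctx)
            if ac.sigma_int is not None:
                entry["sigma_int"] = ac.sigma_int.value
            if ac.sigma_ext is not None:
                entry["sigma_ext"] = ac.sigma_ext.value
            patterns.append(entry)
    else:
        if spectrum is None:
            spectrum = estimate_spectrum(
                trains, cfg, config.n_surrogates, config.dither, rng,
                config.dt, config.K, config.counting_mode)
        concepts = [mr.concept(i) for i in idx]
        kept, significant, sig_map = psf(concepts, spectrum, config.alpha,
                                         cfg.z_min, cfg.c_min)
        report["stages"]["psf_kept"] = len(kept)
        st_kept = [canonicalize(ctx, cc) for cc in kept]
        if config.method == "psf-psr":
            st_final = psr(st_kept, sig_map, PSRConfig(), config.K)
        else:
            st_final = st_kept
        report["stages"]["final"] = len(st_final)
        report["n_signatures_tested"] = len({cc.signature for cc in concepts})
        for st in st_final:
            entry = _pattern_entry(st, ctx)
            entry["p_value"] = spectrum.p_value(st.z, st.c)
            patterns.append(entry)

    patterns.sort(key=lambda e: (-e["z"] * e["c"], -e["z"], e["neurons"], e["lags_ms"]))
    report["patterns"] = patterns
    return report


def _pattern_entry(st: STPattern, ctx) -> dict:
    return {
        "neurons": [int(n) for n, _ in st.spikes],
        "lags_ms": [float(l * ctx.dt) for _, l in st.spikes],
        "occurrences_ms": [float(t * ctx.dt) for t in st.occurrences],
        "z": st.z,
        "c": st.c,
    }
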