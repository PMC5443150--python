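"""Strict scoring against ground truth and the FP/FN matrix harness.

A found pattern is a true positive only when it consists of all and only the
spikes forming the injected pattern — the strictest possible definition: a
sub- or super-pattern of the injected one counts as a false positive, and a
ground-truth pattern with no exact match is a false negative.

The matrix harness sweeps injected signatures (z, c) over a grid, runs the
full pipeline on R seeded realizations per cell, and records per cell the
fraction of realizations with at least one FP and with an FN.  Per-cell seed
streams are derived from the master seed by a counter scheme, so any cell is
reproducible (and parallelizable) in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .fca import STPattern
from .significance import SpadeConfig, spade_run, estimate_spectrum
from .stability import StabilityThresholds, null_stability_values, threshold_from_null
from .synth import GroundTruth, InjectionSpec, RateModel, generate_background, inject_stp

__all__ = [
    "FPFNMatrices",
    "classify_outcome",
    "fp_fn_matrices",
    "stage_counts",
    "model_thresholds",
]


def _report_pattern_key(entry: dict, dt: float) -> tuple:
    return tuple(sorted((int(n), int(round(l / dt)))
                        for n, l in zip(entry["neurons"], entry["lags_ms"])))


def classify_outcome(found: list, truths: list[GroundTruth],
                     dt: float = 1.0, strict_onsets: bool = False):
    """Score found patterns against ground truth.

    ``found`` holds report pattern entries (dicts) or :class:`STPattern`s.
    Returns ``(n_tp, n_fp, fn_flags)`` with one FN flag per ground truth.
    A TP requires the exact (neuron, lag) composition; with ``strict_onsets``
    the reported occurrences must additionally cover every injected onset.
    """
    truth_keys = [t.key(dt) for t in truths]
    truth_onsets = [np.floor((t.onsets) / dt).astype(int) for t in truths]
    matched = [False] * len(truths)
    n_tp = 0
    n_fp = 0
    for f in found:
        if isinstance(f, STPattern):
            key = tuple(sorted(f.spikes))
            occs = set(int(o) for o in f.occurrences)
        else:
            key = _report_pattern_key(f, dt)
            occs = set(int(round(o / dt)) for o in f["occurrences_ms"])
        hit = False
        for k, tk in enumerate(truth_keys):
            if key == tk:
                if strict_onsets and not set(truth_onsets[k]).issubset(occs):
                    continue
                matched[k] = True
                hit = True
        if hit:
            n_tp += 1
        else:
            n_fp += 1
    fn_flags = [not m for m in matched]
    return n_tp, n_fp, fn_flags


@dataclass
class FPFNMatrices:
    """Per-signature FP / FN rates over R realizations per cell."""

    z_values: np.ndarray
    c_values: np.ndarray
    fp_rate: np.ndarray         # shape (len(c_values), len(z_values))
    fn_rate: np.ndarray
    R: int
    model: str
    method: str
    master_seed: int
    failed: np.ndarray | None = None   # realizations that raised, per cell


def model_thresholds(model: RateModel, config: SpadeConfig,
                     n_neurons: int, duration: float,
                     master_seed: int, n_datasets: int = 100,
                     kinds=("intensional", "extensional"),
                     divisor: int | None = None) -> StabilityThresholds:
    """Shared stability thresholds for one background model.

    Pools the null stability distribution over ``n_datasets`` independent
    realizations of the (pattern-free) background model and takes the
    Bonferroni-corrected upper quantile — the shortcut that makes large
    validation sweeps affordable, justified by the injected spikes being far
    too few to move the null.
    """
    rng = np.random.default_rng(np.random.SeedSequence([master_seed, 0xD17]))
    nulls = {k: [] for k in kinds}
    n_per_dataset = []
    for _ in range(n_datasets):
        tr = generate_background(model, n_neurons, duration, rng)
        vals = null_stability_values(tr, config.mining, kinds, config.dither,
                                     1, config.Z, config.dt, config.K, rng,
                                     dither=False)
        for k in kinds:
            nulls[k].append(vals[k])
        n_per_dataset.append(len(vals[kinds[0]]))
    if divisor is None:
        divisor = 2 if len(kinds) == 2 else 1
    # Bonferroni divisor: the number of concepts tested in one analyzed
    # data set, estimated as the mean null count per realization
    n_tested = max(1, int(round(float(np.mean(n_per_dataset)))))
    pooled = {k: np.concatenate(v) for k, v in nulls.items()}
    th = StabilityThresholds(alpha=config.alpha, correction=config.stability_correction,
                             divisor=divisor,
                             n_null=int(pooled[kinds[0]].size))
    if "intensional" in kinds:
        th.theta_int = threshold_from_null(pooled["intensional"], config.alpha,
                                           config.stability_correction, divisor,
                                           n_tested=n_tested)
    if "extensional" in kinds:
        th.theta_ext = threshold_from_null(pooled["extensional"], config.alpha,
                                           config.stability_correction, divisor,
                                           n_tested=n_tested)
    return th


def fp_fn_matrices(model: RateModel, config: SpadeConfig,
                   z_range=range(3, 11), c_range=range(3, 11),
                   R: int = 100, n_neurons: int = 100, duration: float = 1000.0,
                   master_seed: int = 0,
                   thresholds: StabilityThresholds | None = None,
                   share_spectrum: bool = False,
                   lag: float = 5.0) -> FPFNMatrices:
    """FP/FN rates over a grid of injected signatures.

    Stability methods reuse one set of model-level ``thresholds`` (computed
    here if not given).  With ``share_spectrum`` the significance branch
    estimates one spectrum per cell from the first realization's surrogates
    instead of one per realization (scaled-preset shortcut).
    """
    z_values = np.asarray(list(z_range))
    c_values = np.asarray(list(c_range))
    fp = np.zeros((len(c_values), len(z_values)))
    fn = np.zeros_like(fp)
    failed = np.zeros_like(fp, dtype=np.int64)
    stability = config.method.startswith("stab")
    if stability and thresholds is None:
        kinds = {"stab-int": ("intensional",), "stab-ext": ("extensional",),
                 "stab-comb": ("intensional", "extensional")}[config.method]
        thresholds = model_thresholds(model, config, n_neurons, duration,
                                      master_seed, kinds=kinds)
    for ci, c in enumerate(c_values):
        for zi, z in enumerate(z_values):
            n_fp_runs = 0
            n_fn_runs = 0
            spectrum = None
            for r in range(R):
                seq = np.random.SeedSequence([master_seed, int(z), int(c), r])
                rng = np.random.default_rng(seq)
                try:
                    bg = generate_background(model, n_neurons, duration, rng)
                    data, gt = inject_stp(bg, InjectionSpec(z=int(z), c=int(c), lag=lag), rng)
                    if share_spectrum and not stability and spectrum is None:
                        spectrum = estimate_spectrum(
                            data, config.mining, config.n_surrogates,
                            config.dither, rng, config.dt, config.K,
                            config.counting_mode)
                    rep = spade_run(data, config, rng, spectrum=spectrum,
                                    thresholds=thresholds)
                    _, n_fp_found, fn_flags = classify_outcome(
                        rep["patterns"], [gt], config.dt)
                    n_fp_runs += int(n_fp_found > 0)
                    n_fn_runs += int(any(fn_flags))
                except Exception:
                    failed[ci, zi] += 1
            denom = R - failed[ci, zi]
            fp[ci, zi] = n_fp_runs / denom if denom else np.nan
            fn[ci, zi] = n_fn_runs / denom if denom else np.nan
    return FPFNMatrices(z_values=z_values, c_values=c_values, fp_rate=fp,
                        fn_rate=fn, R=R, model=model.kind, method=config.method,
                        master_seed=master_seed, failed=failed)


def stage_counts(run_reports: list[dict]) -> dict[str, float]:
    """Mean pattern count after each pipeline stage, over realizations."""
    keys: list[str] = []
    for rep in run_reports:
        for k in rep["stages"]:
            if k not in keys:
                keys.append(k)
    return {k: float(np.mean([rep["stages"][k] for rep in run_reports
                              if k in rep["stages"]]))
            for k in keys}
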