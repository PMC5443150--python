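# Methods

## Problem and pipeline

Massively parallel spike-train recordings (on the order of 100 neurons) may
contain spatio-temporal patterns (STPs): sequences of spikes with fixed
millisecond-scale lags across neurons that repeat more often than the
neurons' firing rates explain. The number of conceivable STPs grows
exponentially in neurons, pattern size and lag structure, so testing each
candidate individually is statistically and computationally hopeless. This
package implements the SPADE strategy: enumerate only *closed, frequent*
patterns with a data-mining step, then separate genuine from chance patterns
either by concept stability or by surrogate-based significance testing.

The pipeline is: binning → sliding-window formal context → closed frequent
concept mining → canonicalization and size/occurrence pre-filter → one of
two statistical branches (stability thresholds, or pattern spectrum
filtering followed by pattern set reduction).

## Discretization and the formal context

Spike times (ms) are binned at `dt` (default 1 ms, chosen so a neuron emits
at most one spike per bin; duplicates are clipped and counted). A window of
`K` bins (default 50, the assumed maximal STP duration) slides across the
binned data in steps of one bin. Window start `t` is a formal object; the
pair `(neuron n, offset o)`, encoded as the integer `n*K + o`, is a formal
attribute, incident to `t` exactly when `n` spikes in bin `t+o`. Derivation
operators are the standard Galois pair: `A' = attributes common to all
objects in A`, `B' = objects containing all attributes in B`; a concept is a
closed pair `(A, B)` with signature `z = |B|` (spikes) and `c = |A|`
(occurrences).

Conventions (the data model is silent on these; fixed and documented here):

* offsets and indices are 0-based; bins are half-open `[k·dt, (k+1)·dt)`;
* windows are created for **every** start bin (`n_bins` objects), positions
  past the recording reading as empty, so occurrences beginning in the last
  `K−1` bins keep a canonical window (a `windows="valid"` mode with
  `n_bins−K+1` objects exists behind a flag);
* spike files are plain text in two dialects (one row per neuron, or
  `neuron time` pairs) with an explanatory header.

## Canonical representatives: shifts and truncations

Every intent reappears K−L times as a time-shifted copy (L = pattern span).
Copies form an equivalence class represented by the member whose first spike
occupies the first window bin (minimum offset 0); all other members are
duplicates and are dropped after mining.

A subtler duplicate arises at window boundaries: windows starting just
*inside* an occurrence of a long pattern see its suffix, and that suffix is
formally closed within the window frame (the cut-off leading spike lies
outside the attribute space). Such a pattern is not maximal in time and
space at the spike level — every one of its occurrences extends, by the same
spike a fixed number of bins before the window start, to an occurrence of a
larger pattern that itself fits a window and is itself mined. These
*truncated duplicates* are removed together with shifted duplicates: a
canonical pattern is dropped iff some neuron fires `d` bins before the
window start of **all** of its occurrences, for some `d ≥ 1` with extended
span still `≤ K`. Without this rule, a single injected 10-spike pattern
contributes its full suffix ladder (z = 9, 8, …) to every downstream count,
which is incompatible both with strict-TP scoring and with the method's own
definition of closedness. The rule costs `O(patterns × K × c × N)` boolean
checks and removes a negligible (≈1%) fraction of genuine chance patterns.

## Mining

The production miner is an LCM-style depth-first enumeration of closed
itemsets with prefix-preserving closure extension, on the CSR transaction
encoding of the context; every closed set is visited exactly once, and
extents are recovered along the way. It is verified against an exhaustive
oracle (closure of every object subset, |G| ≤ 20) on randomized contexts.

Two implementation points matter for practical speed:

* **Leaf shortcut.** A node whose extent size equals `min_support` cannot be
  extended (any extension item would need to occur in all its transactions
  and is then already in the closure), so its closure is a plain k-way row
  intersection.
* **Canonical-roots search.** With an empty root closure, the generating
  path of a closed set starts at its minimum item. Re-ordering items so that
  offset-0 attributes come first therefore lets the search enumerate exactly
  the canonical (minimum-offset-0) closed sets by exploring only subtrees
  rooted at offset-0 items — a ~20× reduction on typical data, proven
  equivalent to filtering the full enumeration (and tested as such). The
  degenerate case of a non-empty root closure falls back to the full search.

Mining runs single-stage at the effective thresholds (support ≥ 3, size ≥ 3
by default): closedness does not depend on the frequency threshold, so this
is identical to mining at support 2 and filtering afterwards (tested).

The default pre-filter keeps patterns with at least 3 spikes and
3 occurrences — chance patterns below that are so abundant that no
statistical step could cope with them.

## Stability

The intensional stability of a concept `(A, B)` is the fraction of the
`2^|A|` subsets `C ⊆ A` with `C' = B`; extensional stability is the dual
over intent subsets. Both reduce to one combinatorial primitive: a subset
fails exactly when it is contained in some *spoiler* set (for the
intensional case, `S_m = {t ∈ A : m ∈ items(t)}` for each attribute `m`
outside `B`; dually for objects outside `A`). Subsets are encoded as bit
masks; the empty subset derives to the full dual universe and succeeds only
in the degenerate all-of-M / all-of-G cases.

* **Exact mode** enumerates all masks (guarded at 25 elements).
* **Approximate mode** draws `Z` masks with each element included with
  probability 1/2 (uniform over the power set; `Z = 500` by default), an
  unbiased estimator with binomial error. When `2^|A| ≤ Z` the power set is
  enumerated outright, so the "approximate" value is bit-for-bit exact for
  the great majority of patterns (extents ≤ 8 at these data sizes) — which
  is why the zero-error fraction in calibration experiments is ≈99% rather
  than ≈5%: only large-extent concepts carry sampling error.

**Thresholds.** Chance patterns also have nonzero stability, so the
stability cut separating genuine patterns is an upper quantile of the *null*
stability distribution: stabilities of patterns mined from data carrying no
fine-temporal structure. Two null sources are supported: a dithered
surrogate of the data under analysis (the default for real recordings), and
— for validation sweeps — pooling over independent realizations of the
known background model, which sharpens the extreme quantile that the
Bonferroni correction demands (level `α / (n_tested · divisor)` with
`n_tested` the concepts tested per data set and `divisor = 2` when both
stability kinds are applied to the same patterns). The empirical quantile
uses the conservative ceiling-rank convention (`k = ceil(n · level)`-th
largest null value); a plain-quantile mode (`correction="none"`, e.g. the
95th percentile) exists behind a flag. Filtering is strict: a pattern passes
only if its stability strictly exceeds the threshold; the combined mode
keeps a pattern if either measure passes.

A single dithered surrogate contributes only a few hundred to a few thousand
null values at these data sizes; at Bonferroni-corrected levels that sample
cannot resolve the required quantile, which is why the pooled-null route is
used for quantitative validation and thresholds there are effectively the
null maximum.

## Significance: PSF and PSR

**Pattern spectrum filtering.** The p-value of a signature `(z, c)` is the
fraction of surrogates (independently dithered copies of the data; dither
half-width 5 ms by default, uniform displacement redrawn at the recording
edges so counts are preserved) containing at least one canonical filtered
pattern instantiating that signature. In the default *cumulative* counting
mode a surrogate pattern `(z, c')` instantiates every `(z, c ≤ c')`, which
makes p-values monotone in `c`; the literal exact-signature mode is
available behind a flag. Distinct signatures present in the original data
are tested jointly with Benjamini–Hochberg FDR control at `α = 0.01`;
patterns whose signature is rejected survive. The spectrum's resolution
floor is `1/n_surrogates` (at least 100 surrogates are required; 1000 is
the full-scale default), and each surrogate runs on its own child stream of
the master seed, so results do not depend on evaluation order.

**Pattern set reduction.** A genuine pattern inflates the significance of
its chance overlaps with background spikes. Every unordered pair of PSF
survivors with overlapping templates (overlap computed over all relative
shifts, so shifted sub-patterns are recognized) is re-tested conditionally
against the same BH significance map: the larger pattern at signature
`(z_A − z_cond + h, c_A)`, the contained pattern at `(z_B, c_B − c_A + k)`
(for partial overlaps both are size-conditioned on the common part), with
correction factors `h = 0`, `k = 2`. Conditioned signatures falling outside
the mined support (size or count below 3) are not testable and count as
non-significant. If both conditioned tests pass, both patterns are kept; if
one passes, the other is removed; if neither passes, the pattern covering
more spikes (largest `z·c`, ties to larger `z`, then lexicographically
smaller template) is kept. Removals are collected in a single pass over all
pairs and applied at the end, making the outcome independent of pair order.

## Synthetic ground truth

The generator produces the validation conditions the detection claims refer
to: `N = 100` independent Poisson neurons over `T = 1 s`, with background
rate models (i) stationary at 15/20/25 Hz, (ii) a coherent step (10 Hz with
a 60 Hz jump in [600, 700) ms), (iii) heterogeneous rates 5→25 Hz in 0.2 Hz
steps across neurons, and (iv) propagating 5 ms jumps from 14 to 100 Hz
across 20 groups of 5 neurons with sweep onsets at 50 and 550 ms. Injected
patterns are sequences of `z` spikes at a constant 5 ms lag (z = 10 spans
45 ms, fitting the 50 ms window) placed at `c` uniform onsets; occurrences
may overlap, and collisions with background spikes resolve by the binning
clip rule. Piecewise-constant inhomogeneous Poisson simulation is exact
(per-segment Poisson counts, uniform placement).

What the generator does **not** emulate: non-Poisson interval statistics
(bursting, refractoriness), correlated background noise, trial structure,
and jittered or partially participating pattern occurrences. Passing tests
therefore show correct behavior under independent-background nulls with
exact pattern repeats, not robustness to those real-data features.

## Scoring and validation harness

Scoring against ground truth is strict: a found pattern is a true positive
only if its (neuron, lag) composition equals the injected pattern exactly
(optionally also covering every injected onset); any other finding is a
false positive, and a truth without an exact match is a false negative. The
FP/FN harness sweeps injected signatures z, c ∈ {3..10}, runs R seeded
realizations per cell (counter-derived per-cell streams, so any cell is
reproducible in isolation), and reports per-cell FP/FN fractions; stability
methods reuse one set of model-level thresholds across cells, and a scaled
preset ships for desk-size runs.

## Problem sizes and reproducibility

The test suite exercises the full pipeline at 20–30 neurons (100
realizations for type-I control, 20 for stage counts) and the thresholds
and parameter-recovery checks at the full 100-neuron scale with 100
surrogates per realization. The acceptance script runs the 100-neuron
experiments at 100 realizations each and pools the stability null over 100
independent data sets. All randomness flows from explicit seeds
(`numpy.random.Generator`); identical seeds give byte-identical reports.

## Known limitations

* Exact stability is enumerative (≤ 25 elements); the lattice-based exact
  recursion is deliberately out of scope.
* PSF cost is dominated by `n_surrogates` mining runs; it parallelizes
  trivially but is serial here.
* Pattern duration is bounded by the window (`K·dt`); patterns spanning
  more than one window are invisible by construction.
* PSR's conditional tests reuse the original-data BH threshold; with very
  sparse spectra (few surrogates) conditioned signatures may be untestable
  and default to non-significant.
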