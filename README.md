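# spade-stp

Detection and statistical evaluation of **spatio-temporal spike patterns
(STPs)** — sequences of spikes with fixed millisecond-scale lags across
neurons that repeat above chance — in massively parallel spike train
recordings (~100 neurons and more). Such patterns are the predicted
fingerprint of synfire chains, braids and other cell-assembly models, but
finding them is hard: the number of candidate patterns grows exponentially
with population size, pattern size and lag structure, which defeats both
brute-force search and per-pattern statistics.

The package is aimed at computational and systems neuroscientists analyzing
parallel spike trains (or any set of parallel point processes), and at
method developers who need a transparent, oracle-tested reference
implementation with a ground-truth simulation suite.

## Method

1. **Mining.** Spike times are binned at `dt` (1 ms) and scanned with a
   sliding window of `K` bins (50). Window starts are objects and
   `(neuron, offset)` pairs attributes of a formal context; repeating STPs
   are exactly the *closed frequent itemsets* of that context — pattern =
   intent `B`, occurrence windows = extent `A`, signature
   `(z, c) = (|B|, |A|)`. A fast closed-itemset enumerator (verified against
   an exhaustive formal-concept oracle) extracts them; shift- and
   truncation-duplicates are removed and patterns with fewer than 3 spikes
   or 3 occurrences discarded.
2. **Stability branch.** The intensional stability
   `σ(A,B) = |{C ⊆ A : C' = B}| / 2^|A|` (and its extensional dual over
   intent subsets) measures how robustly the pattern is reproduced by
   sub-collections of its occurrences; it is computed exactly for small
   concepts and by uniform power-set Monte-Carlo (`Z = 500`) otherwise.
   Patterns are kept when their stability strictly exceeds a threshold set
   at a Bonferroni-corrected upper quantile of the stability null
   distribution from surrogate (spike-dithered) data.
3. **Significance branch (PSF + PSR).** The p-value of a signature `(z, c)`
   is the fraction of dithered surrogates containing a pattern with that
   signature; signatures present in the data are tested under
   Benjamini–Hochberg FDR control (pattern spectrum filtering), and
   surviving patterns are re-tested pairwise and conditionally on their
   overlaps (pattern set reduction, corrections `h = 0`, `k = 2`) to remove
   chance combinations of a true pattern with background spikes.

A ground-truth generator (stationary, coherent-step, heterogeneous and
propagating-rate Poisson backgrounds, plus lagged pattern injection) and a
strict FP/FN scoring harness reproduce the method's validation conditions.
See `docs/methods.md` for conventions, parameters and limitations.

## Worked example

`examples/01_detect_injected_pattern.py` simulates 30 independent 25 Hz
Poisson neurons for 1 s, injects an 8-spike pattern with 5 ms lags repeated
10 times, and runs mining + PSF + PSR with 100 surrogates:

```
injected: neurons (0, 1, 2, 3, 4, 5, 6, 7) at lags (0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0) ms, 10 occurrences
stage counts: {'mined': 142, 'filtered': 121, 'psf_kept': 6, 'final': 1}
found: neurons [0, 1, 2, 3, 4, 5, 6, 7] lags [0.0, 5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0] ms (z=8, c=10, p=0.000)
```

Mining returns 121 canonical frequent patterns, almost all chance; PSF
retains the 6 whose signatures never occurred in 100 surrogates (p below
the 0.01 resolution floor), and PSR removes the five that are overlaps of
the genuine pattern with background spikes. The single final pattern is
exactly the injected one. The other examples cover stability filtering, the
hand-checkable formal-context toy, the four background models and a small
FP/FN validation matrix. A thin CLI wraps the same calls
(`spade run`, `spade synth`, `spade validate`).

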