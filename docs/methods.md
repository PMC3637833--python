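# Methods

## Data model

A *peak* is one deconvoluted detection: compound name, CAS registry number,
first- and second-dimension retention times RT1 and RT2 (both in seconds;
RT2 values are typically a few seconds at most), peak area (> 0, arbitrary
abundance units), library-match similarity (integer 0–999) and optionally a
mass spectrum, stored sparsely as non-negative intensities over integer m/z
bins.  A *peak list* is the table of one technical replicate.  The grouping
key of a peak — the identity used by merging and by the naive aligner — is
its CAS number when non-empty, otherwise its lower-cased name; CAS is
preferred because names in real exports carry formatting noise.

## Peak merging

One compound frequently elutes as several nearby peaks.  Merging collapses
each grouping key to a single representative: the group member with maximal
area (area rule) or maximal library similarity (similarity rule).  The rule
changes *which* member represents the group, never *how many* groups there
are; both rules return exactly one peak per distinct key.  Ties on the
maximal value are broken by smaller RT1, then smaller RT2, so output is
deterministic.  Representatives are always input peaks — no averaging or
field synthesis.  Merging peaks with *different* identifications that merely
co-elute is out of scope.

## Matching score

The score aligner and the post-hoc cross-check share one matching score in
[0, 1]:

    score(a, b) = w · spectral(a, b) + (1 − w) · closeness(a, b)

* `spectral` is either the cosine of the two intensity vectors aligned onto
  the union of their m/z bins (`dot`, default; in [0, 1] for non-negative
  intensities) or the Pearson correlation clamped below at 0 (`pearson`).
  Clamping, rather than rescaling [−1, 1] to [0, 1], reflects that
  anti-correlated spectra are non-matches, and keeps the cutoff grid
  interpretable as a similarity.  A zero-norm or (for Pearson) constant
  spectrum raises an error rather than returning an arbitrary value.
* `closeness` = exp(−[ΔRT1² / 2σ1² + ΔRT2² / 2σ2²]), a separable Gaussian
  kernel on the RT offsets; 1 iff both RTs coincide, strictly decreasing in
  each |Δ|.

Defaults: w = 0.5 (equal weight), σ1 = 5 s, σ2 = 0.05 s, candidate search
windows 3σ per dimension.  These are plausible scales for GCxGC columns, not
instrument calibrations, and are fully configurable (`ScorerConfig`).

## Aligners

`naive_align` pairs peaks of two *merged* lists whose grouping keys are
equal — one pair per shared key, unscored (the post-hoc scores them lazily
with whatever scorer is active, since the cross-check must use the method's
own scoring system).

`score_align` is a greedy best-hit matcher: all within-window pairs are
scored, then accepted in descending score subject to the one-to-one
constraint.  Greedy — not optimal assignment — mirrors best-hit matching as
practised; on well-separated data the two coincide (tested against
brute-force enumeration on small instances).  Ties are broken by smaller
2-D RT distance and then by the order-insensitive key pair, which makes the
result deterministic and symmetric under swapping the two lists.  Full
score-based alignment methods (dynamic-programming, likelihood-optimised,
or Bayesian matchers) are deliberately not reimplemented: any of them can be
supplied as a ready-made `PairwiseAlignment` whose pairs carry scores in
[0, 1], which is the only interface the post-hoc consumes.

## Pairwise post-hoc

Given the naive and the method alignment of one replicate pair (pair
identity = equal index pair), the Venn partition yields CA (both), DA1
(naive only) and DA2 (method only).  The positive set is

    CA  ∪  {p ∈ DA1 : score(p) > cutoff1}  ∪  {p ∈ DA2 : score(p) > cutoff1}

with a *strict* inequality, CA kept without any score test.  Unscored pairs
are scored at integration time.  Consequences worth noting:

* the positive set is monotone non-increasing in cutoff 1, bounded between
  CA and the union;
* it need not be one-to-one (the union of two one-to-one alignments is
  not); the container relaxes that invariant for positive sets only;
* the method's own pairs can be *removed* (DA2 pairs failing the cutoff),
  so integration at a high cutoff acts as a filter, while a low cutoff acts
  as a rescue of name-confirmed pairs the best-hit constraint discarded.

The standard cutoff-1 grid for sweeps is
0.5, 0.6, 0.7, 0.8, 0.85, 0.9, 0.93, 0.95, 0.97, 0.99.

## Global post-hoc

For n ordered replicates, pairwise integration is applied to each contiguous
pair (E1,E2) … (En−1,En) — never across non-adjacent replicates — and the
positive pairs are chained.  A chain is kept only if it spans all n
replicates; because positive sets may branch, every complete path is
enumerated.  Cutoff 2 then applies to the number of chain members sharing
the modal name: the chain is kept iff that count is ≥ cutoff 2, where
n/2 < cutoff2 ≤ n (a majority, so at most one name can qualify — asserted).
The weaker ≥ (not strict) is used here so that, e.g., a 4-replicate chain
with three agreeing names passes at cutoff 2 = 3.  With name correction
enabled, minority names in kept chains are replaced by the modal name and
the consensus count updated; correction never changes which chains are kept.
Modal ties (possible when n is even) are resolved lexicographically for
determinism and can never satisfy cutoff 2.

## Performance measures

Eight pairwise measures over the pairs of an alignment (all "smaller is
better"); per pair with RTs (a1, a2), (b1, b2):

* d1 = |a1−b1|, d2 = |a2−b2|, d = √(d1²+d2²);
* cv1 = sd(a1, b1) / mean(a1, b1), cv2 analogous, with *sample* sd
  (denominator n−1), so sd(a, b) = |a−b|/√2.

DRT1/DRT2 = mean d1/d2; DMRT = (DRT1+DRT2)/2; DRT = mean d (2-D Euclidean,
which is what distinguishes it from DMRT); CRT1/CRT2 = mean cv1/cv2;
CMRT = (CRT1+CRT2)/2; CRT = mean of (cv1+cv2)/2.  CRT and CMRT coincide
algebraically by linearity of the mean; both code paths are kept and
asserted equal as a cross-check rather than collapsed.  The global variants
replace per-pair quantities with per-chain ones: mean over all C(n,2)
within-chain pairwise distances, and the CV of the chain's n retention
times.  Measures are computed on raw seconds, without RT normalisation.
Empty inputs raise an error rather than returning zero — a zero would
silently mask over-filtering at extreme cutoffs; sweeps record NaN for such
combinations instead.

## Synthetic data

The generator emulates homogeneous technical replicates: one compound
library (default 76 compounds, 10 replicates; uniform base RTs over
300–3300 s and 0.8–5 s, log-normal base areas, sparse random spectra with
10% of 500 bins occupied) shared by all replicates, each of which applies:

* RT jitter — Gaussian, sd 5 s (RT1) and 0.05 s (RT2);
* abundance noise — multiplicative log-normal, sd 0.3 in log space;
* spectral noise — multiplicative log-normal per intensity, sd 0.05;
* similarity jitter — Gaussian, sd 15, clipped to [0, 999];
* dropout — each compound missing with probability 0.1;
* splitting — with probability 0.4 a compound emits 1–4 trailing sub-peaks
  (RT1 offsets of a few seconds, smaller areas, lower similarities),
  motivating merging;
* misidentification — each emitted peak's name/CAS swapped, with
  probability 0.05, for another library compound's.  Swapping to an
  existing identity (not a novel fake name) is what makes naive alignment
  produce plausible *false* pairs, the error mode the post-hoc filters;
  applying it per emitted peak (after splitting) lets split fragments
  escape their merge group, which is why merged counts can exceed the
  library size, as real exports show.

A `TruthMap` records the generating compound of every emitted peak, so
precision (per pair) and recall (per compound represented in both lists)
are exact.  Everything is deterministic given the config seed (library and
replicates use separate seed streams).

The generator does *not* emulate raw 2-D chromatogram signal, co-elution,
detector saturation, heterogeneous samples, or RT drift that is systematic
rather than independent per replicate.  Passing tests on this data
demonstrate the algorithmic properties of the integration — not instrument-
level performance on real chromatograms.

## The recovery experiment and the choice of cutoff 1

The headline synthetic experiment (2 replicates, defaults above, 20 seeds)
checks that the positive set's F1 against ground truth never falls below
the naive alignment's and that its recall never falls below the score
alignment's.  It runs at cutoff 1 = 0.4, chosen a priori from the score's
structure rather than from the grid: with w = 0.5, a name-confirmed pair
whose spectra are intact but whose RT closeness has been destroyed by
jitter scores just under w·1 = 0.5, so any cutoff ≥ 0.5 cannot recover such
pairs, while misidentified pairs — cosine of two unrelated sparse spectra,
typically ≲ 0.2 — score well below 0.4.  The same threshold guarantees that
no true method pair (spectral similarity ≈ 1, hence score ≥ ~0.5) is ever
removed from DA2, which is what makes the recall bound hold seed by seed.
At high cutoffs (e.g. the grid's 0.99) the recall bound is *not* expected to
hold — there integration trades aligned-peak count for RT reproducibility,
which is the behaviour the sweep and measures expose.

## Numerical and degenerate-input choices

* Strict `>` for cutoff 1 (so cutoff 1 = 1.0 reduces the positive set to
  CA); `≥` for cutoff 2.
* Score ties in the greedy matcher: RT distance, then key pair.
* Merging ties: smallest RT1, then RT2.
* Reader: delimiter auto-detected between comma and tab; decimal points
  only; lenient mode (default) skips malformed rows with a logged count,
  strict mode raises with the line number.  Floats are written with `repr`
  so write→read round-trips exactly.
* Empty alignments/chain sets: errors in metrics, empty outputs elsewhere.

## Problem sizes

Tests and the acceptance script run on desk-scale instances: libraries of
15–76 compounds, 2–4 replicates, 20-seed repetitions — large enough to
exercise every code path and the statistical claims (binomial checks use
3-sigma tolerances; the sign test uses α = 0.01), small enough to run in
seconds.
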