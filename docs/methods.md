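# Methods

## Model

A neighborhood decision system is a table (U, C, D, δ): *n* samples U,
*m* real-valued conditional attributes C, one categorical decision D,
and a radius δ ∈ [0, 1].  On an attribute subset B ⊆ C, the
neighborhood class of a sample is every sample within Euclidean
distance δ of it, the boundary inclusive.  Distances are computed on
the raw (or user-normalized) attribute values; there is no per-dimension
rescaling of the metric by |B|, so the neighborhood of a fixed sample
can only shrink as attributes are added.  The empty subset granulates
nothing: n_∅(x) = U.

The decision partition's lower approximation under B (samples whose
whole neighborhood shares their label region) and upper approximation
(samples whose neighborhood touches a label region) give the
approximate precision p_B(D) = |lower| / |upper|; reflexivity makes the
upper approximation all of U, so p_B(D) = |lower| / n.  The decision
neighborhood entropy

    H_δ(D, B) = −(p_B(D)/n) Σᵢ log₁₀(|n_B(xᵢ) ∩ [xᵢ]_D|² / (n · |[xᵢ]_D|))

is the quality score used throughout.  It is nonnegative, bounded by
arguments of the per-sample credibility × coverage product (the
intersection always contains the sample itself, so no log(0) arises; a
zero intersection is treated as a broken index and raised, never as
0·log 0), monotone non-decreasing under attribute addition, and
dominates the precision-weighted plain average entropy on every subset.
These three guarantees are enforced as tests over exhaustively
enumerated subset pairs on randomized small systems.

## Parameters

- **δ (radius), default 0.3 in the selector.**  Governs granule size;
  on [0, 1]-scaled data useful values lie roughly in [0.05, 0.5].  Too
  small makes every neighborhood a singleton (the entropy saturates at
  its maximum and all attributes look alike); too large makes every
  neighborhood impure (precision 0, entropy identically 0 and nothing
  is selectable).  The demonstration table uses 0.3; the synthetic
  recovery setting uses 0.15.
- **Log base, default 10.**  The published per-subset values of the
  worked example (0.0753, 0.1505) are base-10 quantities; any base > 1
  is accepted and rescales all entropies by a constant.
- **Equality tolerance, default 1e−12 (absolute).**  Entropy equality
  (greedy termination, redundancy pruning, reduct checks) is a
  floating-point sum comparison; 1e−12 is far below the smallest
  nonzero entropy gap any small table can produce.
- **Boundary tolerance, 1e−12 on (distance − δ).**  The membership rule
  is inclusive; the tolerance keeps pairs whose true distance equals δ
  from dropping out through rounding (the demonstration table has such
  a pair).
- **Normalization.**  Min–max scaling is an explicit, separate step
  (`normalize_min_max`; `ARDNESelector(normalize=True)` by default, the
  CLI's `--no-normalize` turns it off).  The demonstration table is
  used unnormalized since its columns already lie within [0, 1].

## The greedy search

Forward phase: each round evaluates H_δ(D, R ∪ {a}) for every remaining
attribute and adds the maximizer, ties broken toward the smallest
column index; the loop stops when H_δ(D, R) reaches H_δ(D, C) within
tolerance, or an iteration cap fires.  Plateau rounds (no strict
improvement) still add the argmax: the entropy is monotone, so a
remaining gap can only ever be closed by adding more attributes, and
termination is guaranteed because R = C closes the gap by identity.
Backward phase: the selected attributes are revisited in selection
order and removed whenever the remaining subset still attains the
full-set entropy, the working subset mutating as members fall out.

The greedy result always preserves the full-set entropy; minimality is
not guaranteed in general, so an exhaustive enumerator of inclusion-
minimal entropy-preserving subsets (guarded to ≤ 20 attributes) serves
as the oracle in tests.  On tables whose full-set entropy is zero
(every neighborhood impure at the given δ) no attribute is ever
indispensable and the empty subset is the only true reduct; the greedy
returns it, while the enumerator — which by contract scans nonempty
subsets — reports bare singletons.  Candidate evaluation recomputes
neighborhoods per subset; no caching that could alter results is used.

## Synthetic data

`generate_synthetic` emulates the shape of expression-matrix feature
selection: `n_informative` attributes get per-class Gaussian values
whose means sit on an equally spaced grid (`class_separation` apart,
centered in [0, 1]), `n_noise` attributes are uniform on [0, 1]
independent of class, labels are balanced to within one sample, and
every column is min–max rescaled (rescaling rather than clipping avoids
probability spikes at the bounds).  Defaults: 40 samples, 2 informative
+ 8 noise attributes, 2 classes, separation 0.6, within-class sd 0.05.
It does **not** emulate gene–gene covariance, batch effects, heavy
tails or class imbalance, so passing tests on it show correctness of
the machinery and behavior under an idealized signal-plus-noise model,
not performance on real transcriptomes.

A caveat the test suite documents deliberately: under these defaults at
δ = 0.15, the *full* attribute set granulates every sample into a
singleton (eight uniform noise dimensions push all pairwise distances
past δ), so the termination entropy is the degenerate maximum.  The
greedy's first pick is essentially always a planted informative
attribute (only informative columns produce decision-pure granules,
hence nonzero precision), but subsequent rounds favor noise columns —
they shrink neighborhoods faster than the second informative column
does — so the final reduct usually contains one informative attribute
plus noise rather than both planted ones.  The recovery test asserting
both are found reflects this and fails; the first-selection property is
the one the generator's conditions actually support.  Choosing a
radius commensurate with the selected subspace's dimension, or
penalizing granule shrinkage that adds no precision, would be the
natural remedies, but both would change the published method and are
out of scope.

## Evaluation harness

Cross-validation is repeated stratified k-fold (default 10 × 10) with a
seeded fold PRNG, so accuracies are exactly reproducible; classifiers
are off-the-shelf 3-nearest-neighbors and linear-kernel SVM.  If a
class has fewer samples than the fold count the fold count shrinks to
the largest stratifiable value; a single-sample class is rejected.
Rank tables use fractional (mean) ranks for ties — the only convention
that conserves each row's rank sum at k(k+1)/2 — and the Friedman
chi-square is computed from average ranks, cross-checked in tests
against an independent implementation on tie-free tables.  The
Iman–Davenport F is flagged undefined when its denominator N(k−1) − χ²_F
vanishes.  Bonferroni–Dunn q values are built in for α ∈ {0.05, 0.10},
k ≤ 10; callers may pass any q explicitly.

## Known limitations

- Continuous conditional attributes only; no mixed-type distances,
  missing-value handling, or Manhattan/Chebyshev metrics.
- The greedy search is O(m³n²) worst case in this implementation
  (neighborhoods recomputed per candidate); fine for thousands of
  attributes only with modest sample counts.
- δ is a single global radius; no per-attribute or adaptive radii.
- The decision neighborhood entropy rewards granule shrinkage even when
  the shrinkage adds no decision information (see the synthetic-data
  caveat above), which matters when many irrelevant attributes are
  present at small δ.
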