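# Methods

This note documents the models, parameter choices and numerical decisions
behind `betapipe`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Sketching and the Mash distance

A sequence set is decomposed into canonical k-mers: for every window of
length `k = 21` containing only A/C/G/T, the lexicographically smaller of
the window and its reverse complement (with A<C<G<T, this equals the
numerically smaller 2-bit packed code). Windows touching any other symbol
are skipped. Codes are hashed with a splitmix64 finalizer seeded with 42;
the hash identity is stored in every sketch as `hash_tag = "splitmix64-42"`
and sketches with different tags, k, or capacity are never comparable. The
sketch keeps the `s = 10000` smallest distinct hash values among k-mers
whose exact occurrence count is at least `m` (`m = 2` for reads, suppressing
error k-mers, which are overwhelmingly singletons at ~5-fold coverage;
`m = 1` for assemblies, whose single-copy k-mers are real). The copy filter
uses exact global counting, not a probabilistic shortcut.

Two sketches are compared with the merged bottom-s estimator: with `X` the
`min(s, |union|)` smallest values of the merged hash sets, the Jaccard
estimate is `j = |X ∩ A ∩ B| / |X|`. The Mash distance is
`D = -ln(2j/(1+j))/k`, clamped to [0, 1]; `j = 0` maps to the saturation
value `D = 1` (rather than infinity) because the tree stage requires finite
distances. At `s = 10000` the estimator standard error is approximately
`sqrt(j(1-j)/s)`; this noise floor — about 2e-4 on a distance near 0.01 at
full coverage, and roughly ten times that at 1-fold coverage — is the
quantity that decides which branch lengths the pipeline can resolve.

Distinct k-mers may collide in 64-bit hash space; collisions are accepted
as estimator noise.

## Read quality control

Trimming applies, per read: LEADING (drop 5' bases with quality < 28),
TRAILING (drop 3' bases < 28), SLIDINGWINDOW (scan 5'→3' with a 5-base
window; at the first window with mean quality < 15, cut the read before
that window's start and keep through the last base with quality ≥ 15), and
MINLEN 50. One deliberate refinement: after a window cut, the trailing rule
is re-applied to the survivor. Without it, a window-cut read can end on a
base with quality in [15, 28), and a second pass would trim further; with
it, trimming is exactly idempotent, which the test suite asserts on random
quality strings. The rule is frozen here and tested bit-exactly; no claim
of bit-compatibility with any external trimmer is made. Mates are trimmed
independently — downstream sketching ignores pairing, so no pair-rescue
logic exists.

Coverage is total bases over an assumed genome size. Downsampling keeps
whole fragments (mate pairs) independently with probability target/current,
so pairs survive together. Organelle removal replaces read mapping with
exact canonical k-mer membership: a fragment sharing at least `min_shared`
(default 1) 21-mers with the organelle references is discarded. At k = 21
the chance of a spurious match between unrelated megabase-scale sequences
is ~ L·ℓ/4^21 and negligible; the spike-in experiment verifies the filter
against truth labels.

## Distance matrices and the Mantel test

Rogers' distance between two individuals is computed from 0/1/2 genotype
codes as allele frequencies p ∈ {0, ½, 1}: each marker non-missing in both
rows contributes |p − q|, averaged over the jointly non-missing markers
(pairwise-complete, the standard reading of treating absent calls as
missing; global complete-case deletion would discard data needlessly).

The Mantel test correlates the upper triangles of two label-aligned
matrices (alignment is always by name, never by position) and permutes rows
and columns of the second matrix jointly; the one-sided p-value is
`(#{r_perm ≥ r_obs} + 1)/(permutations + 1)` with 999 permutations by
default. The implementation is vectorized and fully seeded so experiment
reports are byte-reproducible; an independent library implementation is
used as a cross-check in the tests, not as the implementation.

## Tree inference

Fitch–Margoliash least squares minimizes
`SSE = Σ_{i<j} (d_ij − p_ij)² / d_ij^power` with `power = 2` (the classic
criterion; the weighting exponent is a package default, configurable).
Zero distances — expected between duplicates of one accession — are floored
at 1e-9 in the weights. Branch lengths are fitted by weighted least squares
on the pair-edge incidence system and clamped at zero; when the unclamped
solution goes negative on a final fit, a non-negative least-squares solve
replaces it. The search is stepwise addition under a randomized taxon order
(jumbling; 5 orders by default, 3 in the bundled experiment configs),
followed by nearest-neighbor-interchange sweeps and, when global
rearrangements are enabled, subtree-pruning-and-regrafting sweeps over all
prune/regraft positions, alternating with NNI until no strict improvement.
Equal-SSE ties resolve to the first-found candidate under the seeded
order, making runs reproducible. Jumbling stops early once a perfectly
additive fit (SSE ≈ 0) is reached, since nothing can improve on it. On
additive matrices the optimum is recovered exactly (verified against
neighbor joining and the generating tree over 100 random replicates);
equivalence of the *search path* with any particular legacy program is not
claimed, only of the optimum on clean inputs.

Quartet distance is computed by direct enumeration over all C(n,4) leaf
subsets using the four-point condition on unit-branch-length path matrices;
with binary trees every quartet is resolved and the minimum pairing is
unique. This is O(n⁴) and intended for n ≤ ~60, which covers all panels
here; the raw differing-quartet count is reported, unnormalized. An
independent bipartition-based implementation serves as the oracle in tests.
Outgroup rooting places the root at the midpoint of the edge separating the
outgroup set and fails loudly if no such edge exists.

## Synthetic scenarios

The generator emulates the statistical structure the analysis relies on,
not beet biology in detail. The truth tree is
`(outgroup, (atlantic, (cultivar, mediterranean)))` with random binary
subtrees per group; genomes evolve by Jukes–Cantor substitution (root
uniform over ACGT; along a branch of length t each site substitutes with
probability (3/4)(1 − e^{−4t/3})). Defaults: 3 groups × 4 accessions + 1
outgroup, 1 Mb genomes, deep split 0.02 substitutions/site, cultivar split
0.004, outgroup depth 0.05, heterozygosity 0.003 — chosen so pairwise Mash
distances land around 0.02–0.07, the magnitude printed for real beet
panels. Diploids duplicate the genome and resample haplotype 2 at the
heterozygosity rate; duplicate "individuals" of an accession share
haplotype 1 and differ only in that resampling. Reads are 2×125 nt pairs
with a fixed 580 bp insert (optional normal jitter), uniform substitution
errors at 0.5%, and constant Q40 qualities — the trimming stage is
exercised on purpose-built low-quality fixtures instead of a realistic
quality ramp. Genotypes ascertain biallelic sites polymorphic across the
panel (no monomorphic markers, as on a curated array) and mask entries
missing at random.

Three scenarios differ only in within-group spacing and duplication:

* `beet-mini` — within-group branches ~0.001: accessions nearly as close
  as the heterozygosity floor, the hard regime;
* `beet-mini-wide` — within-group ~0.01: a panel of well-separated taxa,
  matching the design of the coverage-titration experiment, which was run
  on distinct species and subspecies rather than near-identical accessions.
  The 0.001 spacing is provably unresolvable at 1-fold coverage (signal
  ~0.001 vs estimator noise ~0.002 per distance), so titration topology
  claims are made — and tested — in the wide regime only;
* `beet-mini-dup` — wide spacing plus two accessions per group sequenced
  twice. Duplicate pairs only (no triplicate): a sibling-pair statistic is
  undefined for triples, whose clade-level placement is covered by the
  monophyly checks instead.

What passing these experiments shows: the pipeline's inferences are correct
when data are generated under its own assumptions, at realistic divergence,
coverage, error and heterozygosity scales. What it does not show: robustness
to repeats, GC bias, PCR duplicates, indels, structural variation,
contamination, or uneven coverage between accessions — none of which the
generator produces. The coverage-dependence experiment itself demonstrates
why comparable per-accession coverage matters: estimated distances inflate
as coverage drops, so mixed-coverage panels would distort distances
systematically.

## Classification of unlabeled accessions

The original procedure — reading an accession's placement off a published
tree figure — is operationalized as two independent, reportable signals:
(1) the majority group among the 5 nearest labeled accessions by distance,
ties broken by the smallest mean distance to the tied groups; (2) whether
the accession falls inside the smallest clade containing at least 90% of
the proposed group's labeled members (the 90% absorbs occasional scattered
outliers). Disagreement between the signals is reported, not hidden. With
very few labeled members per group the clade signal degenerates (the
smallest 90% clade of a single labeled member is that leaf), so the
distance signal is the primary one in hold-out scoring.

## Problem sizes and numerical settings

The bundled experiments run 13-taxon (20 with duplicates) panels on 1 Mb
genomes: large enough that k-mer statistics, the m = 2 filter and the
estimator noise floor behave as they do at genome scale, small enough that
the full validation battery completes in minutes on one CPU. Tolerances in
tests are derived, not tuned: binomial 3–4σ bands for simulated counts,
`4·sqrt(j(1-j)/s)` for the Jaccard estimator, exact equality for additive
tree recovery and closed-form values. The k-mer scan uses a numba kernel
when available and a pure-numpy fallback otherwise; both are tested for
exact agreement.

## Known limitations

* Substitution-only evolution (no indels): Mash distances respond to
  substitution divergence, and indels would add no testable signal here.
* Mash `.msh` files are not read or written; sketches use a documented JSON
  container, and the hash differs from other tools' (by design, flagged via
  `hash_tag`).
* The Fitch–Margoliash search is exact only in the sense of recovering
  additive optima; on noisy data it is a well-behaved heuristic, like every
  least-squares tree search.
* Quartet distance is brute-force O(n⁴); for hundreds of taxa a
  sub-quartic algorithm would be needed.
* p-values for shared-hash counts and containment estimators are out of
  scope.
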