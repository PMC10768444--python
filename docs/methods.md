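# Methods

This note documents the models and procedures implemented in `tcrdiv`, the
parameter choices that matter, and what the synthetic data do and do not
establish.

## Clonotype model and the read-to-clonotype caller

A clonotype is a unique V–CDR3–J rearrangement identity (nucleotide level; no
α–β or γ–δ chain pairing).  δ-locus rearrangements are excluded from
repertoires because α-locus recombination deletes the TRD locus, making δ
data incomparable across samples.  The caller mirrors the targeted-gDNA
protocol:

* **QC**: both mates ≥ 250 bp with every base Phred > 20 (strict
  inequality).  The length rule is interpreted as *at least* 250 bp: a 2×250
  protocol cannot produce longer reads, so a strictly-greater rule would
  discard everything.
* **Demultiplexing/UMI**: the 4 bp validation barcode must match on both
  mates; the two 6 bp mate UMIs are concatenated mate-1-first into a 12 bp
  fragment UMI (the concatenation order is a convention; any fixed order is
  equivalent).  Library IDs are required to be pairwise Hamming distance ≥ 2
  so a single sequencing error cannot silently reassign a read.
* **Tag scanning**: exact string match of 20-base tags positioned 15 bp from
  each segment's predicted RSS cleavage point, on both strands, for coding
  and signal flanks.  Allelic variants are additional exact tags.  Tags
  shared between segments (rtags) are resolved by secondary alt-tags at the
  nearest point of divergence; if zero or several candidates match the alt
  window the hit is reported ambiguous rather than guessed.  A read
  contributes a junction only when a V tag and a J tag of one locus co-occur
  in a recombination-compatible conformation; signal-joint conformations are
  recorded but never enter repertoires (diversity uses coding joints).
* **CDR3 boundaries**: walking from each tag toward its cleavage point while
  comparing the read to the germline reference, the junction boundary is the
  predicted cleavage position or the first divergence, whichever comes
  first.  Exonucleolytic trimming therefore widens the called CDR3 into the
  junction, which is exactly the convention the simulator uses for its truth
  junctions — truth and call are comparable by string equality.  Boundaries
  that cross (V past J) reject the call as incoherent.
* **Productivity**: a cassette is productive iff the V reading frame is
  carried through the junction onto the J segment's designated codon lattice
  and no in-frame stop codon occurs anywhere in the assembled cassette.  The
  frame test uses the junction boundaries actually called, so it is
  invariant to where the divergence walk happens to place the boundary.
  Only productive coding joints are analysed further.
* **UMI deduplication**: within one clonotype of one sample, 12 bp UMIs
  within Hamming distance 2 are merged *transitively* (single-linkage
  connected components over the ≤ 2-mismatch graph).  Components are used
  rather than greedy absorption into high-support representatives because
  components are order-independent, deterministic, and exactly match the
  brute-force graph oracle used in the tests; the two schemes differ only on
  rare chained UMI triples.  The deduplicated component count is the
  molecule count, i.e. the measured clonal-expansion size.
* The repertoire is keyed by (V, CDR3, J).  A D-segment call, when its tag
  survives junctional trimming, is kept as annotation only: the CDR3
  nucleotides already contain all D-derived sequence, so the key loses no
  information, and keying on an unreliably detectable D would corrupt counts.

Every input read pair lands in exactly one accounting bin
(pass / QC-fail / barcode-fail / no-conformation / incoherent), so read
conservation is checkable.

## Diversity profiles and distances

For a count vector with frequencies pᵢ the Rényi entropy of order α is
H_α = log(Σᵢ pᵢ^α)/(1−α) in nats (natural log throughout; the unit cancels
in comparisons).  α = 0 gives log richness; α = 1 is evaluated directly as
Shannon entropy, with grid values within 10⁻⁹ of a special order snapped
rather than approached numerically; large α tends to −log max pᵢ
(Berger–Parker).  The default profile grid is [0, 10] with step 0.2
(51 points); a wider [0, 20]/0.1 grid (201 points) is available for
sensitivity checks.  Profiles are computed on the multiplicity-compressed
count vector with a max-shifted power sum, so they are cheap and stable even
at depth 10⁵ and α = 20.

Sample pairs are compared at equal depth: the deeper member is down-sampled
without replacement (multivariate hypergeometric) to the shallower depth and
the shallower member used as-is.  The pair distance is the Euclidean norm of
the profile difference; one down-sampling draw per pair is the default
(configurable averaging over replicate draws).  Per-pair RNG streams are
derived from the master seed and the *unordered* id pair, making the matrix
symmetric, reproducible and invariant to sample order.  "All chains
combined" concatenates the per-chain profiles of a pair before the norm,
equivalently the root of summed squared per-chain distances.

## Classical MDS

Torgerson scaling: B = −½·J·D²·J, eigendecomposition, coordinates from the
top non-negative eigenpairs scaled by √λ.  Down-sampling noise makes
empirical distance matrices slightly non-Euclidean; negative eigenvalues are
clipped with a warning and their dimensions suppressed, the standard
classical-scaling convention.  Embeddings are compared only through pairwise
distances (rotation/reflection invariance).

## P-SVM classification and permutation testing

The distance matrix is used directly as a relational data matrix K (rows =
samples, columns = reference samples).  K is not a Mercer kernel — it is
indefinite, and after a held-out sample's column is dropped not even square —
which is why an ordinary kernel SVM is inapplicable and the Potential
Support Vector Machine is used: columns of K are treated as features and a
sparse weight vector α over them is fit by the box-constrained ℓ₁-penalised
least-squares dual

minimise (1/2n)‖Kα − y‖² + ε‖α‖₁  subject to |αⱼ| ≤ C,

with y ∈ {−1, +1}, bias b = mean(y − Kα), and prediction sign(k·α + b).
Columns are standardised on training rows so C and ε are comparable across
problems.  The solver is exact cyclic coordinate descent
(soft-threshold + clip per coordinate), compiled with numba; its optima
agree with a generic constrained-QP solver to ≤ 10⁻⁶ on all small test
instances, which is the correctness standard for this component.

Defaults C = 10, ε = 0.05 were chosen so that the box is loose and the ℓ₁
term prunes uninformative reference columns without degrading separable
problems; a leakage-free per-fold inner grid selection is available
(`loocv(..., param_grid=...)`) but is not the default because it multiplies
the cost of every permutation by the grid size.

Cross-validation is leave-one-out with the held-out sample removed both as a
row and as a reference column.  The score is balanced accuracy (mean of
per-class recalls), robust to the unequal group sizes that QC exclusions
produce.  Significance: labels are shuffled (class sizes preserved), the
full LOOCV is re-run per shuffle, and p = (1 + #{perm ≥ obs})/(1 + n_perm)
(add-one rule, so p ≥ 1/(n_perm+1) and never 0).  Runs capped below the
requested shuffle count carry a `truncated` flag.  Because balanced accuracy
takes finitely many values, tied permutation scores make this estimator
*conservative*, not exactly uniform, under the null; the result object
exposes the tie counts so the exactly-uniform tie-randomised p-value
(V + U·(T+1))/(N+1) can be formed, which is what the calibration suite
KS-tests.  Families of comparisons (3 primary and 6 secondary group
hypotheses, each tested for 2 cell types × 3 chains: 18, 36, and 54 tests)
are Bonferroni-corrected at α/m.  The pooled "Cases" group in the secondary
family is configurable (ME only, or ME plus the disease-control group);
neither reading is privileged.

## Synthetic data: what it emulates and what it does not

The simulator reproduces the statistical features the analysis relies on:

* **Toy germlines** default to 8 V / 2 D / 4 J per locus (D only at TRB) —
  small enough for exhaustive oracle checks, rich enough to exercise tag
  ambiguity.  V segments carry a 90 bp stop-free in-frame coding region and
  a 40 bp signal flank with the RSS cleavage point at the boundary; J
  segments the mirror image with a designated coding frame; every segment is
  pairwise distinguishable by all of its 20-mers so a tag library is
  derivable.
* **Recombination** draws geometric exonuclease trims (capped at 12 bp so
  identification tags survive) and Poisson-length N-insertions, with a
  trimmed D core at TRB.  Truth junctions are canonicalised by the caller's
  own divergence-walk rule and truth productivity by the caller's frame
  rule, so round-trips are exact string comparisons.
* **Clone sizes**: a fraction `expansion_fraction` of clonotypes is
  expanded, the rest are singletons.  When the per-sample total is fixed,
  the excess reads are spread over the expanded clones as a uniformly random
  composition — exactly the conditional law of i.i.d. geometric sizes given
  their sum (the geometric likelihood depends on sizes only through the
  sum), with a closed-form negative-hypergeometric marginal used for
  goodness-of-fit testing.  With a free total, sizes are
  1 + Geometric(`expansion_shape`) i.i.d.  This resolves the tension between
  an exact total and an i.i.d. heavy-tailed law without ad-hoc repairs.
* **Cohorts**: per-sample depths log-uniform over a configurable range
  (default [10³, 10⁵], spanning two orders of magnitude; the validation
  study uses [10³, 10⁴]), richness 0.5 × depth, and a group effect that adds
  `effect_delta` to the expanded fraction of designated groups only;
  `effect_delta = 0` yields exchangeable groups for null calibration.
  Cohort repertoires use abstract clonotype identifiers by default (only the
  count structure feeds the diversity analysis); sequence-level cohorts are
  available for read-level studies.
* **Reads**: fragments of 250–350 bp starting inside the V segment, 2×250 bp
  mates with the adapter prefix, per-molecule 12 bp UMIs, Poisson PCR
  duplication whose copies carry up to 2 UMI substitutions, and uniform
  substitution errors from an RNG stream independent of the structural
  draws (so error rate changes do not perturb fragment/UMI layout).

Not emulated: real IMGT germline content and allele frequencies, thymic
selection, non-uniform error profiles, indels, and chimeric reads.  Passing
round-trip and calibration tests therefore demonstrates internal
correctness of the pipeline — that the caller inverts the generative process
and that the permutation machinery is calibrated — not performance on real
sequencer output.

## Numerical and design choices

* Down-sampled distances make matrices slightly non-Euclidean → MDS clips
  negative eigenvalues (warning) rather than failing.
* Permutation seeds, per-pair down-sampling seeds and per-stage pipeline
  seeds are all derived from a single master seed (SeedSequence / hashing),
  so every table is byte-identical across re-runs of one configuration.
* The coordinate-descent solver treats a zero curvature coordinate
  (G_jj = 0) by moving to the box edge when the linear term beats ε,
  otherwise to 0.
* The CMV-serostatus association test is a Pearson χ² of the full
  serostatus × group table including the Equivocal row, without continuity
  correction; all-zero rows/columns are dropped with a warning.  On the
  study's printed 3×4 table this yields χ² = 4.76, df = 6, p = 0.58.
* Validation-study sizes (20 replicates of 20 vs 20 samples, 199 shuffles,
  expanded fraction 0.05 vs 0.35, depths 10³–10⁴) are the package's standard
  demonstration conditions; at these sizes the full study runs in minutes on
  one CPU.

## Known limitations

* Signal joints are detected and counted but their junctions are not
  reconstructed (they never enter diversity analysis).
* Tag matching is exact; a sequencing error inside a 20-base tag loses the
  read (the QC filter makes such reads rare, and UMI counting makes the loss
  depth- rather than bias-inducing).
* With several thousand UMIs in a single clonotype, pairwise dedup is
  quadratic; at the molecule counts this pipeline targets (≤ 10⁴ per sample
  spread over many clonotypes) this is negligible.
* The P-SVM hyperparameters are fixed defaults rather than per-comparison
  tuned; the permutation test remains valid for any fixed rule, but power
  on real data may benefit from the optional inner-fold grid search.
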