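# tcrdiv

Diversity analysis and group classification of T-cell receptor (TCR)
repertoires from targeted genomic DNA sequencing.

The adaptive immune system generates TCR diversity by somatic V(D)J
recombination; chronic disease can reshape a person's repertoire through
clonal expansion of particular T-cell lineages.  `tcrdiv` implements a
complete pipeline for asking whether repertoires differ *in their diversity
structure* between donor groups (e.g. disease cases vs. healthy controls,
profiled separately for CD4⁺/CD8⁺ cells and the α, β and γ chains):

1. **Clonotype calling** (`tcrdiv.clonocall`) — paired 250 bp reads carrying
   a custom adapter (4 bp validation barcode + 6 bp UMI + 4 bp library ID per
   mate) are quality-filtered (every base Phred > 20), demultiplexed, and the
   two mate UMIs concatenated into a fragment-specific 12 bp UMI.  Reads are
   scanned against a library of 20-base tags placed 15 bp from each V/D/J
   segment's predicted recombination-signal-sequence (RSS) cleavage point;
   the CDR3 is the sequence between the V and J cleavage points, pulled in to
   the first point where homology to the germline diverges.  Cassettes are
   kept when productive (frame-preserving junction, no in-frame stop), and
   PCR duplicates are collapsed by degenerate UMI matching (≤ 2 mismatches).
   The result is one clonotype → molecule-count table per sample.
2. **Diversity profiling** (`tcrdiv.diversity`) — each repertoire is
   summarised by its Rényi entropy profile
   H<sub>α</sub> = log(Σᵢ pᵢ^α)/(1−α) over the grid α ∈ [0, 10] in steps of
   0.2 (51 points, natural log): α = 0 is log richness, α → 1 the Shannon
   entropy, large α the Berger–Parker (dominant-clone) regime.  Because
   sequencing depth varies over orders of magnitude, each sample pair is
   compared only after randomly down-sampling the deeper member (without
   replacement) to the shallower depth; the pair distance is the Euclidean
   norm between the two profiles, assembled into a full distance matrix.
3. **Visualisation** (`tcrdiv.embed`) — classical (Torgerson)
   multidimensional scaling of the distance matrix.
4. **Classification** (`tcrdiv.classify`) — the Potential Support Vector
   Machine (P-SVM), a margin classifier that operates directly on relational
   data matrices (distances are not positive semi-definite kernels), with
   leave-one-out cross-validation.  Significance is assessed by label
   permutation: p = (1 + #{permuted score ≥ observed})/(1 + n_perm), with
   balanced accuracy as the score, and Bonferroni correction over the
   18-test primary / 54-test combined hypothesis families (0.05/18 ≈ 0.0028,
   0.05/54 ≈ 9.3×10⁻⁴).
5. **Simulation** (`tcrdiv.simkit`) — synthetic germlines, cohorts and
   UMI-tagged reads with known truth, so every stage above is testable
   end-to-end without any external data.

## Worked example

Simulate a two-group cohort in which group B carries a 0.35 higher fraction
of expanded clones, then run the whole analysis:

```sh
tcrdiv simulate --seed 1 --out-dir sim --n-per-group 4 --effect-delta 0.35 \
    --depth-min 300 --depth-max 1500
tcrdiv diversity sim/S*.rearrangements.tsv --seed 2 --out dist.tsv
tcrdiv mds dist.tsv --metadata sim/metadata.csv --out-prefix mds
tcrdiv classify dist.tsv --metadata sim/metadata.csv \
    --group-a A --group-b B --n-perm 199 --seed 3
```

which prints

```
wrote 8 samples to sim
wrote 8x8 distance matrix to dist.tsv
embedded 8 samples in 2 dimensions
observed balanced accuracy 1.000, p = 0.04 (199 permutations)
```

The classifier separates every held-out sample correctly (balanced accuracy
1.0).  With only 4 samples per group a handful of the 199 label shuffles
reproduce the perfect split by chance (there are only 70 distinct
labellings), so the permutation p-value settles at 0.04; at the study-scale
design of 20 samples per group no shuffle ties the observed score and p
reaches its floor of 1/(199+1) = 0.005, well below a 1 % threshold.  With
`--effect-delta 0` the groups are exchangeable and the p-values are
calibrated by construction.

The same run is available end-to-end as `tcrdiv run-all` or
`tcrdiv.pipeline.run_all(RunConfig(...))`, which also writes profiles, MDS
coordinates/figure and a manifest into one output directory.

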