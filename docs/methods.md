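# Methods

This note documents the models, conventions and numerical choices behind
sinopan, and what the synthetic-data generators do and do not emulate.

## Sequence identity and clustering

Identity between two proteins is defined on a unit-cost (Levenshtein)
Needleman–Wunsch global alignment, computed with edlib:

    identity(a, b) = (identical aligned residue pairs) / (alignment columns).

The alignment-column denominator is deliberate. The common
shorter-sequence denominator degenerates for length-discordant pairs: a
global alignment can match most of a short random protein into a long one
(the matched subsequence approaches the LCS), so unrelated 80 aa × 400 aa
pairs can score 0.3–0.7 "identity" depending on the scoring, and no fixed
separation band between related and unrelated sequences survives. With the
column denominator, unrelated random proteins score ≈ 0.2 across all length
ratios, while indel-free homologs with a substituted fraction k/L score
exactly (L − k)/L. The optimal edit path is not unique; arguments are put
in a canonical order (length, then lexicographic) before aligning so that
identity is symmetric. Co-optimal paths can shift identity by O(1/L); all
separation margins in this package are far wider.

Greedy clustering (threshold θ = 0.70, default) sorts records by decreasing
length (ties: lexicographically smaller id), makes the first unassigned
record a family representative, and assigns each later record to the
representative of highest identity ≥ θ (ties: lowest family index), else
founds a new family. Because every record is compared against candidate
representatives under an exact screen — for any global alignment,
matches m ≤ Ls − (d − ΔL)/2 over at least Ll columns, with d the unit-cost
edit distance, so candidates whose bound cannot reach the running best are
skipped, and edlib's banded mode abandons hopeless distance computations
early — the result is a deterministic function of the record *set*,
invariant to input order. This differs from CD-HIT's first-fit k-mer
heuristic, which is order-sensitive; on data whose within-family identity
sits above θ and between-family identity below it, both coincide with the
connected-components partition (verified against a brute-force oracle in
the tests).

The short-CDS filter removes proteins with fewer than 11 residues
(annotation fragments); exactly 11 is kept.

## Pan-genome set algebra

Presence means member count ≥ 1; paralogy is ignored because families, not
members, are the unit of counting. Species-specific families are species-core
families absent from every strain of every other species (flower-plot
petals) or of one named species (pairwise mode). Strain-unique families are
confined to one strain judged against the **whole dataset**, not just the
strain's own species — the convention that matches reading a strain's
"unique genes" off a genus-wide clustering; the universe is in principle
ambiguous, and the pairwise/species-level quantities are available for the
alternative reading. GC% excludes ambiguity codes from numerator and
denominator; genome size counts all contig residues.

## COG profiling

Gene-level COG letters are input (assignment tools are out of scope).
Multi-letter annotations keep their first letter. Families vote by majority
(ties alphabetical); families with no assigned member are unassigned and
never enter any denominator. Percentages are per partition (core vs
accessory, with an explicit grouping argument for per-species profiles)
over assigned families only, and sum to 100 within each partition.

## F84 distances and the tree pipeline

The F84 model distinguishes transitions from transversions under unequal
base frequencies. With empirical frequencies π̂ (pooled over the whole
alignment, the dnadist default; per-pair estimation is available), πR = π̂A+π̂G,
πY = π̂C+π̂T, A = π̂Cπ̂T/πY + π̂Aπ̂G/πR, B = π̂Cπ̂T + π̂Aπ̂G, C = πRπY, and P, Q
the observed transition/transversion difference proportions:

    d = −2A·ln(1 − P/(2A) − (A−B)·Q/(2AC)) + 2(A−B−C)·ln(1 − Q/(2C)).

This method-of-moments form is ratio-free: no transition/transversion ratio
parameter enters the estimator. At equal frequencies it reduces to the
Kimura two-parameter formula (checked to 1e-12). Sites with a non-ACGT
symbol in either sequence of a pair are skipped (pairwise deletion). A
non-positive log argument (observed divergence at saturation) raises an
error naming the pair.

Neighbor joining uses the Studier–Keppler Q-criterion with a deterministic
tie-break (the lexicographically smallest eligible pair, keyed by the
smallest leaf under each node). Negative branch-length estimates are
clamped to zero with the deficit moved to the sibling edge, the behaviour
of the classic PHYLIP implementation. NJ exactly inverts additive matrices
(oracle-checked to 8 taxa, and cross-checked against scikit-bio's
implementation).

Bootstrap supports resample alignment columns with replacement and rerun
distances + NJ per replicate. Internally a replicate is a column
*reweighting*: per-pair site categories (comparable / transition /
transversion) are classified once, so each replicate's distance matrix is
three matrix-vector products. This is exactly equivalent to materialising
the resampled alignment. Replicates whose distances saturate are skipped
(not retried) and removed from the denominator; the skip count is reported.
Supports are mapped onto the full-data tree by canonical bipartition keys
(the side not containing the lexicographically smallest leaf). Splits with
support strictly below the threshold (default 60%) are collapsed into
polytomies. Rooting at the outgroup is presentational; all computation is
unrooted.

Single-copy family selection requires exactly one member per strain
(count == 1, not ≥ 1). Outgroup anchoring uses bidirectional best hits:
reciprocal unique best-identity hits at ≥ 70% identity with the aligned
span covering ≥ 80% of both sequences; identity strictly below the
threshold is rejected. Concatenation appends per-family alignment columns
in family-id order; alignment construction itself is out of scope
(synthetic families are indel-free, real input must be pre-aligned).

## Phenotype clustering and association

Replicates are averaged per (strain, genotype, trait); missing replicates
are tolerated, a combination with no values is an error. Min-max
normalization maps each (genotype, trait) to [0, 1] across strains; a
degenerate group (all strains equal) is set to 0 with a logged warning —
a constant trait carries no ranking information, and 0 keeps it from
inflating profiles. Normalized values are averaged over genotypes into a
strain × trait profile matrix, clustered agglomeratively with Euclidean
distance and complete linkage (the dist/hclust defaults of R's heatmap.2,
via scipy). The k = 2 cut defines the phenotype clusters; PC I is the
cluster with the higher grand-mean profile (the high-compatibility group).
Uninoculated controls are not strains and must not appear in the table.

Association tables report, per (species, phenotype cluster) group, the
share of strains carrying a gene set — present only if **all** member
families are present — as "percent (count)", percent rounded to the nearest
integer with ties away from zero. Empty groups are blank rather than 0%.

## Synthetic data: what it emulates, what it does not

`generate_pangenome` plants a family partition over a configurable species
layout (default 5 species with a skewed 8/5/3/2/2 strain distribution,
~600 families: 40 genus-core, 20 extra species-core and 40 species-specific
per species, 10–16 strain-unique per strain — accessory-heavy, as real
pan-genomes are). Family ancestors are i.i.d. uniform random proteins of
80–400 aa, rejection-sampled so all pairwise identities stay ≤ 0.30;
members are ancestors with exact-count point substitutions to the target
within-family identity (default 0.90), so planted identities are exact and
the 0.70 threshold separates families with a wide margin. Optional
"symbiosis" families are planted in a designated strain subset to give the
association table a true positive. Fragments (< 11 aa truncations, default
1% rate) exercise the length filter. COG categories are drawn with 2×
weight on C, F, H, M, J, V for planted-core families and on Q, D, K, L for
accessory ones, emulating the canonical core/accessory functional split;
20% of families are unassigned.

Not emulated: indels within families, paralog birth–death, horizontal
transfer mosaics, annotation errors beyond fragmentation, and any sequence
similarity *between* families beyond the rejection bound. Tests passing on
this generator therefore demonstrate correctness of the combinatorics and
estimators under clean separation, not robustness to borderline homology.

`simulate_f84_alignment` evolves i.i.d. sites down a tree with the
calibrated F84 rate matrix (unit expected substitutions per unit branch
length; transition matrices via the symmetric eigendecomposition of the
reversible generator, which matches scipy's matrix exponential to 1e-10
but is closed-form and independent of it). `generate_phenotypes` draws
value = scale(genotype) × (base + effect·σ·1[strain ∈ PC I] + N(0, σ)),
clipped at zero, with per-genotype multiplicative scales (U(0.5, 1.5))
that make the per-genotype normalization consequential; trait baselines
and noise emulate greenhouse symbiosis assays (nodule counts in tens,
masses in mg, SPAD chlorophyll ≈ 40), with three replicates and 27 host
genotypes by default.

## Problem sizes and determinism

Desk-scale defaults keep every stage fast on one CPU: clustering a ~2,300
gene collection takes a few seconds; the tree stage (10–21 leaves,
10,000–20,000 columns, 200 bootstrap replicates by default in the bundled
pipeline, 1,000 available) runs in about a second thanks to the reweighting
formulation. The pipeline fans a single seed into per-stage seeds by fixed
offsets; reruns are byte-identical, and the manifest records seeds,
parameters and input checksums.

## Known limitations

- The greedy stage compares every record against every surviving
  representative (no k-mer prefilter); it is quadratic in family count and
  meant for desk-scale collections, not hundreds of genomes.
- F84 distances are undefined at saturation; the package raises rather
  than imputing, and bootstrap replicates that saturate are dropped from
  the support denominator.
- Complete-linkage ties in the phenotype dendrogram follow scipy's
  deterministic merge order; with heavily tied profiles other orders are
  defensible.
- The association table tests presence, not expression or full-length
  integrity of genes; fragment detection beyond the length filter is out
  of scope.
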