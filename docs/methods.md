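# Methods

This note records the models, defaults and numerical choices behind each
module, what the synthetic-data generator does and does not emulate, and
the known limitations.

## Coordinates, states and formats

All coordinates are 0-based, half-open, forward strand; minus-strand genes
are expected to be reverse-complemented before loading so downstream code
never sees strand. GFF3 output converts to the standard's 1-based
inclusive coordinates. Presence/absence matrices use three first-class
states `P`, `A`, `ND`; `ND` (not determined, e.g. an unresolved PCR assay)
is never silently coerced to `A`. Newick branch lengths are read and
written but ignored by the parsimony code, which is topology-only —
matching the maximum-parsimony framing of the event analysis.

## Spliced alignment (structure)

`infer_introns` aligns a cDNA to its own gene's genomic sequence. Because
the pair comes from the same gene, the model is deliberately restricted:
every cDNA base pairs with exactly one genomic base (substitutions scored
+1/−2, no indels within exons) and the genomic sequence may be skipped in
intron blocks of ≥ `min_intron` bases (open −4, extension free). Leading
and trailing genomic sequence is free. The DP uses two matrices — the
match state and a per-column running maximum that implements "an intron of
at least `min_intron` ended here" in O(1) — for O(n·m) time overall; at
the few-kb scale of single genes the full matrix is cheap, so no banding
is applied. An inference whose best alignment reproduces the cDNA at
< 99% identity is an error, not a result.

Defaults: `min_intron` 20 bp and `min_exon` 15 bp suppress spurious
micro-introns/micro-exons; both sit well below the smallest real intron
classes discussed for this family (< 100 bp) while blocking degenerate
1–10 bp solutions.

**Placement ambiguity.** When an exon flank repeats the intron end — the
very microhomology this package measures — the intron can slide without
changing the alignment score. After traceback the placement is
canonicalised: within the slide range, the leftmost GT..AG-consistent
position wins, then the leftmost position; with `require_gt_ag` set, the
absence of any GT..AG placement is an error. This makes every reported
coordinate, phase and junction string deterministic. Note that the
per-side microhomology values are *not* invariant under sliding (a repeat
of `s` bases presents as `s−d` upstream and `d` downstream after sliding
by `d`); determinism comes from the canonical placement, and the enabling
repeat length itself is the placement-free quantity.

Phases are `(coding bases upstream of the intron) mod 3` from an explicit
start-codon offset (`cds_start`, default 0). For partially sequenced
clones the offset must be supplied; the module refuses to guess.

## Intron homology (homology)

Intron insertion points are mapped through the gap structure of a
user-supplied alignment (genomic mode) or of spliced sequences (cdna
mode); the anchor is the alignment column of the last upstream-exon base.
Slots are single-linkage clusters of projections, linked when columns
differ by ≤ `column_tolerance` and (by default) phases agree; clusters are
numbered 1..S by median column. Defaults are `column_tolerance = 0` with
phase agreement required, i.e. positions are treated as exactly conserved
— appropriate for the within-gene-family alignments this pipeline targets,
where observed intron positions either coincide exactly or are distinct
slots (the two paralog-specific "intron 8" slots, ~500 bp apart with
different phases, must not merge). Tolerance > 0 is available for noisier
alignments but is the user's explicit choice. Two introns of one gene in
one cluster, or a crossing slot order within a gene, abort with an error
rather than a guess.

"Intact" summaries count ND as Present — a gene scored ND at a slot could
not be shown to lack the intron, and the one survey gene affected is
independently believed full-length. Species-level counts offer
`all_copies` (every copy intact; the default used for the 28-of-32-dicots
figure), `any_copy`, and `gene_level`.

## Event reconstruction (events)

Character states per slot are P/A/ND at the leaves (leaves are genes;
within-species duplicates hang as a cherry/polytomy at the species tip so
one shared loss is counted once). The root state is fixed to Present by
default: presence is the inferred ancestral state for this family, and the
assumption is configurable for reuse.

*Dollo (loss-only).* The minimum number of losses is the number of maximal
subtrees holding ≥ 1 Absent and no Present leaf; ND imposes no constraint
(both states free), the standard missing-data treatment, which can only
lower the count (property-tested). Events are placed on the shallowest
branches achieving the minimum; when an ND leaf is basal to an Absent
clade the event placement above vs below the ND split is unidentifiable
and the shallowest-branch convention decides it.

*Sankoff (mixed).* A two-state dynamic program with arbitrary positive
loss/gain costs; ND leaves cost 0 in both states. One optimal labeling is
returned with ties broken toward Present, which pushes events leafward.
`compare_models` contrasts the Dollo count with the unit-cost Sankoff
minimum (root Present). The package reports the unconstrained mixed-model
optimum; a specific published scenario can be reproduced by pinning node
states, since "a" mixed scenario need not be the cheapest one.

Correctness gate: both reconstructions equal exhaustive enumeration over
all ancestral labelings on every rooted binary tree shape with ≤ 6 leaves
× all 3^n leaf-state vectors (shapes, not leaf relabelings, are the
exhaustive axis; labeled trees differ only by permutation). The
equal-cost case is additionally cross-checked against an independent
Fitch implementation, and Sankoff with a prohibitive gain cost reproduces
Dollo exactly (model nesting).

## Microhomology and the penultimate base (boundaries)

`k5` is the longest suffix of the upstream exon equal to the intron
suffix; `k3` the longest intron prefix equal to the downstream exon
prefix; `k = max(k5, k3)`, capped at 8 (the length range of NHEJ deletion
signatures). Both sides are retained because published statements of
"2–4 bases of microhomology" do not fix a side. Comparison is exact,
case-insensitive string equality on verbatim sequences.

The penultimate-base test tabulates the base at exon position −2 (the
codon third position for a phase-1 intron) in genes that retain vs lost
the downstream intron, and computes Fisher's exact test on the 2×k table
(empty columns dropped). scipy covers only 2×2, so the general case is
computed by direct enumeration of tables with fixed margins under the
multivariate hypergeometric null, two-sided by the probability-ordering
rule (as in R's `fisher.test`); the 2×2 case is cross-checked against
`scipy.stats.fisher_exact`. Fisher rather than chi-square because group
sizes in this setting are small. The enumeration is exponential in k in
principle but k ≤ 4 bases and group sizes are tens, so it is exact and
fast where it is used.

## Motif discovery (motifs)

The OOPS model: each sequence contains exactly one site of a W-wide motif
(default W = 12) with position probability matrix θ; all other positions
follow a 0-order background estimated from the input (+1 smoothing). EM
alternates the posterior over site offsets with an expected-count update
under a Dirichlet pseudocount of `0.01 × background` per cell, to
convergence (ΔLLR < 1e−6, cap 200 iterations). Windows overlapping N are
disallowed. Restart strategy: besides `restarts` random W-mer seeds, up to
eight data-driven seeds are taken from the most over-represented exact
8-mers (a recurring motif leaves such words even under noise); every start
runs a short screening EM and the best is converged fully, followed by a
column-shift refinement (±3) that corrects the off-by-one register EM is
prone to. Subsequent motifs are found after masking discovered sites to N.

The reported PPM is computed from the final hard site assignments rather
than the soft posterior (posterior averaging over near-miss offsets
dilutes exactly the column probabilities the >0.8 core definition reads),
and sites scoring below 60% of the median best-site log-odds are left out
of the report: OOPS forces a site into every sequence, including ones
whose motif copy is degraded beyond recognition, and those forced sites
are background. `model.sites` still records one site per sequence.

The significance score is the OOPS log-likelihood ratio against the
background-only model, already penalised by `log(#offsets)` per sequence.
It is a surrogate for ranking and resampling comparisons only and is
explicitly not comparable to MEME e-values, which are not reimplemented.
`empirical_pvalue` reruns discovery with identical parameters on ≥ 20
(typically 100) null sets and reports the fraction of null best-scores ≥
the target's (ties at float precision count as ≥). Scanning
(`scan_mismatches`) is plain minimum Hamming distance over forward-strand
offsets.

## Synthetic data (simulate)

The generator emulates the study's data-generating assumptions: one
ancestral gene of E exons (default 9 introns), exon lengths uniform on
80–220 bp, intron lengths log-normal with median 100 bp (σ = 0.5, floored
at the 20 bp minimum) — matching a family where most lost introns are
short and conserved ones long; evolution on a random rooted binary tree
(uniform over labeled topologies via sequential attachment to a uniform
edge including the stem); per-branch Bernoulli intron loss (default 0.05)
and optional gain (default 0), because the parsimony analysis is
topology-only and event-framed, not rate×length-framed; precise splicing
of lost introns; GT..AG boundaries; uniform point substitutions per branch
(default 0.01/site). Optional plants: exactly-k microhomology at every
junction (guard bases force the (k+1)th base to mismatch, and planted
positions are shielded from substitution so the plant stays exact), and
one noisy motif copy per retaining leaf in a chosen slot, written after
substitution with its own per-position noise. The emitted alignment is
constructed from the known homology — no aligner dependency, columns are
ancestral coordinates, lost introns become gaps.

Not emulated: indels within exons, codon-level selection, rate
heterogeneity, intron sliding, alignment error. Passing end-to-end tests
therefore demonstrates correctness of the machinery under exact homology
and near-identity, not robustness to misalignment — which is why the
pipeline takes alignments as explicit inputs rather than computing them.

## Problem sizes used in tests and the acceptance script

Parsimony oracle sweep: 13 tree shapes (2–6 leaves) × 3^n state vectors
(5301 cases). Parameter recovery: 1000 replicates × 16 leaves × 9 slots at
loss probability 0.05 (the per-slot equality rate is ~97%; the shortfall
from 100% is the expected merging of sibling-branch double losses into one
clade, which parsimony cannot distinguish). Motif recovery: 100 replicates
of 50 × 1000 bp with a 12-wide plant at 10% noise (script: 50 replicates);
resampling null: 100 dinucleotide-shuffled sets. End-to-end matrix
recovery: 8-leaf, 9-intron genomes, 20 replicates. These sizes are chosen
to give stable rates at interactive runtimes.

## Known limitations

- The spliced aligner assumes collinear, near-identical pairs; it is not a
  general spliced aligner (no splice-site scoring models, no isoforms).
- Dollo/Sankoff report one optimal event placement; co-optimal placements
  exist and only the shallowest/Present-preferring representative is
  shown.
- The motif surrogate score is dataset-internal; scores are comparable
  only across runs with identical parameters, as in the resampling null.
- The packaged phylogeny fixture resolves a handful of within-family
  relationships that published phylogenies leave uncertain; event counts
  on it should be read as counts on that topology.
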