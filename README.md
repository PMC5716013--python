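# intronevo

Tools for studying the evolutionary loss (and gain) of spliceosomal introns
in a gene family across a phylogeny. The package grew out of the analysis
of the plant *ABCB1* auxin-transporter gene, whose exon/intron structure is
unusually dynamic across angiosperms — from the ancestral nine introns down
to a single intron in some grasses — while its paralog *ABCB19* barely
changed. It ships that survey as a worked, reproducible example and
provides the general machinery:

- **structure** — infer exon/intron structure from a genomic + cDNA pair by
  splice-aware dynamic programming (GT..AG-canonical placement, intron
  phases, boundary dinucleotides).
- **homology** — project intron positions of many orthologs through a
  shared alignment, cluster them into ancestral intron slots, and build a
  genes × slots Present/Absent/Not-Determined matrix.
- **events** — minimum-event reconstruction of each slot's history on a
  rooted tree: Dollo (loss-only, root state Present) and Sankoff (weighted
  loss + gain) parsimony, with branch-level event placement and a
  loss-only vs mixed model comparison.
- **boundaries** — splice-junction microhomology (the NHEJ deletion
  signature) and an exact contingency test for relaxed selection on the
  penultimate exon base after phase-1 intron loss.
- **motifs** — fixed-width motif discovery in intron sets with a
  one-occurrence-per-sequence EM model, >80%-probability core consensus
  extraction, mismatch scanning, and an empirical resampling null.
- **simulate** — a generator of synthetic trees, loss/gain histories, gene
  sequences, alignments, microhomology and motif plants, with full ground
  truth, so every stage is testable without downloads.

## The models in brief

For one intron slot with leaf states in {P, A, ND}, the Dollo count is the
least number of loss events explaining the leaves given presence at the
root: the number of maximal subtrees containing an Absent leaf and no
Present leaf (ND is free). The mixed model is the Sankoff minimum of
`n_loss·c_loss + n_gain·c_gain` over all ancestral labelings. Microhomology
at a junction is the longest exact repeat shared between an exon flank and
the matching intron end (`k5` upstream/intron suffix, `k3` intron/downstream
prefix, reported with `k = max`). The motif model is an OOPS PPM
`θ (W × 4)` against a 0-order background, fit by EM and scored by the
log-likelihood ratio penalised by `log(#offsets)` per sequence; its "core"
is the longest run of positions whose top base exceeds 0.8.

## Worked example

The packaged fixtures transcribe the published *ABCB1* intron survey
(100 genes from 80 angiosperm species, 9 ancestral intron slots) and the
species/gene phylogeny it was read against:

```
intronevo events \
    --matrix src/intronevo/data/abcb1_intron_matrix.tsv \
    --tree   src/intronevo/data/angiosperm_tree.nwk \
    --out    events_out
```

prints

```
slot 1: dollo=1 mixed=1 (tie)
slot 2: dollo=8 mixed=7 (mixed_preferred)
slot 3: dollo=1 mixed=1 (tie)
slot 4: dollo=3 mixed=3 (tie)
slot 5: dollo=5 mixed=4 (mixed_preferred)
slot 6: dollo=3 mixed=3 (tie)
slot 7: dollo=1 mixed=1 (tie)
slot 8: dollo=3 mixed=3 (tie)
slot 9: dollo=5 mixed=5 (tie)
```

Reading: intron 1 was lost once, on the stem of the grasses plus
*Ecdeiocolea* (the branch report in `events_out/events.tsv` lists the
subtended clade); intron 2 was lost eight independent times under the
loss-only model, and an unconstrained mixed history could explain the same
pattern with seven events (6 losses + 1 gain); intron 7 was lost only once
(a duplicated *Mimulus* copy). `events_out/annotated_tree.nwk` carries the
events as branch tags. A matrix summary
(`intronevo.summarize_matrix`) reports that 28 of the 32 dicot species
carry all nine introns in every copy and that per-gene intron counts range
from 1 to 9.

The full synthetic pipeline — simulate, re-infer structures, rebuild the
matrix, reconstruct events, survey microhomology, discover the planted
motif — runs with `intronevo all --seed 1 --leaves 8 --out pipeline_out`.

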