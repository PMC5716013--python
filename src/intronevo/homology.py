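"""Cross-species intron homology: projection onto a shared alignment,
clustering into ancestral slots, and presence/absence matrix construction.

Intron positions are treated as exactly conserved by default
(column tolerance 0, phases must agree); a tolerance > 0 is available for
noisy user-supplied alignments.  Two nearby projections with different
phases never merge, which keeps positionally close but non-homologous
introns (such as the two distinct "intron 8" slots of the ABCB1/ABCB19
paralog pair) in separate slots.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass

import pandas as pd

from .errors import AmbiguityError, ValidationError
from .io_formats import (
    ABSENT,
    NOT_DETERMINED,
    PRESENT,
    AlignedBlock,
    PresenceMatrix,
)
from .structure import GeneStructure

GENOMIC_MODE = "genomic"
CDNA_MODE = "cdna"


@dataclass(frozen=True)
class IntronProjection:
    """One intron's insertion point mapped to an alignment column.

    ``column`` is the alignment column of the last upstream-exon base.
    """

    gene_id: str
    intron_index: int
    column: int
    phase: int | None


@dataclass
class HomologyMap:
    """Ancestral intron slots (1..S) and each gene's intron -> slot mapping."""

    n_slots: int
    assignments: dict[tuple[str, int], int]  # (gene, intron index) -> slot
    slot_columns: dict[int, float]  # slot -> median alignment column

    def slots_of(self, gene_id: str) -> dict[int, int]:
        return {
            idx: slot
            for (g, idx), slot in self.assignments.items()
            if g == gene_id
        }


def _ungapped_to_column(residues: str) -> list[int]:
    """Map each ungapped position to its alignment column (0-based)."""
    cols = []
    for col, ch in enumerate(residues):
        if ch != "-":
            cols.append(col)
    return cols


def project_introns(
    alignment: AlignedBlock,
    structures: list[GeneStructure],
    mode: str = GENOMIC_MODE,
) -> list[IntronProjection]:
    """Map each intron's insertion point through the gap structure.

    In ``genomic`` mode each structure's genomic sequence must equal its
    aligned record ungapped, and the insertion point is the genomic
    coordinate of the last upstream-exon base.  In ``cdna`` mode the
    alignment is of spliced (exon-only) sequences and the insertion point
    is the cDNA coordinate of the exon junction.
    """
    if mode not in (GENOMIC_MODE, CDNA_MODE):
        raise ValidationError(f"unknown projection mode {mode!r}")
    projections: list[IntronProjection] = []
    for st in structures:
        try:
            rec = alignment.record(st.gene_id)
        except KeyError:
            raise ValidationError(
                f"gene {st.gene_id!r} missing from the alignment"
            ) from None
        ungapped = rec.ungapped
        reference = st.genomic if mode == GENOMIC_MODE else st.cdna
        if ungapped != reference:
            raise ValidationError(
                f"gene {st.gene_id!r}: aligned sequence does not match its "
                f"{mode} sequence (lengths {len(ungapped)} vs {len(reference)})"
            )
        pos_to_col = _ungapped_to_column(rec.residues)
        for intron in st.introns:
            if mode == GENOMIC_MODE:
                anchor = intron.start - 1
            else:
                anchor = (
                    sum(e - s for s, e in st.exons[: intron.index]) - 1
                )
            projections.append(
                IntronProjection(
                    gene_id=st.gene_id,
                    intron_index=intron.index,
                    column=pos_to_col[anchor],
                    phase=intron.phase,
                )
            )
    return projections


def cluster_slots(
    projections: list[IntronProjection],
    column_tolerance: int = 0,
    require_same_phase: bool = True,
) -> HomologyMap:
    """Single-linkage clustering of projections into ancestral slots.

    Two projections link when |column difference| <= tolerance and (if
    required) their phases are equal; clusters are numbered 1..S by median
    column.  A cluster holding two introns of one gene, or a gene whose
    slot mapping is not strictly increasing, raises AmbiguityError.
    """
    if not projections:
        return HomologyMap(n_slots=0, assignments={}, slot_columns={})
    items = sorted(projections, key=lambda p: (p.column, p.gene_id, p.intron_index))
    parent = list(range(len(items)))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    for i, p in enumerate(items):
        for j in range(i + 1, len(items)):
            q = items[j]
            if q.column - p.column > column_tolerance:
                break  # sorted by column
            if require_same_phase and p.phase != q.phase:
                continue
            union(i, j)

    clusters: dict[int, list[IntronProjection]] = {}
    for i, p in enumerate(items):
        clusters.setdefault(find(i), []).append(p)

    ordered = sorted(
        clusters.values(), key=lambda c: statistics.median(p.column for p in c)
    )
    assignments: dict[tuple[str, int], int] = {}
    slot_columns: dict[int, float] = {}
    for slot, members in enumerate(ordered, start=1):
        genes_seen: dict[str, int] = {}
        for p in members:
            if p.gene_id in genes_seen:
                raise AmbiguityError(
                    f"slot {slot}: introns {genes_seen[p.gene_id]} and "
                    f"{p.intron_index} of gene {p.gene_id!r} fall in one "
                    f"cluster (columns within tolerance {column_tolerance})"
                )
            genes_seen[p.gene_id] = p.intron_index
            assignments[(p.gene_id, p.intron_index)] = slot
        slot_columns[slot] = statistics.median(p.column for p in members)

    # crossing check: within each gene the slot order must follow intron order
    by_gene: dict[str, list[tuple[int, int]]] = {}
    for (gene, idx), slot in assignments.items():
        by_gene.setdefault(gene, []).append((idx, slot))
    for gene, pairs in by_gene.items():
        pairs.sort()
        slots = [s for _, s in pairs]
        if slots != sorted(slots):
            raise AmbiguityError(
                f"gene {gene!r}: slot mapping {pairs} crosses (not increasing)"
            )
    return HomologyMap(
        n_slots=len(ordered), assignments=assignments, slot_columns=slot_columns
    )


def build_matrix(
    homology: HomologyMap,
    genes: list[tuple[str, str, str]],
    nd_annotations: dict[tuple[str, int], bool] | None = None,
) -> PresenceMatrix:
    """Presence matrix from a homology map.

    ``genes`` is a list of (gene_id, species, clade) rows; a slot is Present
    where the gene maps an intron to it and Absent otherwise.  ND states are
    overlaid only from explicit ``nd_annotations`` (e.g. PCR-undetermined),
    never produced by clustering.
    """
    slot_names = [str(s) for s in range(1, homology.n_slots + 1)]
    rows = {}
    for gene_id, _, _ in genes:
        mapped = set(homology.slots_of(gene_id).values())
        rows[gene_id] = [PRESENT if s in mapped else ABSENT for s in range(1, homology.n_slots + 1)]
    states = pd.DataFrame.from_dict(rows, orient="index", columns=slot_names, dtype=object)
    if nd_annotations:
        for (gene_id, slot), flagged in nd_annotations.items():
            if flagged:
                states.at[gene_id, str(slot)] = NOT_DETERMINED
    states.index.name = "gene"
    species = pd.Series({g: sp for g, sp, _ in genes}, dtype=object, name="species")
    clade = pd.Series({g: cl for g, _, cl in genes}, dtype=object, name="clade")
    if len(genes) == 0:
        species = pd.Series(dtype=object, name="species")
        clade = pd.Series(dtype=object, name="clade")
    return PresenceMatrix(
        states=states,
        species=species.reindex(states.index),
        clade=clade.reindex(states.index),
    )


# ---------------------------------------------------------------------------
# Matrix summaries
# ---------------------------------------------------------------------------

GENE_LEVEL = "gene_level"
ALL_COPIES = "all_copies"
ANY_COPY = "any_copy"


@dataclass
class MatrixSummary:
    per_gene_counts: dict[str, int]
    min_introns: int
    max_introns: int
    intact_by_clade: dict[str, int]  # clade -> number of units with all slots intact
    units_by_clade: dict[str, int]  # clade -> number of units (genes or species)
    rule: str


def summarize_matrix(
    matrix: PresenceMatrix, collapse: str = ALL_COPIES
) -> MatrixSummary:
    """Per-gene intron counts plus per-clade counts of intact genes/species.

    "Intact" means every slot Present, with ND counted as Present (a gene
    whose undetermined introns could not be scored is given the benefit of
    the doubt, as for the misannotated but likely full-length papaya gene).
    ``collapse``: gene_level counts genes; all_copies counts a species only
    when every copy is intact; any_copy when at least one is.
    """
    if collapse not in (GENE_LEVEL, ALL_COPIES, ANY_COPY):
        raise ValidationError(f"unknown species rule {collapse!r}")
    if matrix.states.empty:
        raise ValidationError("matrix is empty")
    counts = (matrix.states == PRESENT).sum(axis=1)
    per_gene = {g: int(c) for g, c in counts.items()}
    intact_gene = ((matrix.states == PRESENT) | (matrix.states == NOT_DETERMINED)).all(axis=1)

    intact_by_clade: dict[str, int] = {}
    units_by_clade: dict[str, int] = {}
    if collapse == GENE_LEVEL:
        for gene in matrix.genes:
            clade = matrix.clade[gene]
            units_by_clade[clade] = units_by_clade.get(clade, 0) + 1
            if intact_gene[gene]:
                intact_by_clade[clade] = intact_by_clade.get(clade, 0) + 1
    else:
        df = pd.DataFrame(
            {"species": matrix.species, "clade": matrix.clade, "intact": intact_gene}
        )
        agg = df.groupby(["clade", "species"])["intact"].agg(
            "all" if collapse == ALL_COPIES else "any"
        )
        for (clade, _), ok in agg.items():
            units_by_clade[clade] = units_by_clade.get(clade, 0) + 1
            if ok:
                intact_by_clade[clade] = intact_by_clade.get(clade, 0) + 1
    for clade in units_by_clade:
        intact_by_clade.setdefault(clade, 0)
    return MatrixSummary(
        per_gene_counts=per_gene,
        min_introns=int(counts.min()),
        max_introns=int(counts.max()),
        intact_by_clade=intact_by_clade,
        units_by_clade=units_by_clade,
        rule=collapse,
    )
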