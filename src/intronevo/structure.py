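"""Exon/intron structure inference from genomic + cDNA sequence pairs.

The aligner is a two-state dynamic program specialised for same-gene pairs
at near identity: cDNA positions align one-to-one to genomic positions
(substitutions allowed, no indels inside exons) and the genomic sequence may
additionally be skipped in intron blocks of at least ``min_intron`` bases.
Scores: exon match +1, mismatch -2, intron open -4, intron extension 0.
Leading and trailing genomic sequence is free (UTR margins).

Equally scoring intron placements arise whenever the two exon flanks share
sequence with the intron ends - exactly the splice-junction microhomology
this package quantifies - so placement is canonicalised after traceback:
within an intron's slide range the leftmost GT..AG-consistent position wins,
falling back to the leftmost position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InferenceError, ValidationError

MATCH = 1
MISMATCH = -2
INTRON_OPEN = -4

DEFAULT_MIN_INTRON = 20
DEFAULT_MIN_EXON = 15


@dataclass
class IntronRecord:
    """One intron: genomic interval, phase and boundary dinucleotides."""

    index: int  # 1-based ordinal within the gene
    start: int  # 0-based, half-open on genomic
    end: int
    phase: int | None
    donor: str
    acceptor: str

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneStructure:
    """A gene's genomic sequence with its ordered exons and derived introns."""

    gene_id: str
    genomic: str
    exons: list[tuple[int, int]]
    species: str = ""
    cds_start: int | None = 0  # offset of the start codon within the cDNA
    introns: list[IntronRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if not (s1 < e1 <= s2 < e2):
                raise ValidationError(
                    f"{self.gene_id}: exons must be non-overlapping and increasing"
                )
        if not self.introns:
            self.introns = self._derive_introns()

    def _derive_introns(self) -> list[IntronRecord]:
        introns = []
        for i, ((_, e1), (s2, _)) in enumerate(zip(self.exons, self.exons[1:]), start=1):
            seq = self.genomic[e1:s2]
            introns.append(
                IntronRecord(
                    index=i,
                    start=e1,
                    end=s2,
                    phase=self._phase_of(i),
                    donor=seq[:2],
                    acceptor=seq[-2:],
                )
            )
        return introns

    def _phase_of(self, intron_index: int) -> int | None:
        if self.cds_start is None:
            return None
        coding = sum(e - s for s, e in self.exons[:intron_index]) - self.cds_start
        return coding % 3

    @property
    def cdna(self) -> str:
        return "".join(self.genomic[s:e] for s, e in self.exons)

    def intron(self, index: int) -> IntronRecord:
        try:
            return self.introns[index - 1]
        except IndexError:
            raise ValidationError(
                f"{self.gene_id}: no intron {index} (gene has {len(self.introns)})"
            ) from None

    def intron_sequence(self, index: int) -> str:
        rec = self.intron(index)
        return self.genomic[rec.start:rec.end]


def compute_phase(structure: GeneStructure, intron_index: int) -> int:
    """Phase = coding bases upstream of the intron, modulo 3.

    Requires the cDNA offset of the start codon (``cds_start``) to be set;
    partially sequenced clones must state it explicitly.
    """
    structure.intron(intron_index)  # validates the index
    if structure.cds_start is None:
        raise ValidationError(
            f"{structure.gene_id}: cds_start unset - set the start-codon offset "
            "before computing phases"
        )
    return structure._phase_of(intron_index)


def boundary_context(
    structure: GeneStructure, intron_index: int, k: int
) -> tuple[str, str, str, bool]:
    """(upstream exon suffix of <=k, intron, downstream exon prefix of <=k).

    Returns verbatim substrings plus a flag set when a flank was truncated
    because the neighbouring exon is shorter than k.
    """
    if k < 1:
        raise ValidationError("k must be >= 1")
    i = intron_index
    rec = structure.intron(i)
    up_s, up_e = structure.exons[i - 1]
    dn_s, dn_e = structure.exons[i]
    upstream = structure.genomic[max(up_s, up_e - k):up_e]
    downstream = structure.genomic[dn_s:min(dn_e, dn_s + k)]
    truncated = len(upstream) < k or len(downstream) < k
    return upstream, structure.genomic[rec.start:rec.end], downstream, truncated


# ---------------------------------------------------------------------------
# Spliced alignment
# ---------------------------------------------------------------------------

def _slide_range(genomic: str, start: int, end: int, lo: int, hi: int) -> tuple[int, int]:
    """How far the intron [start, end) can shift with an identical alignment.

    Shifting right by one is score-neutral iff genomic[start] == genomic[end]
    (the base entering the upstream exon equals the one leaving the
    downstream exon); symmetric on the left.  ``lo``/``hi`` bound the shift
    by the neighbouring exons.
    """
    left = 0
    while start - left - 1 >= lo and genomic[start - left - 1] == genomic[end - left - 1]:
        left += 1
    right = 0
    while end + right < hi and genomic[start + right] == genomic[end + right]:
        right += 1
    return -left, right


def _canonical_shift(genomic: str, start: int, end: int, shifts: range) -> int | None:
    for d in shifts:  # leftmost first
        if genomic[start + d:start + d + 2] == "GT" and genomic[end + d - 2:end + d] == "AG":
            return d
    return None


def infer_introns(
    genomic: str,
    cdna: str,
    gene_id: str = "gene",
    species: str = "",
    min_exon: int = DEFAULT_MIN_EXON,
    min_intron: int = DEFAULT_MIN_INTRON,
    require_gt_ag: bool = False,
    cds_start: int | None = 0,
    min_identity: float = 0.99,
) -> GeneStructure:
    """Infer exon intervals by maximum-scoring spliced alignment.

    Raises InferenceError when no spliced alignment reproduces the cDNA at
    >= ``min_identity`` identity, or (with ``require_gt_ag``) when an intron
    admits no GT..AG placement within its slide range.
    """
    genomic = genomic.upper().replace("U", "T")
    cdna = cdna.upper().replace("U", "T")
    if not genomic or not cdna:
        raise ValidationError("genomic and cdna must be non-empty")
    if len(cdna) > len(genomic):
        raise ValidationError("cdna longer than genomic sequence")

    n, m = len(genomic), len(cdna)
    NEG = np.int32(-(10 ** 8))
    g = np.frombuffer(genomic.encode(), dtype=np.uint8)
    c = np.frombuffer(cdna.encode(), dtype=np.uint8)

    # M[i, j]: best score with genomic[i-1] aligned to cdna[j-1].
    # L[i, j] = max_{a <= i} M[a, j]  (intron-predecessor running maximum).
    M = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    L = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    M[:, 0] = 0  # free leading genomic before the first exon
    L[0] = M[0]
    sub = np.where(g[:, None] == c[None, :], MATCH, MISMATCH).astype(np.int32)
    for i in range(1, n + 1):
        prev_diag = M[i - 1, :-1]
        open_row = i - 1 - min_intron
        if open_row >= 0:
            intron_pred = L[open_row, :-1] + INTRON_OPEN
            best_pred = np.maximum(prev_diag, intron_pred)
        else:
            best_pred = prev_diag
        M[i, 1:] = best_pred + sub[i - 1]
        np.maximum(L[i - 1], M[i], out=L[i])

    final = M[:, m]
    best_i = int(np.argmax(final))  # leftmost on ties
    score = int(final[best_i])
    if score <= int(NEG) // 2:
        raise InferenceError(
            f"{gene_id}: cDNA not derivable from genomic under settings "
            f"(min_intron={min_intron})"
        )

    # Traceback: prefer exon continuation while walking leftward, which
    # defers intron openings and yields the leftmost raw placement.
    introns_raw: list[tuple[int, int]] = []
    i, j = best_i, m
    while j > 1:
        if M[i, j] == M[i - 1, j - 1] + sub[i - 1, j - 1]:
            i, j = i - 1, j - 1
            continue
        # an intron [a, i-1) closed here; find the earliest best opener
        target = M[i, j] - sub[i - 1, j - 1] - INTRON_OPEN
        col = M[: i - min_intron, j - 1]
        a = int(np.argmax(col == target))
        introns_raw.append((a, i - 1))
        i, j = a, j - 1
    i -= 1  # genomic index of the first exon base

    first_start = i
    introns_raw.reverse()

    # Build exon intervals from intron gaps.
    exons: list[tuple[int, int]] = []
    pos = first_start
    for a, b in introns_raw:
        exons.append((pos, a))
        pos = b
    exons.append((pos, best_i))

    # Canonicalise slidable placements: leftmost GT..AG, else leftmost.
    for k, (a, b) in enumerate(introns_raw):
        lo = exons[k][0]
        hi = exons[k + 1][1]
        left, right = _slide_range(genomic, a, b, lo, hi)
        shifts = range(left, right + 1)
        d = _canonical_shift(genomic, a, b, shifts)
        if d is None:
            if require_gt_ag:
                raise InferenceError(
                    f"{gene_id}: intron {k + 1} admits no GT..AG placement "
                    f"in slide range {left}..{right} at [{a},{b})"
                )
            d = left
        a, b = a + d, b + d
        introns_raw[k] = (a, b)
        exons[k] = (exons[k][0], a)
        exons[k + 1] = (b, exons[k + 1][1])

    structure = GeneStructure(
        gene_id=gene_id,
        species=species,
        genomic=genomic,
        exons=exons,
        cds_start=cds_start,
    )

    spliced = structure.cdna
    if len(spliced) != m:
        raise InferenceError(f"{gene_id}: internal error - spliced length mismatch")
    identity = sum(x == y for x, y in zip(spliced, cdna)) / m
    if identity < min_identity:
        raise InferenceError(
            f"{gene_id}: best spliced alignment reaches only {identity:.2%} "
            f"identity (< {min_identity:.0%}); score={score}, "
            f"{len(introns_raw)} introns"
        )
    if any(e - s < min_exon for s, e in exons):
        raise InferenceError(
            f"{gene_id}: inferred exon shorter than min_exon={min_exon}: {exons}"
        )
    return structure


# ---------------------------------------------------------------------------
# Tabular / GFF3 output
# ---------------------------------------------------------------------------

def intron_table(structures: list[GeneStructure]):
    """Per-intron TSV-ready table: gene, index, start, end, length, phase,
    donor, acceptor."""
    import pandas as pd

    rows = []
    for st in structures:
        for rec in st.introns:
            rows.append(
                {
                    "gene": st.gene_id,
                    "index": rec.index,
                    "start": rec.start,
                    "end": rec.end,
                    "length": rec.length,
                    "phase": rec.phase,
                    "donor": rec.donor,
                    "acceptor": rec.acceptor,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["gene", "index", "start", "end", "length", "phase", "donor", "acceptor"],
    )


def write_gff3(structures: list[GeneStructure], path: str | Path) -> None:
    """Exon features only, 1-based inclusive coordinates per the standard."""
    lines = ["##gff-version 3"]
    for st in structures:
        for i, (s, e) in enumerate(st.exons, start=1):
            lines.append(
                "\t".join(
                    [
                        st.gene_id,
                        "intronevo",
                        "exon",
                        str(s + 1),
                        str(e),
                        ".",
                        "+",
                        ".",
                        f"ID=exon:{st.gene_id}.{i};Parent={st.gene_id}",
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n")
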