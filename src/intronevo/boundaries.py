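"""Splice-junction microhomology and the phase-I penultimate-base test.

Precise intron removal by non-homologous end joining (NHEJ) of a double
strand break is favoured when the sequence flanking the break repeats: a
short identical stretch shared between an exon flank and the matching
intron end lets repair delete exactly the intron.  ``microhomology``
measures that stretch on both junctions: k5 compares the upstream exon
suffix with the intron suffix (a repeat that removes the intron leaving the
exon copy), k3 the intron prefix with the downstream exon prefix.

After a phase-I intron is lost, the last-but-one base of the upstream exon
is a codon third position no longer needed by the splicing machinery and is
free to mutate synonymously; ``penultimate_test`` checks whether its base
composition differs between genes that kept and genes that lost the
downstream intron.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .errors import ValidationError
from .homology import HomologyMap
from .io_formats import PRESENT
from .structure import GeneStructure, boundary_context

DEFAULT_CAP = 8  # NHEJ signatures carry 2-8 bp of microhomology


@dataclass
class MicrohomologyResult:
    gene_id: str
    intron_index: int
    k5: int  # upstream-exon suffix == intron suffix
    k3: int  # intron prefix == downstream-exon prefix
    cap: int
    warning: str | None = None

    @property
    def k(self) -> int:
        return max(self.k5, self.k3)


def _common_suffix(a: str, b: str, cap: int) -> int:
    k = 0
    while k < cap and k < len(a) and k < len(b) and a[-1 - k] == b[-1 - k]:
        k += 1
    return k


def _common_prefix(a: str, b: str, cap: int) -> int:
    k = 0
    while k < cap and k < len(a) and k < len(b) and a[k] == b[k]:
        k += 1
    return k


def microhomology(
    upstream_exon: str,
    intron: str,
    downstream_exon: str,
    cap: int = DEFAULT_CAP,
    gene_id: str = "",
    intron_index: int = 0,
) -> MicrohomologyResult:
    """Longest flank/intron repeats at both junctions (case-insensitive)."""
    if len(intron) < 2:
        raise ValidationError("intron must be at least 2 bp")
    up, iv, dn = upstream_exon.upper(), intron.upper(), downstream_exon.upper()
    warning = None
    if not up or not dn:
        warning = "empty flank"
    k5 = _common_suffix(up, iv, cap) if up else 0
    k3 = _common_prefix(iv, dn, cap) if dn else 0
    return MicrohomologyResult(
        gene_id=gene_id, intron_index=intron_index, k5=k5, k3=k3, cap=cap,
        warning=warning,
    )


def microhomology_survey(
    structures: list[GeneStructure],
    homology: HomologyMap,
    cap: int = DEFAULT_CAP,
    flank: int = DEFAULT_CAP,
) -> pd.DataFrame:
    """Distribution of microhomology length k per ancestral slot.

    Returns a tidy frame (slot, gene, intron_index, k5, k3, k) plus a
    ``modal_k_lt2`` flag per slot marking slots whose modal k is below the
    2 bp NHEJ signature.
    """
    rows = []
    for st in structures:
        slot_map = homology.slots_of(st.gene_id)
        for intron in st.introns:
            slot = slot_map.get(intron.index)
            if slot is None:
                continue
            up, iv, dn, _ = boundary_context(st, intron.index, max(cap, flank))
            res = microhomology(up, iv, dn, cap=cap, gene_id=st.gene_id,
                                intron_index=intron.index)
            rows.append(
                {"slot": slot, "gene": st.gene_id, "intron_index": intron.index,
                 "k5": res.k5, "k3": res.k3, "k": res.k}
            )
    df = pd.DataFrame(rows, columns=["slot", "gene", "intron_index", "k5", "k3", "k"])
    if df.empty:
        df.attrs["flagged_slots"] = []
        return df
    modal = df.groupby("slot")["k"].agg(lambda s: s.mode().iloc[0])
    df.attrs["modal_k"] = modal.to_dict()
    df.attrs["flagged_slots"] = sorted(modal.index[modal < 2])
    return df


# ---------------------------------------------------------------------------
# Penultimate-base contingency test
# ---------------------------------------------------------------------------

@dataclass
class PenultimateTable:
    slot: str
    table: pd.DataFrame  # rows: with/without downstream intron; cols: bases
    p_value: float
    warning: str | None = None


def _exact_2xk_pvalue(table: np.ndarray) -> float:
    """Fisher's exact test on a 2 x k table, two-sided.

    Conditional on both margins, the null is multivariate hypergeometric;
    the two-sided p sums the probabilities of all tables no more probable
    than the observed one (the probability-ordering rule, as in R's
    fisher.test).  Enumeration over the first row is exact and fast at the
    sample sizes seen here.
    """
    table = np.asarray(table, dtype=np.int64)
    col = table.sum(axis=0)
    n1 = int(table[0].sum())
    n = int(table.sum())

    def log_multinom(row: tuple[int, ...]) -> float:
        # log P(row | margins) up to the constant log C(n, n1)
        return float(
            sum(gammaln(c + 1) - gammaln(a + 1) - gammaln(c - a + 1)
                for a, c in zip(row, col))
        )

    log_const = float(gammaln(n + 1) - gammaln(n1 + 1) - gammaln(n - n1 + 1))
    obs = log_multinom(tuple(int(x) for x in table[0])) - log_const

    ranges = [range(0, int(c) + 1) for c in col[:-1]]
    p = 0.0
    for partial in itertools.product(*ranges):
        rest = n1 - sum(partial)
        if rest < 0 or rest > col[-1]:
            continue
        row = partial + (rest,)
        lp = log_multinom(row) - log_const
        if lp <= obs + 1e-9:
            p += math.exp(lp)
    return min(1.0, p)


def penultimate_test(
    structures_with: list[GeneStructure],
    structures_without: list[GeneStructure],
    slot: str | int,
    upstream_exon_index: int,
    expected_phase: int = 1,
) -> PenultimateTable:
    """Base at position -2 of the upstream exon, with vs without the intron.

    ``upstream_exon_index`` is the 0-based index of the exon immediately 5'
    of the slot in each structure's own exon list (callers align this via
    the homology map).  The test is meaningful for phase-1 introns (the
    -2 base is then a codon third position); other phases get a warning but
    the test is still computed.
    """
    if not structures_with or not structures_without:
        raise ValidationError("both groups must be non-empty")

    def base_at(st: GeneStructure) -> str:
        s, e = st.exons[upstream_exon_index]
        if e - s < 2:
            raise ValidationError(f"{st.gene_id}: upstream exon shorter than 2 bp")
        return st.genomic[e - 2]

    with_bases = [base_at(st) for st in structures_with]
    without_bases = [base_at(st) for st in structures_without]
    bases = sorted(set(with_bases) | set(without_bases))
    table = pd.DataFrame(
        [[with_bases.count(b) for b in bases], [without_bases.count(b) for b in bases]],
        index=["intron_present", "intron_absent"],
        columns=bases,
    )
    table = table.loc[:, table.sum(axis=0) > 0]  # drop empty columns
    warning = None
    if expected_phase != 1:
        warning = "slot is not phase 1; the codon-position rationale does not apply"
    if table.shape[1] < 2:
        return PenultimateTable(slot=str(slot), table=table, p_value=1.0, warning=warning)
    p = _exact_2xk_pvalue(table.to_numpy())
    return PenultimateTable(slot=str(slot), table=table, p_value=p, warning=warning)


def size_stats(
    structures: list[GeneStructure], homology: HomologyMap
) -> pd.DataFrame:
    """Mean and median intron length (bp) per ancestral slot."""
    rows = []
    for st in structures:
        slot_map = homology.slots_of(st.gene_id)
        for intron in st.introns:
            slot = slot_map.get(intron.index)
            if slot is not None:
                rows.append({"slot": slot, "length": intron.length})
    if not rows:
        return pd.DataFrame(columns=["slot", "n", "mean_bp", "median_bp"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby("slot")["length"]
        .agg(n="count", mean_bp="mean", median_bp="median")
        .reset_index()
    )
    return out
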