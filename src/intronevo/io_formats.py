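"""Readers and writers for the external representations used by the pipeline.

Formats covered: plain and aligned FASTA ('-' as gap character), newick trees,
and delimited intron presence/absence matrices.  Coordinates everywhere in the
package are 0-based half-open on the forward strand.

FASTA parsing is delegated to Biopython, newick parsing to dendropy; both are
converted into the small domain types defined here so that downstream modules
never touch a third-party object directly.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

from .errors import FormatError, ValidationError

# Presence/absence/not-determined state tokens used throughout.
PRESENT = "P"
ABSENT = "A"
NOT_DETERMINED = "ND"
STATES = (PRESENT, ABSENT, NOT_DETERMINED)


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

@dataclass
class SequenceRecord:
    """A named DNA sequence.

    Residues are uppercase over {A,C,G,T,N}; 'U' is mapped to 'T' at load
    time.  Aligned records may additionally contain '-'.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("sequence record has an empty id")
        if len(self.residues) == 0:
            raise ValidationError(f"sequence {self.id!r} is empty")

    @property
    def ungapped(self) -> str:
        return self.residues.replace("-", "")

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class AlignedBlock:
    """A multiple sequence alignment as an ordered list of gapped records."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.records}
        if len(lengths) > 1:
            raise ValidationError(
                f"aligned records have unequal lengths: {sorted(lengths)}"
            )

    @property
    def length(self) -> int:
        return len(self.records[0]) if self.records else 0

    def record(self, rec_id: str) -> SequenceRecord:
        for r in self.records:
            if r.id == rec_id:
                return r
        raise KeyError(rec_id)


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


def read_fasta(path: str | Path, aligned: bool = False) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords (uppercased, U mapped to T).

    With ``aligned=True`` the gap character '-' is retained, otherwise a gap
    raises a validation error.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValidationError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        residues = _normalize(str(rec.seq))
        if not aligned and "-" in residues:
            raise ValidationError(
                f"record {rec.id!r} contains gaps; use read_alignment for aligned FASTA"
            )
        records.append(
            SequenceRecord(id=rec.id, residues=residues, description=rec.description)
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    path = Path(path)
    bio = [
        _BioRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w", newline="\n") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


def read_alignment(path: str | Path) -> AlignedBlock:
    """Read an aligned FASTA ('-' gaps) into an AlignedBlock."""
    return AlignedBlock(records=read_fasta(path, aligned=True))


def write_alignment(block: AlignedBlock, path: str | Path) -> None:
    write_fasta(block.records, path)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

class TreeNode:
    """A node of a rooted tree; leaves carry taxon/gene labels."""

    __slots__ = ("label", "children", "parent", "length")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.length = length

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.label!r}, n_children={len(self.children)})"


class RootedTree:
    """A rooted phylogeny with unique leaf labels; polytomies allowed.

    Branch lengths are optional and ignored by the parsimony code
    (topology-only reconstruction).
    """

    def __init__(self, root: TreeNode):
        self.root = root
        self._assign_ids()
        labels = self.leaf_labels()
        if len(labels) != len(set(labels)):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValidationError(f"duplicate leaf labels: {dupes}")

    def _assign_ids(self) -> None:
        # Give every unlabeled internal node a stable postorder id.
        for i, node in enumerate(self.postorder()):
            if node.label is None:
                node.label = f"node{i}"

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                out.append(node)
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))
        return out

    def preorder(self) -> list[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def find(self, label: str) -> TreeNode:
        for node in self.preorder():
            if node.label == label:
                return node
        raise KeyError(label)

    def leaf_set(self, label: str) -> frozenset[str]:
        """Leaf labels subtended by the node with the given label."""
        node = self.find(label)
        out = []
        stack = [node]
        while stack:
            n = stack.pop()
            if n.is_leaf:
                out.append(n.label)
            stack.extend(n.children)
        return frozenset(out)

    def subtree(self, label: str) -> "RootedTree":
        """Deep-copied subtree rooted at the named node."""

        def copy(node: TreeNode) -> TreeNode:
            new = TreeNode(node.label, node.length)
            for c in node.children:
                new.add(copy(c))
            return new

        return RootedTree(copy(self.find(label)))

    def restrict(self, keep: set[str]) -> "RootedTree":
        """Prune to the given leaf set, suppressing unary internal nodes."""

        def prune(node: TreeNode) -> TreeNode | None:
            if node.is_leaf:
                return TreeNode(node.label, node.length) if node.label in keep else None
            kids = [k for k in (prune(c) for c in node.children) if k is not None]
            if not kids:
                return None
            if len(kids) == 1:
                return kids[0]
            new = TreeNode(node.label, node.length)
            for k in kids:
                new.add(k)
            return new

        root = prune(self.root)
        if root is None or root.is_leaf:
            raise ValidationError("restriction leaves fewer than 2 leaves")
        return RootedTree(root)

    # -- serialization -----------------------------------------------------

    def newick(self, include_internal_labels: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                s = node.label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = node.label if include_internal_labels else ""
                if label and label.startswith("node"):
                    label = ""
                s = f"({inner}){label}"
            if node.length is not None:
                s += f":{node.length:g}"
            return s

        return fmt(self.root) + ";"

    def __len__(self) -> int:
        return len(self.leaves())


def _check_parentheses(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise FormatError(
                    f"unbalanced ')' at character offset {offset} in newick string"
                )
    if depth != 0:
        raise FormatError(
            f"unbalanced '(' — {depth} unclosed at end of newick string "
            f"(length {len(text)})"
        )


def tree_from_newick(text: str) -> RootedTree:
    """Parse a single rooted newick string; polytomies are preserved."""
    text = text.strip()
    if not text.endswith(";"):
        raise FormatError("newick string must be terminated by ';'")
    _check_parentheses(text)
    dtree = dendropy.Tree.get(
        data=text,
        schema="newick",
        preserve_underscores=True,
        suppress_internal_node_taxa=False,
        rooting="force-rooted",
    )

    def convert(dnode) -> TreeNode:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = TreeNode(label, dnode.edge.length)
        for child in dnode.child_nodes():
            node.add(convert(child))
        return node

    return RootedTree(convert(dtree.seed_node))


def read_newick(path: str | Path) -> RootedTree:
    return tree_from_newick(Path(path).read_text())


def write_newick(tree: RootedTree, path: str | Path) -> None:
    Path(path).write_text(tree.newick() + "\n")


def attach_copies(tree: RootedTree, copies: dict[str, Sequence[str]]) -> RootedTree:
    """Expand species leaves into gene-copy polytomies.

    ``copies`` maps a species leaf label to its gene ids; a species with one
    gene is simply relabeled, one with several becomes a polytomy at the
    species tip so that within-species duplicates share their stem branch.
    """

    def copy(node: TreeNode) -> TreeNode:
        if node.is_leaf:
            genes = copies.get(node.label)
            if genes is None:
                return TreeNode(node.label, node.length)
            if len(genes) == 1:
                return TreeNode(genes[0], node.length)
            tip = TreeNode(node.label + "_copies", node.length)
            for g in genes:
                tip.add(TreeNode(g))
            return tip
        new = TreeNode(node.label, node.length)
        for c in node.children:
            new.add(copy(c))
        return new

    return RootedTree(copy(tree.root))


# ---------------------------------------------------------------------------
# Presence/absence matrices
# ---------------------------------------------------------------------------

@dataclass
class PresenceMatrix:
    """Genes x ancestral-intron-slots with states P / A / ND.

    ``states`` is a DataFrame indexed by gene id with one column per slot;
    ``species`` and ``clade`` are aligned Series of row annotations.
    """

    states: pd.DataFrame
    species: pd.Series
    clade: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.states.index)

    @property
    def slots(self) -> list[str]:
        return list(self.states.columns)

    def state(self, gene: str, slot: str) -> str:
        return self.states.at[gene, str(slot)]

    def column(self, slot: str) -> dict[str, str]:
        """Leaf-state map for one slot, suitable for the events module."""
        return self.states[str(slot)].to_dict()

    def subset(self, genes: Iterable[str]) -> "PresenceMatrix":
        idx = [g for g in self.genes if g in set(genes)]
        return PresenceMatrix(
            states=self.states.loc[idx],
            species=self.species.loc[idx],
            clade=self.clade.loc[idx],
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PresenceMatrix):
            return NotImplemented
        return self.states.equals(other.states)


def read_matrix(path: str | Path) -> PresenceMatrix:
    """Read a delimited presence/absence matrix.

    Layout: columns gene, species, clade, then one column per intron slot
    with tokens in {P, A, ND}.  Tab or comma delimited (sniffed).
    """
    path = Path(path)
    text = path.read_text()
    sep = "\t" if "\t" in text.splitlines()[0] else ","
    df = pd.read_csv(io.StringIO(text), sep=sep, dtype=str)
    if df.shape[1] < 3:
        raise FormatError(
            f"{path}: expected gene, species, clade plus state columns, "
            f"got {df.shape[1]} columns"
        )
    df.columns = [str(c) for c in df.columns]
    gene_col, species_col, clade_col = df.columns[:3]
    slot_cols = list(df.columns[3:])
    if df[gene_col].duplicated().any():
        dupes = sorted(df[gene_col][df[gene_col].duplicated()])
        raise ValidationError(f"{path}: duplicate gene ids {dupes}")
    states = df.set_index(gene_col)[slot_cols]
    for slot in slot_cols:
        for gene, token in states[slot].items():
            if token not in STATES:
                raise ValidationError(
                    f"{path}: unknown state token {token!r} at row {gene!r}, "
                    f"column {slot!r} (expected one of {STATES})"
                )
    annotated = df.set_index(gene_col)
    return PresenceMatrix(
        states=states,
        species=annotated[species_col],
        clade=annotated[clade_col],
    )


def write_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    df = matrix.states.copy()
    df.insert(0, "clade", matrix.clade)
    df.insert(0, "species", matrix.species)
    df.index.name = "gene"
    with open(path, "w", newline="\n") as fh:
        df.to_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

_DATA_DIR = Path(__file__).parent / "data"


def fixture_path(name: str) -> Path:
    """Path of a packaged data fixture (e.g. 'abcb1_intron_matrix.tsv')."""
    p = _DATA_DIR / name
    if not p.exists():
        raise FileNotFoundError(p)
    return p


def load_abcb1_matrix() -> PresenceMatrix:
    """The ABCB1 intron presence/absence survey across angiosperms."""
    return read_matrix(fixture_path("abcb1_intron_matrix.tsv"))


def load_angiosperm_tree() -> RootedTree:
    """Gene-level angiosperm phylogeny matching the ABCB1 survey rows."""
    return read_newick(fixture_path("angiosperm_tree.nwk"))
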