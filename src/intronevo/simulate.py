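"""Synthetic intron-evolution datasets with full ground truth.

The generator emulates the data the pipeline is built for: an ancestral
gene of E exons and E-1 GT..AG introns evolves along a random rooted tree;
on every branch each retained intron is lost with a fixed probability (and
optionally regained), lost introns are spliced out precisely, and point
substitutions accumulate.  Optional plants give every splice junction an
exact k-base microhomology and place one noisy copy of a motif inside a
chosen intron of every leaf that retains it.

Everything is emitted with its ground truth (true events per branch, true
presence matrix, true gene structures, true motif sites, and an alignment
constructed from the known homology), so inference can be scored exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError
from .io_formats import (
    ABSENT,
    PRESENT,
    AlignedBlock,
    PresenceMatrix,
    RootedTree,
    SequenceRecord,
    TreeNode,
    write_alignment,
    write_fasta,
    write_matrix,
    write_newick,
)
from .structure import DEFAULT_MIN_INTRON, GeneStructure

BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset."""

    seed: int = 0
    n_leaves: int = 16
    n_introns: int = 9
    loss_prob: float = 0.05  # per branch, per retained intron
    gain_prob: float = 0.0  # per branch, per lost intron
    exon_len: tuple[int, int] = (80, 220)  # uniform bounds, bp
    intron_median_bp: float = 100.0  # log-normal median
    intron_sigma: float = 0.5  # log-normal shape (natural log scale)
    mutation_rate: float = 0.01  # per site per branch substitution prob
    microhomology_k: int = 0  # 0 = no plant
    motif: str | None = None  # e.g. "TGTAACATGNNA"; N = random per leaf
    motif_noise: float = 0.0  # per-position replacement probability
    motif_slot: int = 7  # 1-based intron slot carrying the motif
    base_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def validate(self) -> None:
        for p in (self.loss_prob, self.gain_prob, self.mutation_rate, self.motif_noise):
            if not 0.0 <= p <= 1.0:
                raise ValidationError(f"probability out of range: {p}")
        if self.n_leaves < 2 or self.n_introns < 1:
            raise ValidationError("need >= 2 leaves and >= 1 intron")
        if self.exon_len[0] < 2 * (self.microhomology_k + 1):
            raise ValidationError("exons too short for the microhomology plant")
        if self.motif is not None:
            if not 1 <= self.motif_slot <= self.n_introns:
                raise ValidationError(f"motif_slot {self.motif_slot} out of range")
            if len(self.motif) + 4 > 2 * self.intron_median_bp:
                raise ValidationError(
                    "motif longer than the intron length distribution can "
                    "plausibly accommodate (needs > 2x the median intron)"
                )

    def min_intron_bp(self) -> int:
        floor = DEFAULT_MIN_INTRON
        if self.motif is not None:
            floor = max(floor, len(self.motif) + 4 + 2 * (self.microhomology_k + 1))
        if self.microhomology_k:
            floor = max(floor, 2 * (self.microhomology_k + 1) + 2)
        return floor


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset."""

    config: SimConfig
    tree: RootedTree
    leaf_states: dict[str, dict[str, str]]  # leaf -> slot -> P|A
    events: list[tuple[str, str, str]]  # (branch label, slot, loss|gain)
    structures: dict[str, GeneStructure]
    matrix: PresenceMatrix
    alignment: AlignedBlock
    motif_sites: dict[str, int]  # leaf -> offset of the motif in its intron
    ancestral_exon_lengths: list[int] = field(default_factory=list)
    ancestral_intron_lengths: list[int] = field(default_factory=list)

    def true_loss_count(self, slot: str) -> int:
        return sum(1 for _, s, kind in self.events if s == str(slot) and kind == "loss")

    def intron_sequence(self, leaf: str, slot: int | str) -> str | None:
        """Sequence of the ancestral slot's intron in a leaf, or None if lost.

        A leaf's own intron indices are compacted after losses, so the
        slot must be translated through the leaf's retained-slot order.
        """
        states = self.leaf_states[leaf]
        slot = str(slot)
        if states[slot] != PRESENT:
            return None
        own = sum(
            1 for s in range(1, int(slot) + 1) if states[str(s)] == PRESENT
        )
        return self.structures[leaf].intron_sequence(own)


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def simulate_tree(n_leaves: int, seed: int | np.random.Generator = 0) -> RootedTree:
    """Random rooted binary tree by sequential random attachment.

    Each new leaf attaches to an edge chosen uniformly among all edges,
    including the stem above the root, which makes every labelled rooted
    topology equally likely ((2n-3)!! of them).
    """
    if n_leaves < 2:
        raise ValidationError("need at least 2 leaves")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = TreeNode()
    root.add(TreeNode("t1"))
    root.add(TreeNode("t2"))
    nodes: list[TreeNode] = [root.children[0], root.children[1], root]  # root = stem
    for k in range(3, n_leaves + 1):
        target = nodes[int(rng.integers(len(nodes)))]
        leaf = TreeNode(f"t{k}")
        mid = TreeNode()
        if target.parent is None:
            mid.add(target)
            mid.add(leaf)
            root = mid
        else:
            parent = target.parent
            parent.children[parent.children.index(target)] = mid
            mid.parent = parent
            mid.add(target)
            mid.add(leaf)
        nodes.append(leaf)
        nodes.append(mid)
    return RootedTree(root)


# ---------------------------------------------------------------------------
# Intron histories
# ---------------------------------------------------------------------------

def simulate_events(
    tree: RootedTree, config: SimConfig, seed: int | np.random.Generator | None = None
) -> tuple[dict[str, dict[str, str]], list[tuple[str, str, str]]]:
    """Evolve presence/absence of each slot along every branch.

    Every slot starts Present at the root; on each branch a Present slot is
    lost with ``loss_prob`` and (if ``gain_prob`` > 0) an Absent slot is
    regained.  Returns per-leaf states and the event log.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slots = [str(i) for i in range(1, config.n_introns + 1)]
    events: list[tuple[str, str, str]] = []
    leaf_states: dict[str, dict[str, str]] = {}

    def walk(node: TreeNode, state: dict[str, str]) -> None:
        if node.parent is not None:  # root keeps the ancestral all-Present state
            state = dict(state)
            for slot in slots:
                if state[slot] == PRESENT:
                    if rng.random() < config.loss_prob:
                        state[slot] = ABSENT
                        events.append((node.label, slot, "loss"))
                elif config.gain_prob > 0 and rng.random() < config.gain_prob:
                    state[slot] = PRESENT
                    events.append((node.label, slot, "gain"))
        if node.is_leaf:
            leaf_states[node.label] = state
        for child in node.children:
            walk(child, state)

    walk(tree.root, {slot: PRESENT for slot in slots})
    return leaf_states, events


# ---------------------------------------------------------------------------
# Sequences
# ---------------------------------------------------------------------------

def _random_seq(rng: np.random.Generator, n: int, comp) -> np.ndarray:
    return rng.choice(4, size=n, p=np.asarray(comp))


def _different_base(rng: np.random.Generator, base: int) -> int:
    return (base + 1 + int(rng.integers(3))) % 4


def emit_sequences(
    tree: RootedTree,
    leaf_states: dict[str, dict[str, str]],
    config: SimConfig,
    seed: int | np.random.Generator | None = None,
) -> SimTruth:
    """Sample an ancestral gene, evolve it along the tree, and splice.

    Lost introns are removed precisely.  GT..AG boundaries, any planted
    microhomology and the guard bases that keep it exact are shielded from
    substitution so plants stay exact by construction; the motif is written
    into each retaining leaf after substitution, with its own noise.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    comp = np.asarray(config.base_composition, dtype=float)
    comp = comp / comp.sum()
    E = config.n_introns + 1
    exon_lens = [int(rng.integers(config.exon_len[0], config.exon_len[1] + 1)) for _ in range(E)]
    min_intron = config.min_intron_bp()
    mu = float(np.log(config.intron_median_bp))
    intron_lens = []
    for _ in range(config.n_introns):
        L = int(round(float(rng.lognormal(mu, config.intron_sigma))))
        intron_lens.append(max(min_intron, L))

    exons = [_random_seq(rng, n, comp) for n in exon_lens]
    introns = []
    code = {b: i for i, b in enumerate("ACGT")}
    for L in intron_lens:
        arr = _random_seq(rng, L, comp)
        arr[0], arr[1] = code["G"], code["T"]
        arr[-2], arr[-1] = code["A"], code["G"]
        introns.append(arr)

    k = config.microhomology_k
    frozen: list[np.ndarray] = []  # per-segment mutation masks (True = frozen)
    for arr in exons:
        frozen.append(np.zeros(len(arr), dtype=bool))
    for arr in introns:
        m = np.zeros(len(arr), dtype=bool)
        m[:2] = True
        m[-2:] = True
        frozen.append(m)  # placeholder ordering fixed below

    # interleave masks in gene order: exon0, intron0, exon1, ...
    exon_masks = frozen[:E]
    intron_masks = frozen[E:]

    if k > 0:
        for i, intron in enumerate(introns):
            up, dn = exons[i], exons[i + 1]
            # 5' junction: upstream exon suffix equals intron suffix
            up[-k:] = intron[-k:]
            up[-k - 1] = _different_base(rng, int(intron[-k - 1]))
            # 3' junction: downstream exon prefix equals intron prefix
            dn[:k] = intron[:k]
            dn[k] = _different_base(rng, int(intron[k]))
            exon_masks[i][-k - 1:] = True
            exon_masks[i + 1][: k + 1] = True
            intron_masks[i][: k + 1] = True
            intron_masks[i][-k - 1:] = True

    motif_offset = -1
    motif_arr = None
    if config.motif is not None:
        motif_arr = np.array(
            [code.get(ch, -1) for ch in config.motif.upper()], dtype=int
        )
        target = introns[config.motif_slot - 1]
        lo = 2 + (k + 1 if k else 0)
        hi = len(target) - 2 - (k + 1 if k else 0) - len(motif_arr)
        motif_offset = int(rng.integers(lo, max(lo + 1, hi + 1)))

    segments = []
    for i in range(config.n_introns):
        segments.append(("exon", i, exons[i], exon_masks[i]))
        segments.append(("intron", i, introns[i], intron_masks[i]))
    segments.append(("exon", E - 1, exons[E - 1], exon_masks[E - 1]))

    # evolve every segment along the tree with per-branch substitutions
    def mutate(arrs: list[np.ndarray]) -> list[np.ndarray]:
        out = []
        for (kind, i, _, mask), arr in zip(segments, arrs):
            arr = arr.copy()
            hits = np.flatnonzero(
                (rng.random(len(arr)) < config.mutation_rate) & ~mask
            )
            for h in hits:
                arr[h] = _different_base(rng, int(arr[h]))
            out.append(arr)
        return out

    leaf_seqs: dict[str, list[np.ndarray]] = {}

    def walk(node: TreeNode, arrs: list[np.ndarray]) -> None:
        if node.parent is not None:
            arrs = mutate(arrs)
        if node.is_leaf:
            leaf_seqs[node.label] = arrs
        for child in node.children:
            walk(child, arrs)

    walk(tree.root, [arr for _, _, arr, _ in segments])

    # assemble leaves: splice out lost introns, plant the motif, build truth
    structures: dict[str, GeneStructure] = {}
    aligned_records: list[SequenceRecord] = []
    motif_sites: dict[str, int] = {}
    slots = [str(i) for i in range(1, config.n_introns + 1)]
    for leaf in tree.leaf_labels():
        states = leaf_states[leaf]
        arrs = leaf_seqs[leaf]
        pieces: list[str] = []
        aligned: list[str] = []
        exon_coords: list[tuple[int, int]] = []
        pos = 0
        for seg_idx, (kind, i, _, _) in enumerate(segments):
            arr = arrs[seg_idx]
            text = "".join(BASES[arr])
            if kind == "exon":
                if exon_coords and exon_coords[-1][1] == pos:
                    # previous intron was lost: exons fuse precisely
                    exon_coords[-1] = (exon_coords[-1][0], pos + len(text))
                else:
                    exon_coords.append((pos, pos + len(text)))
                pieces.append(text)
                aligned.append(text)
                pos += len(text)
            else:
                slot = str(i + 1)
                if states[slot] == PRESENT:
                    if motif_arr is not None and slot == str(config.motif_slot):
                        site = arr.copy()
                        for w, b in enumerate(motif_arr):
                            bb = int(rng.integers(4)) if b < 0 else int(b)
                            if config.motif_noise and rng.random() < config.motif_noise:
                                bb = int(rng.integers(4))
                            site[motif_offset + w] = bb
                        text = "".join(BASES[site])
                        motif_sites[leaf] = motif_offset
                    pieces.append(text)
                    aligned.append(text)
                    pos += len(text)
                else:
                    aligned.append("-" * len(text))
        genomic = "".join(pieces)
        structures[leaf] = GeneStructure(
            gene_id=leaf, species=leaf, genomic=genomic, exons=exon_coords
        )
        aligned_records.append(SequenceRecord(id=leaf, residues="".join(aligned)))

    import pandas as pd

    state_df = pd.DataFrame.from_dict(
        {leaf: [leaf_states[leaf][s] for s in slots] for leaf in tree.leaf_labels()},
        orient="index",
        columns=slots,
        dtype=object,
    )
    state_df.index.name = "gene"
    matrix = PresenceMatrix(
        states=state_df,
        species=pd.Series({l: l for l in tree.leaf_labels()}, name="species"),
        clade=pd.Series({l: "sim" for l in tree.leaf_labels()}, name="clade"),
    )
    return SimTruth(
        config=config,
        tree=tree,
        leaf_states=leaf_states,
        events=[],
        structures=structures,
        matrix=matrix,
        alignment=AlignedBlock(records=aligned_records),
        motif_sites=motif_sites,
        ancestral_exon_lengths=exon_lens,
        ancestral_intron_lengths=intron_lens,
    )


def simulate_dataset(config: SimConfig) -> SimTruth:
    """Tree + histories + sequences in one call, all from ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = simulate_tree(config.n_leaves, rng)
    leaf_states, events = simulate_events(tree, config, rng)
    truth = emit_sequences(tree, leaf_states, config, rng)
    truth.events = events
    return truth


def write_dataset(truth: SimTruth, outdir: str | Path) -> dict[str, str]:
    """Write the dataset directory; returns the file manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genomic = [
        SequenceRecord(id=l, residues=truth.structures[l].genomic)
        for l in truth.tree.leaf_labels()
    ]
    cdna = [
        SequenceRecord(id=l, residues=truth.structures[l].cdna)
        for l in truth.tree.leaf_labels()
    ]
    write_fasta(genomic, outdir / "genomic.fasta")
    write_fasta(cdna, outdir / "cdna.fasta")
    write_alignment(truth.alignment, outdir / "alignment.afa")
    write_newick(truth.tree, outdir / "tree.nwk")
    write_matrix(truth.matrix, outdir / "truth_matrix.tsv")
    with open(outdir / "truth_events.tsv", "w", newline="\n") as fh:
        fh.write("branch\tslot\ttype\n")
        for branch, slot, kind in truth.events:
            fh.write(f"{branch}\t{slot}\t{kind}\n")
    manifest = {
        "config": dataclasses.asdict(truth.config),
        "files": [
            "genomic.fasta", "cdna.fasta", "alignment.afa", "tree.nwk",
            "truth_matrix.tsv", "truth_events.tsv",
        ],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
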