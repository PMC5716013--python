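import numpy as np
import pytest

from intronevo import homology as hom
from intronevo.errors import AmbiguityError, ValidationError
from intronevo.io_formats import AlignedBlock, SequenceRecord
from intronevo.simulate import SimConfig, simulate_dataset
from intronevo.structure import GeneStructure, infer_introns


def structure_from(genomic, exons, gene_id="g"):
    return GeneStructure(gene_id=gene_id, genomic=genomic, exons=exons)


class TestProjection:
    def test_identical_genes_project_to_identical_columns(self):
        genomic = "AAAAAAAAAA" + "GT" + "C" * 20 + "AG" + "TTTTTTTTTT"
        sts = [
            structure_from(genomic, [(0, 10), (34, 44)], f"g{i}") for i in range(2)
        ]
        block = AlignedBlock(
            records=[SequenceRecord(id=f"g{i}", residues=genomic) for i in range(2)]
        )
        p1, p2 = hom.project_introns(block, sts)
        assert p1.column == p2.column == 9

    def test_gaps_shift_columns(self):
        g1 = "AAAAAAAAAA" + "GT" + "C" * 20 + "AG" + "TTTTTTTTTT"
        g2 = "AAAAAAAA" + "GT" + "C" * 20 + "AG" + "TTTTTTTTTT"
        sts = [
            structure_from(g1, [(0, 10), (34, 44)], "g1"),
            structure_from(g2, [(0, 8), (32, 42)], "g2"),
        ]
        block = AlignedBlock(
            records=[
                SequenceRecord(id="g1", residues=g1),
                SequenceRecord(id="g2", residues="--" + g2),
            ]
        )
        p1, p2 = hom.project_introns(block, sts)
        assert p1.column == p2.column == 9  # homologous despite length diff

    def test_zero_intron_gene_yields_zero_projections(self):
        g = "ACGT" * 10
        block = AlignedBlock(records=[SequenceRecord(id="g", residues=g)])
        assert hom.project_introns(block, [structure_from(g, [(0, 40)])]) == []

    def test_sequence_alignment_mismatch_names_gene(self):
        g = "ACGT" * 10
        block = AlignedBlock(records=[SequenceRecord(id="g", residues="A" * 40)])
        with pytest.raises(ValidationError, match="'g'"):
            hom.project_introns(block, [structure_from(g, [(0, 40)])])

    def test_cdna_mode_projects_exon_junctions(self):
        genomic = "AAAAAAAAAA" + "GT" + "C" * 20 + "AG" + "TTTTTTTTTT"
        stc = structure_from(genomic, [(0, 10), (34, 44)])
        block = AlignedBlock(
            records=[SequenceRecord(id="g", residues="AAAAAAAAAATTTTTTTTTT")]
        )
        (proj,) = hom.project_introns(block, [stc], mode=hom.CDNA_MODE)
        assert proj.column == 9


class TestClustering:
    def _proj(self, gene, idx, col, phase=0):
        return hom.IntronProjection(gene, idx, col, phase)

    def test_exact_columns_tolerance_zero(self):
        projections = [
            self._proj("a", 1, 10), self._proj("b", 1, 10),
            self._proj("a", 2, 30), self._proj("b", 2, 44),
        ]
        result = hom.cluster_slots(projections, column_tolerance=0)
        assert result.n_slots == 3
        assert result.assignments[("a", 1)] == result.assignments[("b", 1)] == 1

    def test_nearby_but_different_phase_never_merges(self):
        # two nearby slots stay distinct when phases differ (the paralog
        # intron-8 situation: same neighbourhood, different phase)
        projections = [self._proj("a", 1, 100, phase=0), self._proj("b", 1, 102, phase=1)]
        result = hom.cluster_slots(projections, column_tolerance=5)
        assert result.n_slots == 2
        merged = hom.cluster_slots(projections, column_tolerance=5, require_same_phase=False)
        assert merged.n_slots == 1

    def test_matches_brute_force_transitive_closure(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            tol = int(rng.integers(0, 4))
            projections = [
                self._proj(f"g{i}", 1, int(rng.integers(0, 40)), int(rng.integers(2)))
                for i in range(8)
            ]
            try:
                result = hom.cluster_slots(projections, column_tolerance=tol)
            except AmbiguityError:
                continue
            # brute-force closure over the pairwise relation
            n = len(projections)
            adj = {i: {i} for i in range(n)}
            for i in range(n):
                for j in range(n):
                    if (
                        abs(projections[i].column - projections[j].column) <= tol
                        and projections[i].phase == projections[j].phase
                    ):
                        adj[i].add(j)
            changed = True
            while changed:
                changed = False
                for i in range(n):
                    for j in list(adj[i]):
                        if not adj[j] <= adj[i]:
                            adj[i] |= adj[j]
                            changed = True
            components = {frozenset(adj[i]) for i in range(n)}
            assert result.n_slots == len(components)

    def test_two_introns_of_one_gene_in_one_cluster_is_ambiguous(self):
        projections = [
            self._proj("a", 1, 10), self._proj("a", 2, 11), self._proj("b", 1, 10),
        ]
        with pytest.raises(AmbiguityError, match="'a'"):
            hom.cluster_slots(projections, column_tolerance=2)

    def test_slot_order_invariant_to_gene_input_order(self):
        rng = np.random.default_rng(23)
        cols = [5, 20, 33, 47]
        projections = [
            self._proj(f"g{i}", k + 1, cols[k] + 0)
            for i in range(5)
            for k in range(4)
        ]
        base = hom.cluster_slots(projections)
        for _ in range(5):
            shuffled = list(projections)
            rng.shuffle(shuffled)
            again = hom.cluster_slots(shuffled)
            assert again.assignments == base.assignments


class TestBuildMatrix:
    def test_empty_gene_list_gives_empty_matrix(self):
        out = hom.build_matrix(
            hom.HomologyMap(n_slots=3, assignments={}, slot_columns={}), []
        )
        assert out.genes == []

    def test_present_absent_and_nd_overlay(self):
        hmap = hom.HomologyMap(
            n_slots=3,
            assignments={("a", 1): 1, ("a", 2): 3, ("b", 1): 2},
            slot_columns={1: 1.0, 2: 2.0, 3: 3.0},
        )
        out = hom.build_matrix(
            hmap,
            [("a", "spA", "x"), ("b", "spB", "x")],
            nd_annotations={("b", 3): True},
        )
        assert list(out.states.loc["a"]) == ["P", "A", "P"]
        assert list(out.states.loc["b"]) == ["A", "P", "ND"]


class TestSummaries:
    def test_fixture_28_of_32_dicot_species_intact(self, abcb1_matrix):
        summary = hom.summarize_matrix(abcb1_matrix, collapse=hom.ALL_COPIES)
        assert summary.units_by_clade["dicot"] == 32
        assert summary.intact_by_clade["dicot"] == 28

    def test_fixture_intron_count_range_one_to_nine(self, abcb1_matrix):
        summary = hom.summarize_matrix(abcb1_matrix)
        assert summary.min_introns == 1
        assert summary.max_introns == 9

    def test_all_present_toy_counts_equal_slot_count(self):
        hmap = hom.HomologyMap(
            n_slots=2,
            assignments={("a", 1): 1, ("a", 2): 2, ("b", 1): 1, ("b", 2): 2},
            slot_columns={1: 1.0, 2: 2.0},
        )
        m = hom.build_matrix(hmap, [("a", "s1", "c"), ("b", "s2", "c")])
        summary = hom.summarize_matrix(m, collapse=hom.GENE_LEVEL)
        assert set(summary.per_gene_counts.values()) == {2}
        assert summary.intact_by_clade == {"c": 2}

    def test_species_rules_bracket_gene_level(self, abcb1_matrix):
        strict = hom.summarize_matrix(abcb1_matrix, collapse=hom.ALL_COPIES)
        loose = hom.summarize_matrix(abcb1_matrix, collapse=hom.ANY_COPY)
        for clade in strict.units_by_clade:
            assert strict.intact_by_clade[clade] <= loose.intact_by_clade[clade]

    def test_unknown_rule_rejected(self, abcb1_matrix):
        with pytest.raises(ValidationError):
            hom.summarize_matrix(abcb1_matrix, collapse="bogus")


class TestEndToEnd:
    def test_pipeline_matrix_equals_simulated_truth(self):
        """infer -> project -> cluster -> build equals the generator's
        truth matrix (restricted to slots retained in >= 1 leaf)."""
        for seed in range(8):
            cfg = SimConfig(seed=seed, n_leaves=6, n_introns=5, loss_prob=0.15)
            truth = simulate_dataset(cfg)
            structures = [
                infer_introns(s.genomic, s.cdna, gene_id=s.gene_id)
                for s in truth.structures.values()
            ]
            hmap = hom.cluster_slots(hom.project_introns(truth.alignment, structures))
            built = hom.build_matrix(
                hmap, [(s.gene_id, s.gene_id, "sim") for s in structures]
            )
            surviving = [
                c for c in truth.matrix.slots if (truth.matrix.states[c] == "P").any()
            ]
            assert built.states.shape[1] == len(surviving)
            expected = truth.matrix.states[surviving].loc[built.states.index]
            assert (built.states.to_numpy() == expected.to_numpy()).all()
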