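import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_
from scipy.stats import fisher_exact

from intronevo import boundaries as bnd
from intronevo.boundaries import _exact_2xk_pvalue
from intronevo.errors import ValidationError
from intronevo.homology import cluster_slots, project_introns
from intronevo.simulate import SimConfig, simulate_dataset
from intronevo.structure import GeneStructure, infer_introns
from oracles import naive_microhomology

dna = st_.text(alphabet="ACGT", min_size=0, max_size=20)


class TestMicrohomology:
    def test_definition_examples(self):
        res = bnd.microhomology("TTACAG", "GTTTTCAG", "AAAA")
        assert res.k5 == 3
        res = bnd.microhomology("CCCC", "GTAATTTTAG", "GTACCC")
        assert res.k3 == 3

    def test_brute_force_equivalence_random(self):
        rng = np.random.default_rng(31)
        for _ in range(2000):
            up = "".join(rng.choice(list("ACGT"), size=rng.integers(0, 12)))
            iv = "".join(rng.choice(list("ACGT"), size=rng.integers(2, 15)))
            dn = "".join(rng.choice(list("ACGT"), size=rng.integers(0, 12)))
            res = bnd.microhomology(up, iv, dn)
            assert (res.k5, res.k3) == naive_microhomology(up, iv, dn)

    @settings(max_examples=200, derandomize=True)
    @given(up=dna, iv=st_.text(alphabet="ACGT", min_size=2, max_size=20), dn=dna)
    def test_brute_force_equivalence_property(self, up, iv, dn):
        res = bnd.microhomology(up, iv, dn)
        assert (res.k5, res.k3) == naive_microhomology(up, iv, dn)

    def test_reverse_complement_symmetry(self):
        """k is invariant under reverse-complementing all three pieces with
        the exon roles swapped (k5 and k3 exchange)."""
        comp = str.maketrans("ACGT", "TGCA")

        def rc(s):
            return s.translate(comp)[::-1]

        rng = np.random.default_rng(37)
        for _ in range(500):
            up = "".join(rng.choice(list("ACGT"), size=8))
            iv = "".join(rng.choice(list("ACGT"), size=12))
            dn = "".join(rng.choice(list("ACGT"), size=8))
            fwd = bnd.microhomology(up, iv, dn)
            rev = bnd.microhomology(rc(dn), rc(iv), rc(up))
            assert (fwd.k5, fwd.k3) == (rev.k3, rev.k5)

    def test_placement_invariance_on_sliders(self):
        """An intron that can slide (upstream exon suffix equals the intron
        suffix) yields the same max-k at every equivalent placement: the
        shared bases move from the 5' side to the 3' side but max(k5, k3)
        is unchanged."""
        rng = np.random.default_rng(53)
        for _ in range(200):
            s = int(rng.integers(1, 5))  # shared bases enabling the slide
            shared = "".join(rng.choice(list("ACGT"), size=s))
            up = "".join(rng.choice(list("ACGT"), size=6)) + shared
            iv = "".join(rng.choice(list("ACGT"), size=8)) + shared
            dn = "".join(rng.choice(list("ACGT"), size=8))
            for d in range(s + 1):  # slide the intron left by d bases
                up_d = up[: len(up) - d]
                iv_d = up[len(up) - d:] + iv[: len(iv) - d]
                dn_d = iv[len(iv) - d:] + dn
                res = bnd.microhomology(up_d, iv_d, dn_d)
                # the repeat enabling an s-base slide is split d/(s-d)
                # across the junctions; each side sees at least its share
                assert res.k5 >= s - d and res.k3 >= d
                assert res.k >= max(d, s - d)
            # the two extreme placements both expose the full repeat
            assert bnd.microhomology(up, iv, dn).k >= s

    def test_empty_flank_warns_with_zero_k(self):
        res = bnd.microhomology("", "GTAAAG", "AAA")
        assert res.k5 == 0 and res.warning == "empty flank"

    def test_intron_shorter_than_two_rejected(self):
        with pytest.raises(ValidationError):
            bnd.microhomology("AAA", "G", "AAA")


class TestSurvey:
    def test_planted_k_is_modal_everywhere(self):
        cfg = SimConfig(seed=3, n_leaves=8, n_introns=5, loss_prob=0.05,
                        microhomology_k=3)
        truth = simulate_dataset(cfg)
        structures = list(truth.structures.values())
        hmap = cluster_slots(project_introns(truth.alignment, structures))
        survey = bnd.microhomology_survey(structures, hmap)
        assert set(survey.attrs["modal_k"].values()) == {3}
        assert survey.attrs["flagged_slots"] == []

    def test_no_plant_matches_closed_form_null(self):
        """Without a plant, P(k >= 1) per junction is 1 - (3/4)^2 (either
        side matching one random base); checked within binomial error."""
        rng = np.random.default_rng(41)
        hits = total = 0
        for _ in range(3000):
            up = "".join(rng.choice(list("ACGT"), size=8))
            iv = "".join(rng.choice(list("ACGT"), size=12))
            dn = "".join(rng.choice(list("ACGT"), size=8))
            res = bnd.microhomology(up, iv, dn)
            hits += res.k >= 1
            total += 1
        expected = 1 - (3 / 4) ** 2
        se = np.sqrt(expected * (1 - expected) / total)
        assert abs(hits / total - expected) < 4 * se

    def test_empty_structure_list_gives_empty_survey(self):
        from intronevo.homology import HomologyMap

        survey = bnd.microhomology_survey(
            [], HomologyMap(n_slots=0, assignments={}, slot_columns={})
        )
        assert survey.empty and survey.attrs["flagged_slots"] == []


class TestPenultimate:
    def _structure(self, base_at_minus2, gene_id):
        # exon1 ends ...<base>G | intron | exon2
        e1 = "ATGAAAAAAA" + base_at_minus2 + "G"
        genomic = e1 + "GT" + "C" * 20 + "AG" + "TTTTTTTTTTTT"
        return GeneStructure(
            gene_id=gene_id, genomic=genomic,
            exons=[(0, len(e1)), (len(e1) + 24, len(genomic))],
        )

    def test_identical_composition_gives_p_one(self):
        grp1 = [self._structure("A", f"a{i}") for i in range(6)]
        grp2 = [self._structure("A", f"b{i}") for i in range(6)]
        res = bnd.penultimate_test(grp1, grp2, slot=2, upstream_exon_index=0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_column_case_matches_scipy_fisher(self):
        rng = np.random.default_rng(43)
        for _ in range(30):
            n1, n2 = int(rng.integers(3, 10)), int(rng.integers(3, 10))
            a = int(rng.integers(0, n1 + 1))
            b = int(rng.integers(0, n2 + 1))
            grp1 = [self._structure("A", f"a{i}") for i in range(a)] + [
                self._structure("C", f"aa{i}") for i in range(n1 - a)
            ]
            grp2 = [self._structure("A", f"b{i}") for i in range(b)] + [
                self._structure("C", f"bb{i}") for i in range(n2 - b)
            ]
            res = bnd.penultimate_test(grp1, grp2, slot=2, upstream_exon_index=0)
            table = [[a, n1 - a], [b, n2 - b]]
            if res.table.shape[1] == 2:
                _, expected = fisher_exact(table, alternative="two-sided")
                assert res.p_value == pytest.approx(expected, rel=1e-6)

    def test_disjoint_base_usage_matches_hand_hypergeometric(self):
        # 8 vs 8 with disjoint single-base usage: 2x2 with zero diagonal;
        # hand enumeration: p = 2 / C(16, 8)
        grp1 = [self._structure("A", f"a{i}") for i in range(8)]
        grp2 = [self._structure("G", f"b{i}") for i in range(8)]
        res = bnd.penultimate_test(grp1, grp2, slot=2, upstream_exon_index=0)
        from math import comb

        assert res.p_value == pytest.approx(2 / comb(16, 8), rel=1e-9)

    def test_exact_2xk_against_r_style_enumeration(self):
        # 2x3 table checked against independent full-table enumeration
        import itertools
        from math import comb

        table = np.array([[4, 1, 0], [1, 3, 3]])
        col = table.sum(axis=0)
        n1 = table[0].sum()

        def prob(row):
            num = 1
            for a, c in zip(row, col):
                num *= comb(c, a)
            return num / comb(table.sum(), n1)

        obs = prob(tuple(table[0]))
        expected = sum(
            prob((a, b, n1 - a - b))
            for a in range(col[0] + 1)
            for b in range(col[1] + 1)
            if 0 <= n1 - a - b <= col[2]
            and prob((a, b, n1 - a - b)) <= obs + 1e-12
        )
        assert _exact_2xk_pvalue(table) == pytest.approx(expected, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            bnd.penultimate_test([], [self._structure("A", "b")], 2, 0)


class TestSizeStats:
    def test_single_gene_mean_equals_median(self):
        cfg = SimConfig(seed=5, n_leaves=4, n_introns=3, loss_prob=0.0)
        truth = simulate_dataset(cfg)
        structures = list(truth.structures.values())[:1]
        hmap = cluster_slots(project_introns(truth.alignment, structures))
        stats = bnd.size_stats(structures, hmap)
        assert (stats["mean_bp"] == stats["median_bp"]).all()

    def test_two_value_arithmetic(self):
        vals = np.array([68, 1071])
        assert vals.mean() == 569.5 and np.median(vals) == 569.5

    def test_lognormal_lengths_recover_generating_mean(self):
        cfg = SimConfig(seed=11, n_leaves=4, n_introns=40, loss_prob=0.0,
                        intron_median_bp=150.0, intron_sigma=0.4)
        truth = simulate_dataset(cfg)
        lengths = np.array(truth.ancestral_intron_lengths, dtype=float)
        gen_mean = 150.0 * np.exp(0.4 ** 2 / 2)
        se = lengths.std(ddof=1) / np.sqrt(len(lengths))
        assert abs(lengths.mean() - gen_mean) < 2.5 * se + 2
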