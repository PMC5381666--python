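"""Ratios, exact tests, permutation null and dataset-level tables."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from termswitch.alignment import TerminatorAlignment
from termswitch.ancestral import SubstitutionModel, reconstruct_alignment
from termswitch.stats import (PermutationNull, SwitchSummary,
                              bidirectional_analysis, binomial_two_tailed,
                              compare_compensation_distances,
                              conservation_summary, expected_double_fraction,
                              fisher_two_tailed, intermediate_observed_ratio,
                              pair_fate_table, permutation_null,
                              positional_variability, tir)
from termswitch.ancestral import GeneReconstruction
from termswitch.structure import parse_dot_bracket
from termswitch.switches import pair_code

from conftest import make_joint

REF_STRUCT = "(((((...)))))"
A, C, G, U = 0, 1, 2, 3


def make_aln(gene_id, sequences, ref="a", struct=REF_STRUCT,
             struct_seq="GGGGGAAACCCCC"):
    structure = parse_dot_bracket(struct, struct_seq)
    return TerminatorAlignment.from_structure(gene_id, sequences, ref,
                                              structure)


class TestRatios:
    def test_tir_values(self):
        assert tir(112, 65, 65) == pytest.approx(177 / 65)
        assert round(tir(112, 65, 65), 2) == 2.72
        assert tir(2, 1, 1) == 3.0
        assert tir(1, 0, 0) == math.inf
        with pytest.raises(ValueError):
            tir(-1, 1, 1)

    def test_intermediate_observed_ratio(self):
        assert intermediate_observed_ratio((2, 1, 1, 1, 1)) == 1.0
        assert intermediate_observed_ratio((10, 2, 1, 2, 1)) == 3.0
        assert intermediate_observed_ratio((1, 0, 0, 0, 0)) == math.inf

    def test_summary_from_no_events(self):
        s = SwitchSummary.from_events([])
        assert s.total == 0
        assert s.tir == math.inf


class TestExactTests:
    def test_binomial_all_failures(self):
        assert binomial_two_tailed(0, 10, 0.5) == pytest.approx(2 / 1024)

    def test_binomial_symmetry(self):
        assert binomial_two_tailed(3, 10, 0.5) == \
            pytest.approx(binomial_two_tailed(7, 10, 0.5))

    def test_binomial_validation(self):
        with pytest.raises(ValueError):
            binomial_two_tailed(11, 10, 0.5)
        with pytest.raises(ValueError):
            binomial_two_tailed(5, 10, 0.0)

    def test_fisher_diagonal_table(self):
        # [[10,0],[0,10]]: the two one-sided extremes each have
        # probability 1/C(20,10); two-sided doubles it
        assert fisher_two_tailed([[10, 0], [0, 10]]) == \
            pytest.approx(2 / comb(20, 10, exact=True))

    def test_fisher_no_association(self):
        assert fisher_two_tailed([[5, 5], [5, 5]]) == pytest.approx(1.0)

    def test_expected_double_fraction(self):
        e, p = expected_double_fraction(10, 20, 100, 2)
        assert e == pytest.approx(0.02)
        assert p == pytest.approx(binomial_two_tailed(2, 100, 0.02))
        e0, p0 = expected_double_fraction(0, 20, 100, 0)
        assert e0 == 0.0 and p0 == 1.0

    def test_mannwhitney_separated_groups(self):
        p, m1, m2 = compare_compensation_distances([1, 2, 3], [10, 11, 12])
        assert p == pytest.approx(0.1)       # exact: 2/C(6,3)
        assert (m1, m2) == (2.0, 11.0)

    def test_mannwhitney_identical_groups(self):
        p, _, _ = compare_compensation_distances([1.0, 2.0], [2.0, 1.0])
        assert p == 1.0

    def test_mannwhitney_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_compensation_distances([], [1.0])


class TestPermutationNull:
    def _pool(self, ladder_tree):
        # three resolved nucleotide columns over the ladder tree
        cols = np.array([
            [A, A, G, A, A, A, G],
            [U, U, C, U, U, U, C],
            [G, G, G, A, G, G, A],
        ])
        return cols

    def test_deterministic(self, ladder_tree):
        pool = self._pool(ladder_tree)
        a = permutation_null(ladder_tree, pool, n_permutations=200, seed=5,
                             batch_size=10, n_samples=50)
        b = permutation_null(ladder_tree, pool, n_permutations=200, seed=5,
                             batch_size=10, n_samples=50)
        assert np.array_equal(a.type_counts, b.type_counts)
        assert np.array_equal(a.tir_samples, b.tir_samples)

    def test_counts_shape_and_accounting(self, ladder_tree):
        null = permutation_null(ladder_tree, self._pool(ladder_tree),
                                n_permutations=100, seed=0,
                                batch_size=4, n_samples=30)
        assert null.type_counts.shape == (100, 5)
        assert np.all(null.type_counts >= 0)
        assert null.tir_samples.size + null.n_undefined_tir == 30
        assert null.ratio_samples.size + null.n_undefined_ratio == 30

    def test_invariant_pool_all_undefined(self, ladder_tree):
        pool = np.array([[A] * 7, [U] * 7, [G] * 7])
        null = permutation_null(ladder_tree, pool, n_permutations=50,
                                seed=1, n_samples=20)
        assert null.n_undefined_tir == 20
        assert math.isnan(null.interval("tir")[0])
        assert null.significant(5.0, "tir") is False

    def test_interval_order_statistics_with_inf(self):
        samples = np.array([0.5, 1.0, 2.0, math.inf])
        null = PermutationNull(
            n_permutations=4, seed=0, type_counts=np.zeros((4, 5), int),
            batch_size=1, n_samples=4, tir_samples=samples,
            ratio_samples=samples, n_undefined_tir=0, n_undefined_ratio=0)
        lo, hi = null.interval("tir")
        assert lo == 0.5 and hi == math.inf
        assert null.significant(0.4, "tir")
        assert not null.significant(100.0, "tir")   # inf upper bound

    def test_tiny_pool_rejected(self, ladder_tree):
        with pytest.raises(ValueError):
            permutation_null(ladder_tree, np.array([[A] * 7]),
                             n_permutations=10)


class TestConservation:
    def test_region_fractions(self):
        seqs = {"a": "GGGGGAAACCCCC", "b": "GGGGGAACCCCCC"}  # loop col 7 A/C
        df = conservation_summary([make_aln("g1", seqs)])
        stem = df[df.region == "stem"].iloc[0]
        loop = df[df.region == "loop"].iloc[0]
        assert stem.invariant_fraction == 1.0
        assert loop.invariant_fraction == pytest.approx(2 / 3)
        assert loop.variable_mismatch_fraction == 1.0


def _two_strain_rec(aln, cherry_tree, resolved_cols):
    """GeneReconstruction with hand-set resolved states (n_cols, 3)."""
    res = np.asarray(resolved_cols, dtype=np.int64)
    post = np.zeros((res.shape[0], 3, 4))
    model = SubstitutionModel.jc()
    return GeneReconstruction(gene_id=aln.gene_id, tree=cherry_tree,
                              model=model, posteriors=post, resolved=res)


class TestPairFates:
    def test_single_side_destination(self, cherry_tree):
        # root AU at pair (0,12); strain b substitutes A->G: single_first
        # with destination GU
        seqs = {"a": "AGGGGAAACCCCU", "b": "GGGGGAAACCCCU"}
        aln = make_aln("g1", seqs, struct_seq="AGGGGAAACCCCU")
        res = np.full((13, 3), -1, dtype=np.int64)
        for col, vals in {0: [A, A, G], 1: [G, G, G], 2: [G, G, G],
                          3: [G, G, G], 4: [G, G, G], 10: [C, C, C],
                          9: [C, C, C], 11: [C, C, C], 12: [U, U, U],
                          8: [C, C, C]}.items():
            res[col] = vals
        rec = _two_strain_rec(aln, cherry_tree, res)
        df = pair_fate_table([aln], {"g1": rec})
        row = df[(df.ancestral_pair == "AU")
                 & (df.category == "single_first")]
        assert len(row) == 1
        assert row.iloc[0].destination == "GU"
        assert row.iloc[0]["count"] == 1
        inv = df[(df.ancestral_pair == "GC") & (df.category == "invariant")]
        assert inv.iloc[0]["count"] == 4

    def test_unresolved_root_bucket(self, cherry_tree):
        seqs = {"a": "GGGGGAAACCCCC", "b": "GGGGGAAACCCCC"}
        aln = make_aln("g1", seqs)
        res = np.full((13, 3), -1, dtype=np.int64)   # everything unresolved
        df = pair_fate_table([aln], {"g1": _two_strain_rec(
            aln, cherry_tree, res)})
        assert df[df.category == "unresolved_root"].iloc[0]["count"] == 5

    def test_both_sides_with_wc_switch(self, cherry_tree):
        # pair (0,12): a=AU, b=GC, root resolved GU -> both columns
        # variable, and the joint states contain a WC switch
        seqs = {"a": "AGGGGAAACCCCU", "b": "GGGGGAAACCCCC"}
        aln = make_aln("g1", seqs, struct_seq="AGGGGAAACCCCU")
        res = np.full((13, 3), -1, dtype=np.int64)
        res[0] = [G, A, G]
        res[12] = [U, U, C]
        for col in (1, 2, 3, 4):
            res[col] = [G, G, G]
        for col in (8, 9, 10, 11):
            res[col] = [C, C, C]
        df = pair_fate_table([aln], {"g1": _two_strain_rec(
            aln, cherry_tree, res)})
        both = df[df.category == "both"]
        assert both.iloc[0].destination == "with_wc_switch"


class TestPositional:
    def test_tables_partition_columns(self, cherry_tree):
        seqs = {"a": "AGGGGAAACCCCU", "b": "GGGGGAAACCCCU"}
        aln = make_aln("g1", seqs, struct_seq="AGGGGAAACCCCU")
        res = np.full((13, 3), -1, dtype=np.int64)
        res[0] = [A, A, G]
        res[12] = [U, U, U]
        for col in (1, 2, 3, 4):
            res[col] = [G, G, G]
        for col in (8, 9, 10, 11):
            res[col] = [C, C, C]
        out = positional_variability([aln], {"g1": _two_strain_rec(
            aln, cherry_tree, res)})
        tab_au, _ = out["external_vs_internal_AU"]
        # pair 0 (AU root) is the outer external pair: one variable
        # column (0) and one invariant (12)
        assert tab_au.tolist() == [[1, 1], [0, 0]]
        tab_gc, _ = out["external_vs_internal_GC"]
        assert tab_gc.tolist() == [[0, 2], [0, 6]]
        io, _ = out["inner_vs_outer_external"]
        assert io.tolist() == [[0, 2], [1, 1]]
        arm, p = out["right_vs_left_outer_arm"]
        assert arm.tolist() == [[0, 1], [1, 0]]
        assert 0.0 <= p <= 1.0


def _mirror_aln(aln, gene_id):
    """Reverse-complement counterpart reading the same physical hairpin."""
    comp = {"A": "U", "U": "A", "G": "C", "C": "G"}
    seqs = {k: "".join(comp[c] for c in reversed(v))
            for k, v in aln.sequences.items()}
    ref_rc = "".join(comp[c] for c in reversed(aln.ungapped_reference))
    return make_aln(gene_id, seqs, struct_seq=ref_rc)


class TestBidirectional:
    def _annotations(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "start", "end",
                                           "strand", "term_start",
                                           "term_end"])

    def test_coinciding_counted_per_gene(self):
        a = make_aln("gA", {"a": "AGGGGAAACCCCU", "b": "GGGGGAAACCCCU"},
                     struct_seq="AGGGGAAACCCCU")
        b = _mirror_aln(a, "gB")
        base = make_aln("gC", {"a": "GGGGGAAACCCCC", "b": "GGGGGAAACCCCC"})
        base2 = make_aln("gD", {"a": "GGGGGAAACCCCC", "b": "GGGGGAAACCCCC"})
        ann = self._annotations([
            ("gA", 0, 100, "+", 110, 123),
            ("gB", 200, 300, "-", 110, 123),
            ("gC", 400, 500, "+", 510, 523),
            ("gD", 600, 700, "+", 710, 723),
        ])
        res = bidirectional_analysis(ann, [a, b, base, base2])
        assert res.category_by_gene["gA"] == "coinciding"
        assert res.category_by_gene["gB"] == "coinciding"
        # gA has one single-variable pair; its mirror gB has the same one,
        # and coinciding terminators are counted once per gene => 2
        assert res.tables["coinciding"][0].tolist() == [2, 8]
        assert 0.0 <= res.p_values["coinciding"] <= 1.0

    def test_terminator_inside_second_gene_excluded(self):
        a = make_aln("gA", {"a": "GGGGGAAACCCCC", "b": "GGGGGAAACCCCC"})
        ann = self._annotations([
            ("gA", 0, 100, "+", 250, 263),     # inside gB
            ("gB", 200, 400, "-", -1, -1),
        ])
        res = bidirectional_analysis(ann, [a])
        assert res.exclusions.get("inside_second_gene") == 1
        assert "gA" not in res.category_by_gene

    def test_single_shared_requires_proximity(self):
        a = make_aln("gA", {"a": "GGGGGAAACCCCC", "b": "GGGGGAAACCCCC"})
        near = self._annotations([
            ("gA", 0, 100, "+", 110, 123),
            ("gB", 150, 300, "-", -1, -1),
        ])
        far = self._annotations([
            ("gA", 0, 100, "+", 110, 123),
            ("gB", 900, 1100, "-", -1, -1),
        ])
        res_near = bidirectional_analysis(near, [a])
        res_far = bidirectional_analysis(far, [a])
        assert res_near.category_by_gene.get("gA") == "single_shared"
        assert res_far.exclusions.get("too_far") == 1

    def test_missing_strand_column_rejected(self):
        with pytest.raises(ValueError):
            bidirectional_analysis(pd.DataFrame({"gene_id": []}), [])
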