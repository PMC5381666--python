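"""Simulator: pair rate matrix, jump chain, Yule trees, full datasets."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.linalg import expm

from termswitch.ancestral import SubstitutionModel, f81_transition_matrix
from termswitch.simulate import (DEFAULT_ROOT_COMPOSITION, PairFitnessModel,
                                 SimulationConfig, build_pair_rate_matrix,
                                 generate_dataset, simulate_pair_evolution,
                                 simulate_yule_tree)
from termswitch.switches import (WC_CODES, GU, UG, pair_code, pair_string,
                                 switch_type_counts)

A, C, G, U = 0, 1, 2, 3


def code(s):
    return pair_code(s)


class TestRateMatrix:
    def test_single_change_rates(self):
        m = PairFitnessModel(mutation_rate=2.0,
                             base_frequencies=(0.1, 0.2, 0.3, 0.4),
                             acceptance_gu=0.3, acceptance_mismatch=0.01)
        Q = build_pair_rate_matrix(m)
        # AU -> GU: left A->G, resulting pair is wobble -> mu*pi_G*g
        assert Q[code("AU"), code("GU")] == pytest.approx(2.0 * 0.3 * 0.3)
        # AU -> AC: right U->C, resulting pair mismatch -> mu*pi_C*m
        assert Q[code("AU"), code("AC")] == pytest.approx(2.0 * 0.2 * 0.01)
        # GU -> GC: right U->C, resulting pair WC -> mu*pi_C*1
        assert Q[code("GU"), code("GC")] == pytest.approx(2.0 * 0.2 * 1.0)
        # AU -> GC needs two simultaneous changes: rate 0
        assert Q[code("AU"), code("GC")] == 0.0

    def test_rows_sum_to_zero(self):
        Q = build_pair_rate_matrix(PairFitnessModel(
            base_frequencies=(0.4, 0.1, 0.2, 0.3)))
        assert np.allclose(Q.sum(axis=1), 0.0)
        off = Q - np.diag(np.diag(Q))
        assert np.all(off >= 0)

    def test_detailed_balance_stationary(self):
        # stationary density prop. to acceptance(s) * pi_l * pi_r
        m = PairFitnessModel(base_frequencies=(0.1, 0.2, 0.3, 0.4),
                             acceptance_gu=0.3, acceptance_mismatch=0.01)
        Q = build_pair_rate_matrix(m)
        acc = np.array([1.0 if s in WC_CODES else
                        0.3 if s in (GU, UG) else 0.01 for s in range(16)])
        pi = np.array([m.pi[s // 4] * m.pi[s % 4] for s in range(16)]) * acc
        pi /= pi.sum()
        assert np.allclose(pi @ Q, 0.0, atol=1e-12)
        # detailed balance pi_s Q_st = pi_t Q_ts
        assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-14)

    def test_neutral_factorizes_into_two_f81_columns(self):
        # g = m = 1: the joint chain is two independent F81 sites, so
        # expm(Q t) equals the outer product of two F81 transition matrices
        freqs = (0.15, 0.35, 0.3, 0.2)
        m = PairFitnessModel(base_frequencies=freqs, acceptance_gu=1.0,
                             acceptance_mismatch=1.0)
        Q = build_pair_rate_matrix(m)
        # F81 rate matrix beta-normalized to 1 sub/site differs from this
        # chain only by total rate; compare via matching time scales
        f81 = SubstitutionModel(name="F81", base_frequencies=freqs)
        for t in (0.05, 0.3):
            P16 = expm(Q * t)
            # the pair chain uses unnormalized rates mu*pi_j, i.e. the F81
            # chain with beta = 1; rescale t to F81's calibrated clock
            P4 = f81_transition_matrix(f81, t / f81.beta)
            want = np.kron(P4, P4)
            assert np.allclose(P16, want, atol=1e-10)

    def test_acceptance_ordering_enforced(self):
        with pytest.raises(ValueError):
            PairFitnessModel(acceptance_gu=0.1, acceptance_mismatch=0.5)
        PairFitnessModel(acceptance_gu=0.1, acceptance_mismatch=0.5,
                         allow_unordered=True)

    def test_mismatch_monotonicity(self):
        # larger m -> larger entry rates into mismatch pairs
        lo = build_pair_rate_matrix(PairFitnessModel(acceptance_mismatch=.01))
        hi = build_pair_rate_matrix(PairFitnessModel(acceptance_mismatch=.2))
        assert hi[code("AU"), code("AC")] > lo[code("AU"), code("AC")]
        assert hi[code("AU"), code("GU")] == lo[code("AU"), code("GU")]


class TestJumpChain:
    def test_zero_rate_freezes_states(self, ladder_tree):
        m = PairFitnessModel(mutation_rate=0.0)
        states, events = simulate_pair_evolution(ladder_tree, 10, m, seed=1)
        assert events == []
        assert np.all(states == states[0])

    def test_events_replay_to_node_states(self, ladder_tree):
        m = PairFitnessModel(mutation_rate=30.0)   # force many events
        states, events = simulate_pair_evolution(ladder_tree, 6, m, seed=7)
        # replay: start from each node's parent state, apply its branch
        # events in positional order
        by_branch = {}
        for (pidx, node, pos, old, new) in events:
            by_branch.setdefault(node, []).append((pos, pidx, old, new))
        for node in range(1, ladder_tree.n_nodes):
            s = states[ladder_tree.parent[node]].copy()
            for pos, pidx, old, new in sorted(by_branch.get(node, [])):
                assert s[pidx] == old
                assert 0.0 <= pos <= float(ladder_tree.blen[node])
                s[pidx] = new
            assert np.array_equal(s, states[node])

    def test_m_zero_confines_to_wc_and_wobble(self, ladder_tree):
        m = PairFitnessModel(mutation_rate=20.0, acceptance_gu=0.5,
                             acceptance_mismatch=0.0)
        states, events = simulate_pair_evolution(
            ladder_tree, 50, m, root_composition={"AU": 1.0}, seed=3)
        allowed = set(WC_CODES) | {GU, UG}
        assert set(np.unique(states)) <= allowed
        assert len(events) > 0
        # every AU<>GC switch in this regime must show a wobble intermediate
        for (pidx, node, pos, old, new) in events:
            assert new in allowed

    def test_seed_reproducible(self, five_leaf_tree):
        m = PairFitnessModel(mutation_rate=5.0)
        a = simulate_pair_evolution(five_leaf_tree, 8, m, seed=11)
        b = simulate_pair_evolution(five_leaf_tree, 8, m, seed=11)
        assert np.array_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_root_composition_respected(self, cherry_tree):
        states, _ = simulate_pair_evolution(
            cherry_tree, 200, PairFitnessModel(mutation_rate=0.0),
            root_composition={"GC": 0.5, "CG": 0.5}, seed=5)
        assert set(pair_string(int(s)) for s in states[0]) <= {"GC", "CG"}


class TestYule:
    def test_shape_and_determinism(self):
        t1 = simulate_yule_tree(25, 0.2, seed=4)
        t2 = simulate_yule_tree(25, 0.2, seed=4)
        assert t1.to_newick() == t2.to_newick()
        assert len(t1.leaves) == 25
        assert t1.n_nodes == 2 * 25 - 1      # binary rooted
        assert simulate_yule_tree(25, 0.2, seed=5).to_newick() != \
            t1.to_newick()

    def test_ultrametric_with_requested_depth(self):
        t = simulate_yule_tree(12, 0.37, seed=9)
        depths = t.dist_root[t.leaves]
        assert np.allclose(depths, 0.37)
        assert np.all(t.blen[1:] > 0)

    @given(n=st.integers(2, 30), seed=st.integers(0, 50))
    def test_parent_indices_preorder(self, n, seed):
        t = simulate_yule_tree(n, 0.1, seed=seed)
        assert t.parent[0] == -1
        assert all(t.parent[i] < i for i in range(1, t.n_nodes))

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            simulate_yule_tree(1, 0.1, seed=0)
        with pytest.raises(ValueError):
            simulate_yule_tree(5, 0.0, seed=0)


class TestDataset:
    def test_deterministic_output(self, tmp_path):
        d1 = generate_dataset(SimulationConfig(n_strains=8, n_genes=6),
                              seed=42)
        d2 = generate_dataset(SimulationConfig(n_strains=8, n_genes=6),
                              seed=42)
        assert d1.tree.to_newick() == d2.tree.to_newick()
        for a1, a2 in zip(d1.alignments, d2.alignments):
            assert a1.gene_id == a2.gene_id
            assert a1.sequences == a2.sequences
        assert d1.true_events == d2.true_events
        out1, out2 = tmp_path / "r1", tmp_path / "r2"
        d1.write(str(out1))
        d2.write(str(out2))
        for rel in ("tree.nwk", "structures.tsv", "events.tsv",
                    "manifest.tsv"):
            assert (out1 / rel).read_bytes() == (out2 / rel).read_bytes()

    def test_alignments_cover_strains(self):
        d = generate_dataset(SimulationConfig(n_strains=10, n_genes=5),
                             seed=1)
        for aln in d.alignments:
            assert len(aln.sequences) == 10
            L = {len(s) for s in aln.sequences.values()}
            assert len(L) == 1

    def test_truth_matches_leaf_sequences(self):
        from termswitch.ancestral import NUCLEOTIDES
        d = generate_dataset(SimulationConfig(n_strains=6, n_genes=4),
                             seed=3)
        for aln in d.alignments:
            mat = d.truth[aln.gene_id]
            for i in d.tree.leaves:
                want = "".join(NUCLEOTIDES[c] for c in mat[i])
                assert aln.sequences[d.tree.names[i]] == want

    def test_events_only_touch_stem_columns(self):
        d = generate_dataset(SimulationConfig(n_strains=6, n_genes=4),
                             seed=8)
        for aln in d.alignments:
            stem_cols = {c for lr in aln.structure.pairs for c in lr}
            for e in d.true_events:
                if e.gene_id == aln.gene_id:
                    assert e.column in stem_cols

    def test_annotation_table_layout(self):
        d = generate_dataset(SimulationConfig(n_strains=5, n_genes=10),
                             seed=2)
        ann = d.annotations
        assert list(ann.columns) == ["gene_id", "start", "end", "strand",
                                     "term_start", "term_end"]
        assert len(ann) == 10
        with_term = ann[ann.term_start >= 0]
        assert (with_term.term_end > with_term.term_start).all()
        # genes whose terminator column is -1 have no alignment
        missing = set(ann[ann.term_start < 0].gene_id)
        present = {a.gene_id for a in d.alignments}
        assert missing.isdisjoint(present)

    def test_stem_variability_near_nine_percent(self):
        # default depth calibration: realized fraction of variable
        # interacting columns over 500 genes should sit within 3
        # percentage points of 8.2%
        d = generate_dataset(SimulationConfig(n_strains=25, n_genes=500),
                             seed=0)
        variable = total = 0
        for aln in d.alignments:
            mat = d.truth[aln.gene_id]
            leaf_rows = mat[d.tree.leaves]
            for l, r in aln.structure.pairs:
                for c in (l, r):
                    total += 1
                    variable += len(np.unique(leaf_rows[:, c])) > 1
        frac = variable / total
        assert abs(frac - 0.082) < 0.03

    def test_neutral_regime_generates_mismatch_states(self):
        cfg = SimulationConfig(
            n_strains=12, n_genes=20,
            model=PairFitnessModel(acceptance_gu=1.0,
                                   acceptance_mismatch=1.0),
            root_composition={pair_string(s): 1 / 16 for s in range(16)})
        d = generate_dataset(cfg, seed=6)
        seen = set()
        for gid, mat in d.truth.items():
            aln = d.alignment(gid)
            for l, r in aln.structure.pairs:
                for row in mat[d.tree.leaves]:
                    seen.add(pair_string(int(row[l] * 4 + row[r])))
        # with no pairing selection every pair state should be reachable
        assert len(seen) == 16
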