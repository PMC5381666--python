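"""Synthetic terminator evolution with known ground truth.

Simulates a strain phylogeny (Yule), then evolves each terminator's stem
as paired dinucleotide columns under a 16-state continuous-time Markov
chain in which only single-nucleotide changes occur and the rate of a
change is scaled by the acceptance of the *resulting* pair: Watson-Crick
pairs are accepted at 1, GU/UG wobble pairs at ``g`` and all other
(mismatch) pairs at ``m`` (the selection ranking WC > GU > mismatch).
Stems are simulated with an exact jump chain so every intermediate visit
and its branch position is recorded; loops, poly-U tracts and flanks
evolve as independent neutral F81 columns. No indels are simulated.

Defaults emulate the study conditions: 25 strains, stems of 5-19 pairs,
ancestral pair composition ~43.6% AU / 52.4% GC / 4% GU, and a tree depth
(0.2 mean root-to-tip) calibrated so that roughly 9% of stem columns are
variable, as in closely related bacterial strain panels.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from ._tree import IndexedTree
from .ancestral import NUCLEOTIDES, SubstitutionModel, f81_transition_matrix
from .alignment import TerminatorAlignment
from .structure import StemStructure
from .switches import WC_CODES, GU, UG, pair_string, pair_code

__all__ = [
    "PairFitnessModel", "SimulationConfig", "SimEvent", "SimulatedDataset",
    "simulate_yule_tree", "build_pair_rate_matrix", "simulate_pair_evolution",
    "simulate_neutral_columns", "generate_dataset",
    "DEFAULT_ROOT_COMPOSITION",
]

# ancestral stem-pair composition, strand-symmetrized halves of
# AU 43.58% / GC 52.37% / GU 4.02% (renormalized)
DEFAULT_ROOT_COMPOSITION: Mapping[str, float] = {
    "AU": 0.4358 / 2, "UA": 0.4358 / 2,
    "GC": 0.5237 / 2, "CG": 0.5237 / 2,
    "GU": 0.0402 / 2, "UG": 0.0402 / 2,
}


@dataclass(frozen=True)
class PairFitnessModel:
    """Mutation and acceptance parameters of the paired-site chain."""

    mutation_rate: float = 1.0
    base_frequencies: tuple[float, float, float, float] = (.25, .25, .25, .25)
    acceptance_wc: float = 1.0
    acceptance_gu: float = 0.3
    acceptance_mismatch: float = 0.01
    allow_unordered: bool = False     # lift the m <= g <= 1 check

    def __post_init__(self):
        pi = np.asarray(self.base_frequencies, float)
        if abs(pi.sum() - 1.0) > 1e-8 or np.any(pi < 0):
            raise ValueError("base_frequencies must be a distribution")
        if not self.allow_unordered:
            if not (0.0 <= self.acceptance_mismatch
                    <= self.acceptance_gu <= 1.0):
                raise ValueError(
                    "expected 0 <= m <= g <= 1 (pass allow_unordered=True "
                    "to override)")

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.base_frequencies, float)


@dataclass(frozen=True)
class SimEvent:
    """One recorded substitution in the simulated history."""

    gene_id: str
    column: int                # alignment column of the changed nucleotide
    branch: str                # child-node name of the carrying branch
    position: float            # distance from the branch's parent end
    from_state: str
    to_state: str
    pair_from: str = ""        # joint pair states, for stem columns
    pair_to: str = ""


def simulate_yule_tree(n_taxa: int, depth: float, seed: int) -> IndexedTree:
    """Ultrametric rooted binary Yule tree, scaled to the given mean
    root-to-tip path length (expected substitutions/site).

    Leaves are renamed s01..sNN in preorder for stable downstream naming.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    # pure-birth process: the root splits at time 0; with k lineages the
    # next split comes after Exp(k); after the (n-1)th split the process
    # runs one more Exp(n) interval to the present, so no pendant edge has
    # zero length and the tree is exactly ultrametric
    parent = [-1, 0, 0]
    birth = [0.0, 0.0, 0.0]
    split = [0.0, None, None]         # split time; None while a tip
    active = [1, 2]
    t = 0.0
    while len(active) < n_taxa:
        t += rng.exponential(1.0 / len(active))
        node = active.pop(int(rng.integers(len(active))))
        split[node] = t
        for _ in range(2):
            parent.append(node)
            birth.append(t)
            split.append(None)
            active.append(len(parent) - 1)
    t_end = t + rng.exponential(1.0 / n_taxa)
    n_nodes = len(parent)
    blen = [0.0] * n_nodes
    names = [""] * n_nodes
    k = 0
    for i in range(n_nodes):
        end = split[i] if split[i] is not None else t_end
        blen[i] = 0.0 if i == 0 else end - birth[i]
        if split[i] is None:
            k += 1
            names[i] = f"s{k:02d}"
        else:
            names[i] = f"N{i}"
    tree = IndexedTree(parent, blen, names)
    mean_depth = float(np.mean(tree.dist_root[tree.leaves]))
    return IndexedTree(parent, tree.blen * (depth / mean_depth), names)


def _acceptance(code: int, model: PairFitnessModel) -> float:
    if code in WC_CODES:
        return model.acceptance_wc
    if code in (GU, UG):
        return model.acceptance_gu
    return model.acceptance_mismatch


def build_pair_rate_matrix(model: PairFitnessModel) -> np.ndarray:
    """16x16 rate matrix over dinucleotide states (code = 4*left+right).

    Off-diagonal rate for a single-nucleotide change is mutation_rate x
    target-base frequency x acceptance of the resulting pair; simultaneous
    double changes have rate 0; diagonals make rows sum to zero.
    """
    pi = model.pi
    Q = np.zeros((16, 16))
    for s in range(16):
        l, r = s // 4, s % 4
        for j in range(4):
            if j != l:
                t = j * 4 + r
                Q[s, t] = model.mutation_rate * pi[j] * _acceptance(t, model)
            if j != r:
                t = l * 4 + j
                Q[s, t] = model.mutation_rate * pi[j] * _acceptance(t, model)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def _composition_vector(root_composition: Mapping[str, float]) -> np.ndarray:
    p = np.zeros(16)
    for k, v in root_composition.items():
        p[pair_code(k)] = v
    if p.sum() <= 0:
        raise ValueError("empty root composition")
    return p / p.sum()


def simulate_pair_evolution(tree: IndexedTree, n_pairs: int,
                            model: PairFitnessModel,
                            root_composition: Mapping[str, float] | None = None,
                            seed: int | None = None,
                            rng: np.random.Generator | None = None
                            ) -> tuple[np.ndarray, list[tuple]]:
    """Exact jump-chain simulation of paired columns on a tree.

    Returns (states (n_nodes, n_pairs) int codes; raw events as tuples
    (pair_index, child_node, position_on_branch, from_code, to_code)).
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    if root_composition is None:
        root_composition = DEFAULT_ROOT_COMPOSITION
    Q = build_pair_rate_matrix(model)
    rates = -np.diag(Q)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump = np.where(rates[:, None] > 0, Q / rates[:, None], 0.0)
    np.fill_diagonal(jump, 0.0)
    jump_cum = np.cumsum(jump, axis=1)
    p0 = _composition_vector(root_composition)
    states = np.empty((tree.n_nodes, n_pairs), dtype=np.int64)
    states[0] = rng.choice(16, size=n_pairs, p=p0)
    events: list[tuple] = []
    for node in range(1, tree.n_nodes):
        t = float(tree.blen[node])
        s = states[tree.parent[node]].copy()
        elapsed = np.zeros(n_pairs)
        r = rates[s]
        with np.errstate(divide="ignore"):
            wait = np.where(r > 0, rng.exponential(1.0, n_pairs) /
                            np.where(r > 0, r, 1.0), np.inf)
        tnext = elapsed + wait
        active = np.flatnonzero(tnext < t)
        while active.size:
            for idx in active:
                pos = tnext[idx]
                old = s[idx]
                u = rng.random()
                new = int(np.searchsorted(jump_cum[old], u))
                events.append((int(idx), node, float(pos), int(old), new))
                s[idx] = new
                elapsed[idx] = pos
                rr = rates[new]
                tnext[idx] = pos + (rng.exponential() / rr if rr > 0
                                    else np.inf)
            active = active[tnext[active] < t]
        states[node] = s
    return states, events


def simulate_neutral_columns(tree: IndexedTree, n_cols: int,
                             model: SubstitutionModel,
                             rng: np.random.Generator,
                             root_states: np.ndarray | None = None
                             ) -> np.ndarray:
    """Independent F81 columns sampled node-by-node down the tree."""
    states = np.empty((tree.n_nodes, n_cols), dtype=np.int64)
    if root_states is None:
        states[0] = rng.choice(4, size=n_cols, p=model.pi)
    else:
        states[0] = root_states
    for node in range(1, tree.n_nodes):
        P = f81_transition_matrix(model, float(tree.blen[node]))
        cum = np.cumsum(P, axis=1)
        u = rng.random(n_cols)
        ps = states[tree.parent[node]]
        states[node] = (u[:, None] > cum[ps]).sum(axis=1)
    return states


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic dataset (defaults = study conditions)."""

    n_strains: int = 25
    n_genes: int = 100
    # mean root-to-tip depth in neutral substitutions/site; 0.2 makes
    # ~9% of stem columns variable under the default selection model,
    # matching closely related bacterial strain panels
    depth: float = 0.2
    stem_pairs: tuple[int, int] = (5, 19)      # inclusive range
    loop_len: tuple[int, int] = (3, 8)
    polyU_len: tuple[int, int] = (6, 9)
    flank_len: int = 3
    model: PairFitnessModel = field(default_factory=PairFitnessModel)
    root_composition: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROOT_COMPOSITION))
    # gene-pair layout fractions (per consecutive gene pair)
    frac_convergent: float = 0.35
    frac_divergent: float = 0.15
    frac_coinciding: float = 0.5       # among convergent pairs
    frac_single_terminator: float = 0.2  # among non-coinciding convergent
    gene_length: int = 600

    def __post_init__(self):
        if self.n_genes < 1:
            raise ValueError("n_genes must be >= 1")
        if self.n_strains < 2:
            raise ValueError("n_strains must be >= 2")


@dataclass
class SimulatedDataset:
    """Tree, alignments, truth states/events, and gene annotations."""

    tree: IndexedTree
    alignments: list[TerminatorAlignment]
    truth: dict[str, np.ndarray]          # gene -> (n_nodes, L) nt codes
    true_events: list[SimEvent]
    annotations: pd.DataFrame
    config: SimulationConfig
    seed: int

    def alignment(self, gene_id: str) -> TerminatorAlignment:
        for a in self.alignments:
            if a.gene_id == gene_id:
                return a
        raise KeyError(gene_id)

    def write(self, outdir: str) -> None:
        """Write every external-interface file (newick, FASTA, manifest,
        structures, truth and event TSVs, annotation TSV)."""
        import os
        os.makedirs(os.path.join(outdir, "alignments"), exist_ok=True)
        with open(os.path.join(outdir, "tree.nwk"), "w") as fh:
            fh.write(self.tree.to_newick() + "\n")
        man = []
        with open(os.path.join(outdir, "structures.tsv"), "w") as sfh:
            for aln in self.alignments:
                fname = f"alignments/{aln.gene_id}.fasta"
                with open(os.path.join(outdir, fname), "w") as fh:
                    for strain, seq in aln.sequences.items():
                        fh.write(f">{strain}\n{seq}\n")
                man.append((aln.gene_id, fname, aln.reference_strain))
                pu = aln.structure.polyU_span
                pu_txt = f"{pu[0]}:{pu[1]}" if pu else "-"
                sfh.write(f"{aln.gene_id}\t{aln.structure.to_dot_bracket()}"
                          f"\t{aln.ungapped_reference}\t{pu_txt}\n")
        with open(os.path.join(outdir, "manifest.tsv"), "w") as fh:
            fh.write("gene_id\tfile\treference_strain\n")
            for row in man:
                fh.write("\t".join(row) + "\n")
        with open(os.path.join(outdir, "truth_states.tsv"), "w") as fh:
            fh.write("gene_id\tnode\tcolumn\tstate\n")
            for gene, mat in self.truth.items():
                for i in range(mat.shape[0]):
                    name = self.tree.names[i]
                    for c in range(mat.shape[1]):
                        fh.write(f"{gene}\t{name}\t{c}\t"
                                 f"{NUCLEOTIDES[mat[i, c]]}\n")
        with open(os.path.join(outdir, "events.tsv"), "w") as fh:
            fh.write("gene_id\tcolumn\tbranch\tposition\tfrom\tto\t"
                     "pair_from\tpair_to\n")
            for e in self.true_events:
                fh.write(f"{e.gene_id}\t{e.column}\t{e.branch}\t"
                         f"{e.position:.6g}\t{e.from_state}\t{e.to_state}\t"
                         f"{e.pair_from}\t{e.pair_to}\n")
        self.annotations.to_csv(os.path.join(outdir, "annotations.tsv"),
                                sep="\t", index=False)


_COMPLEMENT = np.array([3, 2, 1, 0])     # A<->U, C<->G


def _mirror_gene(states: np.ndarray, structure: StemStructure
                 ) -> tuple[np.ndarray, StemStructure]:
    """Reverse-complement a gene's truth matrix and mirror its structure."""
    L = states.shape[1]
    rc = _COMPLEMENT[states][:, ::-1]
    pairs = tuple(sorted((L - 1 - r, L - 1 - l) for l, r in structure.pairs))
    lo, hi = structure.loop_span
    return rc, StemStructure(pairs=pairs, loop_span=(L - hi, L - lo),
                             length=L, polyU_span=None)


def _gene_truth(tree: IndexedTree, cfg: SimulationConfig,
                rng: np.random.Generator, gene_id: str
                ) -> tuple[np.ndarray, StemStructure, list[SimEvent]]:
    """Simulate one terminator: stem pairs + neutral loop/polyU/flanks."""
    k = int(rng.integers(cfg.stem_pairs[0], cfg.stem_pairs[1] + 1))
    loop = int(rng.integers(cfg.loop_len[0], cfg.loop_len[1] + 1))
    pu = int(rng.integers(cfg.polyU_len[0], cfg.polyU_len[1] + 1))
    fl = cfg.flank_len
    L = fl + 2 * k + loop + pu + fl
    pairs = tuple((fl + i, fl + k + loop + (k - 1 - i)) for i in range(k))
    structure = StemStructure(
        pairs=pairs, loop_span=(fl + k, fl + k + loop), length=L,
        polyU_span=(fl + 2 * k + loop, fl + 2 * k + loop + pu))
    pair_states, raw_events = simulate_pair_evolution(
        tree, k, cfg.model, cfg.root_composition, rng=rng)
    neutral_model = SubstitutionModel(
        name="F81", base_frequencies=tuple(cfg.model.pi))
    n_neutral = L - 2 * k
    roots = rng.choice(4, size=n_neutral, p=neutral_model.pi)
    # poly-U root is a U run
    neutral_cols = ([*range(0, fl)], [*range(fl + k, fl + k + loop)],
                    [*range(fl + 2 * k + loop, L)])
    flat_neutral = [c for grp in neutral_cols for c in grp]
    pu_offset = fl + loop
    roots[pu_offset:pu_offset + pu] = 3          # U
    neutral_states = simulate_neutral_columns(
        tree, n_neutral, neutral_model, rng, root_states=roots)
    states = np.empty((tree.n_nodes, L), dtype=np.int64)
    for i, (l, r) in enumerate(pairs):
        states[:, l] = pair_states[:, i] // 4
        states[:, r] = pair_states[:, i] % 4
    for j, c in enumerate(flat_neutral):
        states[:, c] = neutral_states[:, j]
    events = []
    for (pidx, node, pos, old, new) in raw_events:
        l, r = pairs[pidx]
        col = l if old // 4 != new // 4 else r
        f = old // 4 if col == l else old % 4
        t = new // 4 if col == l else new % 4
        events.append(SimEvent(
            gene_id=gene_id, column=col, branch=tree.names[node],
            position=pos, from_state=NUCLEOTIDES[f], to_state=NUCLEOTIDES[t],
            pair_from=pair_string(old), pair_to=pair_string(new)))
    return states, structure, events


def _leaf_sequences(tree: IndexedTree, states: np.ndarray) -> dict[str, str]:
    return {tree.names[i]: "".join(NUCLEOTIDES[c] for c in states[i])
            for i in tree.leaves}


def generate_dataset(config: SimulationConfig | None = None,
                     seed: int = 0) -> SimulatedDataset:
    """Build a full synthetic dataset with ground truth.

    A single master seed drives a per-gene substream (so any gene is
    reproducible in isolation) plus one stream for the tree and the gene
    layout. Fixed seed => byte-identical output.
    """
    cfg = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    streams = ss.spawn(cfg.n_genes + 1)
    layout_rng = np.random.default_rng(streams[-1])
    tree = simulate_yule_tree(cfg.n_strains, cfg.depth,
                              seed=int(ss.generate_state(1)[0] % (2**31)))
    ref = tree.names[int(tree.leaves[0])]

    alignments: list[TerminatorAlignment] = []
    truth: dict[str, np.ndarray] = {}
    events: list[SimEvent] = []
    ann_rows = []

    # gene-pair layout: draw an adjacency class per consecutive pair
    pair_classes = []
    i = 0
    while i + 1 < cfg.n_genes:
        u = layout_rng.random()
        if u < cfg.frac_convergent:
            v = layout_rng.random()
            if v < cfg.frac_coinciding:
                cls = "conv_coinciding"
            elif v < cfg.frac_coinciding + (1 - cfg.frac_coinciding) * \
                    cfg.frac_single_terminator:
                w = layout_rng.random()
                cls = ("conv_single_far" if w < 0.2 else
                       "conv_single_inside" if w < 0.3 else "conv_single")
            else:
                cls = "conv_both"
        elif u < cfg.frac_convergent + cfg.frac_divergent:
            cls = "divergent"
        else:
            cls = "cooriented"
        pair_classes.append(cls)
        i += 2
    leftover = (cfg.n_genes % 2) == 1

    SEG = 2600
    gidx = 0

    for p, cls in enumerate(pair_classes):
        base = p * SEG
        rng_a = np.random.default_rng(streams[2 * p])
        rng_b = np.random.default_rng(streams[2 * p + 1])
        gid_a = f"g{gidx:04d}"
        st_a, struct_a, ev_a = _gene_truth(tree, cfg, rng_a, gid_a)
        gidx += 1
        gid_b = f"g{gidx:04d}"
        gidx += 1
        len_a = st_a.shape[1]
        a0, a1 = base + 100, base + 100 + cfg.gene_length
        aln_a = TerminatorAlignment.from_structure(
            gid_a, _leaf_sequences(tree, st_a), ref, struct_a)
        if cls == "divergent":
            strand_a, strand_b = "-", "+"
        elif cls == "cooriented":
            strand_a, strand_b = "+", "+"
        else:
            strand_a, strand_b = "+", "-"

        if cls == "conv_coinciding":
            # one shared physical terminator, seen revcomp by gene B
            st_b, struct_b = _mirror_gene(st_a, struct_a)
            ev_b = []
            aln_b = TerminatorAlignment.from_structure(
                gid_b, _leaf_sequences(tree, st_b), ref, struct_b)
            term_a = (a1 + 10, a1 + 10 + len_a)
            term_b = term_a
            b0, b1 = term_a[1] + 10, term_a[1] + 10 + cfg.gene_length
        else:
            st_b, struct_b, ev_b = _gene_truth(tree, cfg, rng_b, gid_b)
            len_b = st_b.shape[1]
            aln_b = TerminatorAlignment.from_structure(
                gid_b, _leaf_sequences(tree, st_b), ref, struct_b)
            if cls == "cooriented":
                b0 = a1 + 300
                b1 = b0 + cfg.gene_length
                term_a = (a1 + 10, a1 + 10 + len_a)
                term_b = (b1 + 10, b1 + 10 + len_b)
            elif cls == "divergent":
                b0 = a1 + 300
                b1 = b0 + cfg.gene_length
                term_a = (a0 - 10 - len_a, a0 - 10)
                term_b = (b1 + 10, b1 + 10 + len_b)
            elif cls == "conv_both":
                b0 = a1 + 300
                b1 = b0 + cfg.gene_length
                term_a = (a1 + 10, a1 + 10 + len_a)
                term_b = (b0 - 10 - len_b, b0 - 10)
            elif cls == "conv_single":
                b0 = a1 + 120
                b1 = b0 + cfg.gene_length
                term_a = (a1 + 10, a1 + 10 + len_a)
                term_b = None
            elif cls == "conv_single_far":
                b0 = a1 + 600
                b1 = b0 + cfg.gene_length
                term_a = (a1 + 10, a1 + 10 + len_a)
                term_b = None
            else:  # conv_single_inside: A's terminator inside gene B
                b0 = a1 + 60
                b1 = b0 + cfg.gene_length
                term_a = (b0 + 50, b0 + 50 + len_a)
                term_b = None

        for gid, st, aln, ev, strand, g0, g1, term in (
                (gid_a, st_a, aln_a, ev_a, strand_a, a0, a1, term_a),
                (gid_b, st_b, aln_b, ev_b, strand_b, b0, b1, term_b)):
            keep_aln = not (term is None)
            if keep_aln:
                alignments.append(aln)
                truth[gid] = st
                events.extend(ev)
            ann_rows.append(dict(
                gene_id=gid, start=g0, end=g1, strand=strand,
                term_start=term[0] if term else -1,
                term_end=term[1] if term else -1))

    if leftover:
        base = len(pair_classes) * SEG
        rng = np.random.default_rng(streams[cfg.n_genes - 1])
        gid = f"g{gidx:04d}"
        st, struct, ev = _gene_truth(tree, cfg, rng, gid)
        gidx += 1
        aln = TerminatorAlignment.from_structure(
            gid, _leaf_sequences(tree, st), ref, struct)
        alignments.append(aln)
        truth[gid] = st
        events.extend(ev)
        g0, g1 = base + 100, base + 100 + cfg.gene_length
        ann_rows.append(dict(gene_id=gid, start=g0, end=g1, strand="+",
                             term_start=g1 + 10,
                             term_end=g1 + 10 + st.shape[1]))

    annotations = pd.DataFrame(
        ann_rows, columns=["gene_id", "start", "end", "strand",
                           "term_start", "term_end"])
    return SimulatedDataset(tree=tree, alignments=alignments, truth=truth,
                            true_events=events, annotations=annotations,
                            config=cfg, seed=seed)
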