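"""Marginal ancestral state reconstruction under F81 / JC.

Felsenstein's pruning algorithm on a fixed rooted tree with its input
branch lengths, followed by an outside pass that yields per-node marginal
posteriors. A node is resolved to its maximum-posterior nucleotide when
that posterior reaches the resolvability threshold (default 0.8);
otherwise it is UNRESOLVED. Substitutions are mapped onto branches whose
two endpoint states are both resolved and differ.

F81 closed form: P(i->j; t) = e^{-beta t} [i=j] + (1 - e^{-beta t}) pi_j,
with beta = 1/(1 - sum pi^2) so that t is in expected substitutions/site.
JC is the uniform-frequency special case.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from ._tree import IndexedTree

__all__ = [
    "NUCLEOTIDES", "UNRESOLVED", "SubstitutionModel",
    "AncestralReconstruction", "BranchEvent",
    "f81_transition_matrix", "column_likelihood", "marginal_posteriors",
    "reconstruct_columns", "map_substitutions", "encode_state",
    "empirical_frequencies", "GeneReconstruction", "reconstruct_alignment",
]

NUCLEOTIDES = "ACGU"
NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}
UNRESOLVED = -1


def encode_state(ch: str) -> int:
    """A/C/G/U -> 0..3; gaps and ambiguity codes -> -1 (missing)."""
    return NT_INDEX.get(ch.upper().replace("T", "U"), -1)


@dataclass(frozen=True)
class SubstitutionModel:
    """F81 (arbitrary stationary frequencies) or its JC special case."""

    name: str = "F81"
    base_frequencies: tuple[float, float, float, float] = (.25, .25, .25, .25)

    def __post_init__(self):
        pi = np.asarray(self.base_frequencies, dtype=float)
        if pi.shape != (4,) or np.any(pi <= 0):
            raise ValueError("base_frequencies must be 4 positive values")
        if abs(pi.sum() - 1.0) > 1e-8:
            raise ValueError("base_frequencies must sum to 1")
        if self.name == "JC" and np.max(np.abs(pi - 0.25)) > 1e-12:
            raise ValueError("JC requires uniform frequencies")
        if self.name not in ("F81", "JC"):
            raise ValueError(f"unknown model {self.name!r}")

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.base_frequencies, dtype=float)

    @property
    def beta(self) -> float:
        pi = self.pi
        return 1.0 / (1.0 - float(pi @ pi))

    @classmethod
    def jc(cls) -> "SubstitutionModel":
        return cls(name="JC")


def empirical_frequencies(columns: np.ndarray | Sequence[Sequence[int]],
                          pseudocount: float = 1.0) -> SubstitutionModel:
    """F81 model with frequencies from observed states plus a pseudocount.

    ``columns`` holds encoded states (missing = -1), any shape.
    """
    arr = np.asarray(columns)
    counts = np.array([np.sum(arr == i) for i in range(4)], dtype=float)
    counts += pseudocount
    pi = counts / counts.sum()
    return SubstitutionModel(name="F81", base_frequencies=tuple(pi))


def f81_transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """Row-stochastic 4x4 transition matrix for branch length ``t``."""
    if t < 0:
        raise ValueError("branch length must be non-negative")
    e = np.exp(-model.beta * t)
    return e * np.eye(4) + (1.0 - e) * np.tile(model.pi, (4, 1))


@dataclass
class AncestralReconstruction:
    """Per-node posteriors and resolved states for one alignment column."""

    tree: IndexedTree
    posteriors: np.ndarray            # (n_nodes, 4)
    resolved: np.ndarray              # (n_nodes,) int, -1 = UNRESOLVED
    threshold: float = 0.8
    missing_leaves: frozenset[int] = field(default_factory=frozenset)

    def resolved_state(self, node: int) -> str:
        s = self.resolved[node]
        return NUCLEOTIDES[s] if s >= 0 else "UNRESOLVED"


@dataclass(frozen=True)
class BranchEvent:
    """A substitution mapped to the branch above ``branch`` (child name)."""

    branch: str
    column: int
    from_state: str
    to_state: str


def _leaf_matrix(tree: IndexedTree,
                 leaf_states: Mapping[str, object]) -> np.ndarray:
    """Single-column leaf states -> (1, n_leaves) int array in tree order."""
    states = np.empty((1, len(tree.leaves)), dtype=np.int64)
    for k, i in enumerate(tree.leaves):
        name = tree.names[i]
        if name not in leaf_states:
            raise KeyError(f"leaf {name!r} absent from leaf_states")
        v = leaf_states[name]
        states[0, k] = v if isinstance(v, (int, np.integer)) \
            else encode_state(str(v))
    return states


def _transition_matrices(tree: IndexedTree,
                         model: SubstitutionModel) -> np.ndarray:
    P = np.empty((tree.n_nodes, 4, 4))
    P[0] = np.eye(4)
    for i in range(1, tree.n_nodes):
        P[i] = f81_transition_matrix(model, float(tree.blen[i]))
    return P


def _pruning(tree: IndexedTree, states: np.ndarray, P: np.ndarray):
    """Down (inside) pass, vectorized over columns.

    Returns (down partials D (n_nodes, n_cols, 4); child messages
    C[i] = D[i] @ P[i].T; per-column log rescaling terms).
    """
    n_cols = states.shape[0]
    n = tree.n_nodes
    D = np.empty((n, n_cols, 4))
    C = np.empty((n, n_cols, 4))
    logscale = np.zeros(n_cols)
    leaf_pos = {int(i): k for k, i in enumerate(tree.leaves)}
    for i in tree.postorder:
        if tree.is_leaf[i]:
            s = states[:, leaf_pos[i]]
            d = np.zeros((n_cols, 4))
            obs = s >= 0
            d[obs, s[obs]] = 1.0
            d[~obs] = 1.0
            D[i] = d
        else:
            d = np.ones((n_cols, 4))
            for c in tree.children[i]:
                d = d * C[c]
            mx = d.max(axis=1)
            mx[mx == 0] = 1.0
            D[i] = d / mx[:, None]
            logscale += np.log(mx)
        C[i] = D[i] @ P[i].T
    return D, C, logscale


def column_likelihood(tree: IndexedTree,
                      leaf_states: Mapping[str, object],
                      model: SubstitutionModel) -> float:
    """Felsenstein pruning likelihood of one column.

    Missing leaves (gap/N) contribute all-ones partial vectors; the root
    is weighted by the stationary frequencies.
    """
    states = _leaf_matrix(tree, leaf_states)
    P = _transition_matrices(tree, model)
    D, _, logscale = _pruning(tree, states, P)
    return float(D[0, 0] @ model.pi) * float(np.exp(logscale[0]))


def reconstruct_columns(tree: IndexedTree, states: np.ndarray,
                        model: SubstitutionModel, threshold: float = 0.8
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Marginal posteriors for many columns at once.

    ``states``: (n_cols, n_leaves) encoded leaf states in ``tree.leaves``
    order (-1 = missing). Returns (posteriors (n_cols, n_nodes, 4),
    resolved (n_cols, n_nodes) with -1 for UNRESOLVED). Observed leaves
    are fixed to their observation; missing leaves stay UNRESOLVED.
    """
    n_cols, _ = states.shape
    n = tree.n_nodes
    P = _transition_matrices(tree, model)
    D, C, _ = _pruning(tree, states, P)
    # outside pass: U[i] = message arriving at node i from the rest of
    # the tree (root prior included)
    U = np.empty((n, n_cols, 4))
    U[0] = model.pi
    for p in range(n):
        kids = tree.children[p]
        for c in kids:
            m = U[p].copy()
            for s in kids:
                if s != c:
                    m = m * C[s]
            mx = m.max(axis=1)
            mx[mx == 0] = 1.0
            U[c] = (m / mx[:, None]) @ P[c]
    post = U * D
    tot = post.sum(axis=2, keepdims=True)
    if np.any(tot[:, :, 0] <= 0):
        raise ValueError("zero total likelihood (contradictory states)")
    post = (post / tot).transpose(1, 0, 2)      # (n_cols, n_nodes, 4)
    resolved = np.where(post.max(axis=2) >= threshold,
                        post.argmax(axis=2), UNRESOLVED).astype(np.int64)
    for k, i in enumerate(tree.leaves):
        obs = states[:, k]
        has = obs >= 0
        resolved[has, i] = obs[has]
        resolved[~has, i] = UNRESOLVED
    return post, resolved


def marginal_posteriors(tree: IndexedTree,
                        leaf_states: Mapping[str, object],
                        model: SubstitutionModel,
                        threshold: float = 0.8) -> AncestralReconstruction:
    """Single-column marginal reconstruction with the threshold rule."""
    states = _leaf_matrix(tree, leaf_states)
    post, resolved = reconstruct_columns(tree, states, model, threshold)
    missing = frozenset(int(i) for k, i in enumerate(tree.leaves)
                        if states[0, k] < 0)
    return AncestralReconstruction(tree=tree, posteriors=post[0],
                                   resolved=resolved[0],
                                   threshold=threshold,
                                   missing_leaves=missing)


@dataclass
class GeneReconstruction:
    """All-column reconstruction of one terminator alignment.

    ``resolved`` is (n_columns, n_nodes) with -1 = UNRESOLVED; node 0 is
    the root (the last common ancestor of all strains).
    """

    gene_id: str
    tree: IndexedTree
    model: SubstitutionModel
    posteriors: np.ndarray            # (n_cols, n_nodes, 4)
    resolved: np.ndarray              # (n_cols, n_nodes)
    threshold: float = 0.8


def reconstruct_alignment(tree: IndexedTree, alignment,
                          threshold: float = 0.8,
                          pseudocount: float = 1.0,
                          model: SubstitutionModel | None = None
                          ) -> GeneReconstruction:
    """Reconstruct every column of one terminator alignment.

    Unless a model is given, per-gene F81 frequencies are estimated from
    the stem columns of this alignment (plus the pseudocount). Strains
    absent from the alignment are treated as fully missing.
    """
    n_cols = alignment.length
    leaves = tree.leaves
    states = np.full((n_cols, len(leaves)), -1, dtype=np.int64)
    for k, i in enumerate(leaves):
        seq = alignment.sequences.get(tree.names[i])
        if seq is None:
            continue
        states[:, k] = [encode_state(c) for c in seq]
    if model is None:
        stem_cols = [c for c, cls in enumerate(alignment.region_classes)
                     if cls == "stem"]
        if not stem_cols:
            raise ValueError("alignment has no stem columns")
        model = empirical_frequencies(states[stem_cols], pseudocount)
    post, resolved = reconstruct_columns(tree, states, model, threshold)
    return GeneReconstruction(gene_id=alignment.gene_id, tree=tree,
                              model=model, posteriors=post,
                              resolved=resolved, threshold=threshold)


def map_substitutions(tree: IndexedTree,
                      reconstruction: AncestralReconstruction,
                      column: int = 0) -> list[BranchEvent]:
    """One event per branch whose two resolved endpoint states differ.

    Branches with an UNRESOLVED endpoint yield no event; that uncertainty
    is handled downstream by the switch typing.
    """
    res = reconstruction.resolved
    events = []
    for i in range(1, tree.n_nodes):
        p = tree.parent[i]
        if res[i] >= 0 and res[p] >= 0 and res[i] != res[p]:
            events.append(BranchEvent(branch=tree.names[i], column=column,
                                      from_state=NUCLEOTIDES[res[p]],
                                      to_state=NUCLEOTIDES[res[i]]))
    return events
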