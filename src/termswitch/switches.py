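"""Phylogenetic blocks and Watson-Crick base-pair switches.

For one pair of interacting alignment columns, every tree node carries a
joint dinucleotide state (or UNRESOLVED). A *block* is a maximal connected
set of nodes sharing one resolved joint state; UNRESOLVED nodes belong to
no block and sever connectivity. A *switch* is an unordered pair of blocks
with different WC states (AU/UA/GC/CG) such that, along the unique tree
path between the blocks, each column's state changes exactly once — i.e. a
complete compensatory double substitution.

Switches are classified into five types by whether the last common
ancestor (LCA) of the two blocks is resolved and whether the one-off
non-WC intermediate is observed on the path:

    1  LCA carries a terminal WC state, intermediate never observed
    2  LCA carries the intermediate state
    3  LCA carries a terminal WC state, intermediate observed on the path
    4  LCA unresolved, intermediate never observed
    5  LCA unresolved, intermediate observed on the path

Joint states are encoded as ints 0..15 (4*left + right), -1 = UNRESOLVED.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from ._tree import IndexedTree
from .ancestral import NUCLEOTIDES, UNRESOLVED, AncestralReconstruction

__all__ = [
    "WC_CODES", "Block", "SwitchEvent", "SWITCH_KINDS",
    "pair_code", "pair_string", "switch_kind", "kind_intermediates",
    "joint_states", "identify_blocks", "enumerate_switches",
    "classify_switch", "analyze_pair", "compensation_distance",
    "switch_type_counts",
]

# dinucleotide codes
AU, UA, GC, CG = 3, 12, 9, 6
GU, UG = 11, 14
WC_CODES = frozenset({AU, UA, GC, CG})

SWITCH_KINDS = ("AU<>GC", "AU<>CG", "AU<>UA", "GC<>CG")

# intermediates per strand-symmetrized kind (reported orientation)
_KIND_INTERMEDIATES = {
    "AU<>GC": ("GU", "AC"),
    "AU<>CG": ("AG", "UC"),
    "AU<>UA": ("AA", "UU"),
    "GC<>CG": ("GG", "CC"),
}


def pair_code(dinuc: str) -> int:
    return NUCLEOTIDES.index(dinuc[0]) * 4 + NUCLEOTIDES.index(dinuc[1])


def pair_string(code: int) -> str:
    return NUCLEOTIDES[code // 4] + NUCLEOTIDES[code % 4]


def _swap(code: int) -> int:
    return (code % 4) * 4 + code // 4


_CANONICAL = {
    frozenset({AU, GC}): ("AU<>GC", False), frozenset({UA, CG}): ("AU<>GC", True),
    frozenset({AU, CG}): ("AU<>CG", False), frozenset({UA, GC}): ("AU<>CG", True),
    frozenset({AU, UA}): ("AU<>UA", False),
    frozenset({GC, CG}): ("GC<>CG", False),
}


def switch_kind(state_a: str | int, state_b: str | int) -> str:
    """Strand-symmetrized kind of a WC switch (AU<>GC covers UA<>CG...)."""
    a = state_a if isinstance(state_a, int) else pair_code(state_a)
    b = state_b if isinstance(state_b, int) else pair_code(state_b)
    return _CANONICAL[frozenset({a, b})][0]


def kind_intermediates(kind: str) -> tuple[str, str]:
    """The two possible one-off intermediates of a switch kind."""
    return _KIND_INTERMEDIATES[kind]


def symmetrized_intermediate(state_a: str | int, state_b: str | int,
                             intermediate: str | int) -> str:
    """Report an observed intermediate in its kind's canonical orientation."""
    a = state_a if isinstance(state_a, int) else pair_code(state_a)
    b = state_b if isinstance(state_b, int) else pair_code(state_b)
    m = intermediate if isinstance(intermediate, int) else pair_code(intermediate)
    _, swapped = _CANONICAL[frozenset({a, b})]
    return pair_string(_swap(m) if swapped else m)


@dataclass(frozen=True)
class Block:
    """Maximal connected same-state node group for one column pair."""

    block_id: int
    nodes: tuple[int, ...]
    joint_state: str
    is_wc: bool

    @property
    def root(self) -> int:
        return self.nodes[0]          # shallowest node (preorder first)


@dataclass
class SwitchEvent:
    """A compensatory WC base-pair switch between two blocks."""

    block_a: int
    block_b: int
    state_a: str
    state_b: str
    kind: str
    switch_type: Optional[int] = None
    intermediate: str = "UNKNOWN"
    lca_state: str = "UNRESOLVED"
    event_branches: tuple[Optional[str], Optional[str]] = (None, None)
    gene_id: str = ""
    left_col: int = -1
    right_col: int = -1
    flags: tuple[str, ...] = ()
    # midpoint positions of the two event branches along the block-to-block
    # path (None when a substitution cannot be placed on a single branch)
    _mids: tuple[Optional[float], Optional[float]] = (None, None)
    _branch_nodes: tuple[int, int] = (-1, -1)
    _branch_lens: tuple[float, float] = (0.0, 0.0)


def joint_states(reconstruction_left: AncestralReconstruction,
                 reconstruction_right: AncestralReconstruction) -> np.ndarray:
    """Combine two per-column reconstructions into joint pair states.

    A node is UNRESOLVED (-1) if either column is.
    """
    if reconstruction_left.tree is not reconstruction_right.tree and \
            reconstruction_left.tree.names != reconstruction_right.tree.names:
        raise ValueError("reconstructions are on different trees")
    return joint_state_codes(reconstruction_left.resolved,
                             reconstruction_right.resolved)


def joint_state_codes(left: np.ndarray, right: np.ndarray) -> np.ndarray:
    """Joint codes 4*left+right from two resolved-state arrays (-1 missing)."""
    js = left * 4 + right
    js[(left < 0) | (right < 0)] = UNRESOLVED
    return js


def _block_ids(tree: IndexedTree, jstate) -> tuple[list[int], list[int], list[int]]:
    """Preorder block labelling.

    Returns (bid per node, -1 for unresolved; block state per block;
    block root node per block).
    """
    n = tree.n_nodes
    parent = tree._parent
    if not isinstance(jstate, list):
        jstate = np.asarray(jstate).tolist()
    bid = [-1] * n
    states: list[int] = []
    roots: list[int] = []
    for i in range(n):
        s = jstate[i]
        if s < 0:
            continue
        p = parent[i]
        if p >= 0 and bid[p] >= 0 and jstate[p] == s:
            bid[i] = bid[p]
        else:
            bid[i] = len(states)
            states.append(int(s))
            roots.append(i)
    return bid, states, roots


def identify_blocks(tree: IndexedTree, joint_state_map: np.ndarray
                    ) -> list[Block]:
    """Maximal connected components of resolved nodes sharing a state."""
    bid, states, _ = _block_ids(tree, joint_state_map)
    members: dict[int, list[int]] = {}
    for node, b in enumerate(bid):
        if b >= 0:
            members.setdefault(b, []).append(node)
    return [Block(block_id=b, nodes=tuple(members[b]),
                  joint_state=pair_string(states[b]),
                  is_wc=states[b] in WC_CODES)
            for b in sorted(members)]


def _raw_switches(tree: IndexedTree, jstate) -> list[tuple]:
    """Enumerate and type all switches for one column pair.

    Returns raw tuples
    (block_u, block_v, state_u, state_v, switch_type, intermediate_code,
     lca_code, node_L, node_R, mid_L, mid_R, blen_L, blen_R)
    where node_X is the child node of the branch carrying column X's
    substitution (-1 when not assignable to a single branch) and mid_X its
    midpoint position along the path.
    """
    if not isinstance(jstate, list):
        jstate = np.asarray(jstate).tolist()
    bid, states, roots = _block_ids(tree, jstate)
    wc_blocks = [b for b, s in enumerate(states) if s in WC_CODES]
    if len(wc_blocks) < 2:
        return []
    out = []
    blen = tree._blen
    parent = tree._parent
    for x in range(len(wc_blocks)):
        for y in range(x + 1, len(wc_blocks)):
            u, v = wc_blocks[x], wc_blocks[y]
            su, sv = states[u], states[v]
            if su == sv:
                continue
            path = tree.path(roots[u], roots[v])
            i0 = 0
            while bid[path[i0]] == u:
                i0 += 1
            i1 = len(path) - 1
            while bid[path[i1]] == v:
                i1 -= 1
            seg = path[i0 - 1:i1 + 2]      # boundary_a .. boundary_b
            # cumulative positions along the segment
            cum = [0.0]
            for k in range(1, len(seg)):
                a, b = seg[k - 1], seg[k]
                cum.append(cum[-1] + blen[b if parent[b] == a else a])
            ok = True
            ev_nodes = [-1, -1]
            ev_mids: list[Optional[float]] = [None, None]
            ev_lens = [0.0, 0.0]
            for col in (0, 1):
                va = su // 4 if col == 0 else su % 4
                vb = sv // 4 if col == 0 else sv % 4
                idxs, vals = [], []
                for k, node in enumerate(seg):
                    s = jstate[node]
                    if s < 0:
                        continue
                    val = s // 4 if col == 0 else s % 4
                    idxs.append(k)
                    vals.append(val)
                if any(val not in (va, vb) for val in vals):
                    ok = False
                    break
                changes = [t for t in range(1, len(vals))
                           if vals[t] != vals[t - 1]]
                if len(changes) != 1 or vals[0] != va or vals[-1] != vb:
                    ok = False
                    break
                ku, kv = idxs[changes[0] - 1], idxs[changes[0]]
                if kv == ku + 1:           # adjacent: single branch
                    a, b = seg[ku], seg[kv]
                    child = b if parent[b] == a else a
                    ev_nodes[col] = child
                    ev_mids[col] = (cum[ku] + cum[kv]) / 2.0
                    ev_lens[col] = float(blen[child])
            if not ok:
                continue
            # observed one-off intermediates strictly between the blocks
            iAB = (su // 4) * 4 + sv % 4
            iBA = (sv // 4) * 4 + su % 4
            inter = -1
            for node in seg[1:-1]:
                s = jstate[node]
                if s == iAB or s == iBA:
                    inter = int(s)
                    break
            lca = tree.lca(roots[u], roots[v])
            ls = int(jstate[lca])
            if ls == su or ls == sv:
                stype = 3 if inter >= 0 else 1
            elif ls == iAB or ls == iBA:
                stype = 2
                inter = ls
            elif ls == UNRESOLVED:
                stype = 5 if inter >= 0 else 4
            else:
                raise RuntimeError(
                    f"LCA state {pair_string(ls)} is neither terminal nor "
                    "intermediate: switch enumeration is inconsistent")
            out.append((u, v, su, sv, stype, inter, ls,
                        ev_nodes[0], ev_nodes[1], ev_mids[0], ev_mids[1],
                        ev_lens[0], ev_lens[1]))
    return out


def _event_from_raw(tree: IndexedTree, raw: tuple, typed: bool = True
                    ) -> SwitchEvent:
    (u, v, su, sv, stype, inter, ls, nL, nR, mL, mR, lL, lR) = raw
    ev = SwitchEvent(
        block_a=u, block_b=v,
        state_a=pair_string(su), state_b=pair_string(sv),
        kind=switch_kind(su, sv),
        switch_type=stype if typed else None,
        intermediate=pair_string(inter) if (typed and inter >= 0) else "UNKNOWN",
        lca_state=pair_string(ls) if ls >= 0 else "UNRESOLVED",
        event_branches=(tree.names[nL] if nL >= 0 else None,
                        tree.names[nR] if nR >= 0 else None),
        _mids=(mL, mR), _branch_nodes=(nL, nR), _branch_lens=(lL, lR))
    return ev


def enumerate_switches(blocks: Sequence[Block], tree: IndexedTree,
                       joint_state_map: np.ndarray) -> list[SwitchEvent]:
    """All WC-block pairs separated by one substitution per column.

    ``blocks`` must come from :func:`identify_blocks` on the same state
    map (accepted for interface symmetry; enumeration re-derives the
    labelling). Events are returned untyped.
    """
    return [_event_from_raw(tree, r, typed=False)
            for r in _raw_switches(tree, joint_state_map)]


def classify_switch(event: SwitchEvent, tree: IndexedTree,
                    joint_state_map: np.ndarray) -> SwitchEvent:
    """Assign the 1-5 type (and intermediate / LCA state) to one event."""
    for r in _raw_switches(tree, joint_state_map):
        ev = _event_from_raw(tree, r)
        if (ev.block_a, ev.block_b) == (event.block_a, event.block_b):
            return replace(ev, gene_id=event.gene_id,
                           left_col=event.left_col,
                           right_col=event.right_col)
    raise ValueError("event does not match any enumerated switch")


def analyze_pair(tree: IndexedTree, joint_state_map: np.ndarray,
                 gene_id: str = "", left_col: int = -1, right_col: int = -1
                 ) -> list[SwitchEvent]:
    """Full per-pair analysis: blocks, enumeration, typing, shared flags."""
    events = [_event_from_raw(tree, r)
              for r in _raw_switches(tree, joint_state_map)]
    seen: dict[tuple[int, int], int] = {}
    for ev in events:
        for col, node in enumerate(ev._branch_nodes):
            if node >= 0:
                seen[(col, node)] = seen.get((col, node), 0) + 1
    out = []
    for ev in events:
        flags = tuple(
            ["shared_substitution"]
            if any(node >= 0 and seen[(col, node)] > 1
                   for col, node in enumerate(ev._branch_nodes)) else [])
        out.append(replace(ev, gene_id=gene_id, left_col=left_col,
                           right_col=right_col, flags=flags))
    return out


def compensation_distance(event: SwitchEvent, tree: IndexedTree
                          ) -> Optional[float]:
    """Distance (substitutions/site) between the two substitution branches.

    Measured between branch midpoints along the block-to-block path;
    defined for types 2 and 3 with both substitutions assignable to single
    branches. When both events fall on one branch the convention is half
    that branch's length. Returns None (UNDEFINED) otherwise.
    """
    if event.switch_type not in (2, 3):
        return None
    nL, nR = event._branch_nodes
    if nL < 0 or nR < 0:
        return None
    if nL == nR:
        return event._branch_lens[0] / 2.0
    mL, mR = event._mids
    return abs(mL - mR)


def switch_type_counts(tree: IndexedTree, joint_state_map: np.ndarray
                       ) -> np.ndarray:
    """Counts of switches by type 1..5 for one column pair (fast path)."""
    counts = np.zeros(5, dtype=np.int64)
    for r in _raw_switches(tree, joint_state_map):
        counts[r[4] - 1] += 1
    return counts
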