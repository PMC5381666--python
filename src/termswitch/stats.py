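"""Summary statistics and tests for terminator stem evolution.

Headline quantities: the terminal-to-intermediate ratio TIR = (type-1 +
type-3 switches) / type-2 switches (large values mean both substitutions of
a switch tend to occur in one lineage, i.e. fast compensation); the
intermediate-observation ratio (types 1+4)/(types 2+3+5); per-region
conservation fractions; pair-fate accounting by ancestral pair; positional
variability tables with Fisher tests; the bidirectional-terminator
comparison; and a permutation null built from artificial column pairs that
controls for tree shape.

Exact tests wrap scipy.stats and use the two-sided minimum-likelihood
convention (the p-value sums all outcomes whose point probability does not
exceed the observed one's).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._tree import IndexedTree
from .alignment import TerminatorAlignment, FilterThresholds
from .ancestral import GeneReconstruction
from .structure import classify_stem_positions, COMPLEMENTARY_PAIRS
from .switches import (SWITCH_KINDS, SwitchEvent, pair_string,
                       switch_type_counts, _swap)

__all__ = [
    "SwitchSummary", "PermutationNull", "tir", "intermediate_observed_ratio",
    "tir_by_conservation", "binomial_two_tailed", "fisher_two_tailed",
    "expected_double_fraction", "permutation_null", "conservation_summary",
    "pair_fate_table", "positional_variability", "bidirectional_analysis",
    "compare_compensation_distances", "BidirectionalResult",
]

_WC_SYM = {"AU": "AU", "UA": "AU", "GC": "GC", "CG": "GC",
           "GU": "GU", "UG": "GU"}


# ---------------------------------------------------------------- ratios

def tir(n_type1: int, n_type2: int, n_type3: int) -> float:
    """Terminal-to-intermediate ratio (types 1+3) / type 2.

    Returns +inf when no type-2 switch was observed.
    """
    if min(n_type1, n_type2, n_type3) < 0:
        raise ValueError("counts must be non-negative")
    if n_type2 == 0:
        return math.inf
    return (n_type1 + n_type3) / n_type2


def intermediate_observed_ratio(n_by_type: Sequence[int]) -> float:
    """(types 1+4) / (types 2+3+5): unobserved vs observed intermediates."""
    n1, n2, n3, n4, n5 = n_by_type
    denom = n2 + n3 + n5
    if denom == 0:
        return math.inf
    return (n1 + n4) / denom


@dataclass
class SwitchSummary:
    """Switch counts by type (1-5) and by strand-symmetrized kind."""

    n_by_type: np.ndarray                       # (5,)
    n_by_kind: dict[str, int]
    n_by_kind_and_type: pd.DataFrame            # kinds x types

    @classmethod
    def from_events(cls, events: Sequence[SwitchEvent]) -> "SwitchSummary":
        mat = pd.DataFrame(0, index=list(SWITCH_KINDS),
                           columns=[1, 2, 3, 4, 5])
        for ev in events:
            mat.loc[ev.kind, ev.switch_type] += 1
        return cls(n_by_type=mat.sum(axis=0).to_numpy(),
                   n_by_kind=mat.sum(axis=1).to_dict(),
                   n_by_kind_and_type=mat)

    @property
    def total(self) -> int:
        return int(self.n_by_type.sum())

    @property
    def tir(self) -> float:
        n = self.n_by_type
        return tir(int(n[0]), int(n[1]), int(n[2]))

    @property
    def intermediate_observed_ratio(self) -> float:
        return intermediate_observed_ratio(self.n_by_type)


def tir_by_conservation(events: Sequence[SwitchEvent],
                        max_switches: int = 3) -> dict[str, float]:
    """TIR split by column-pair conservation.

    Pairs carrying at most ``max_switches`` switches form the conserved
    group; pairs with more form the variable group.
    """
    per_pair: dict[tuple, list[SwitchEvent]] = {}
    for ev in events:
        per_pair.setdefault((ev.gene_id, ev.left_col, ev.right_col),
                            []).append(ev)
    out = {}
    for label, keep in (("conserved", True), ("variable", False)):
        ns = [0, 0, 0]
        for evs in per_pair.values():
            if (len(evs) <= max_switches) == keep:
                for ev in evs:
                    if ev.switch_type in (1, 2, 3):
                        ns[ev.switch_type - 1] += 1
        out[label] = tir(*ns)
    return out


# ------------------------------------------------------------ exact tests

def binomial_two_tailed(k: int, n: int, p0: float) -> float:
    """Exact two-sided binomial test, minimum-likelihood convention."""
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 < p0 < 1.0):
        raise ValueError("p0 must be in (0,1)")
    return float(sps.binomtest(k, n, p0, alternative="two-sided").pvalue)


def fisher_two_tailed(table) -> float:
    """Exact conditional two-sided Fisher test on a 2x2 table."""
    arr = np.asarray(table)
    if arr.shape != (2, 2) or np.any(arr < 0):
        raise ValueError("need a non-negative 2x2 table")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def expected_double_fraction(nA_subst: int, nB_subst: int, n_pairs: int,
                             n_observed_double: int) -> tuple[float, float]:
    """Expected both-substituted fraction under independence, with p-value.

    The probability of each side changing is its substituted fraction
    among ancestral pairs; the expectation is their product, tested
    against the observed double count with the exact binomial test.
    """
    if n_pairs == 0:
        raise ValueError("n_pairs must be positive")
    expected = (nA_subst / n_pairs) * (nB_subst / n_pairs)
    if expected <= 0.0:
        p = 1.0 if n_observed_double == 0 else 0.0
    elif expected >= 1.0:
        p = 1.0 if n_observed_double == n_pairs else 0.0
    else:
        p = binomial_two_tailed(n_observed_double, n_pairs, expected)
    return expected, p


def compare_compensation_distances(distances_gu: Sequence[float],
                                   distances_other: Sequence[float]
                                   ) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U (midrank ties) and the two group means."""
    a = np.asarray(distances_gu, float)
    b = np.asarray(distances_other, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both distance lists must be non-empty")
    if np.array_equal(np.sort(a), np.sort(b)):
        p = 1.0
    else:
        method = "exact" if (a.size <= 8 and b.size <= 8 and
                             np.unique(np.r_[a, b]).size == a.size + b.size) \
            else "asymptotic"
        p = float(sps.mannwhitneyu(a, b, alternative="two-sided",
                                   method=method).pvalue)
    return p, float(a.mean()), float(b.mean())


# --------------------------------------------------------- permutations

@dataclass
class PermutationNull:
    """Null distribution from artificial column pairs.

    ``type_counts`` holds per-artificial-pair switch counts by type, one
    row per permutation. A single artificial pair rarely defines the TIR
    or the intermediate-observation ratio, so the ratio null samples are
    built at dataset scale: each of ``n_samples`` bootstrap batches draws
    ``batch_size`` artificial pairs (with replacement) from the
    permutation rows — ``batch_size`` defaulting to the observed number
    of real column pairs so a batch mimics one dataset — sums their type
    counts and evaluates the ratios. Batches where a statistic is
    undefined are dropped and counted separately.
    """

    n_permutations: int
    seed: int
    type_counts: np.ndarray               # (n_permutations, 5)
    batch_size: int
    n_samples: int
    tir_samples: np.ndarray
    ratio_samples: np.ndarray
    n_undefined_tir: int
    n_undefined_ratio: int
    percentile_bounds: tuple[float, float] = (2.5, 97.5)

    @property
    def mean_counts_per_pair(self) -> np.ndarray:
        return self.type_counts.mean(axis=0)

    def expected_counts(self, n_pairs: int) -> np.ndarray:
        """Expected type counts for a dataset of ``n_pairs`` column pairs."""
        return self.mean_counts_per_pair * n_pairs

    @property
    def expected_tir(self) -> float:
        e = self.mean_counts_per_pair
        return math.inf if e[1] == 0 else (e[0] + e[2]) / e[1]

    @property
    def expected_ratio(self) -> float:
        e = self.mean_counts_per_pair
        d = e[1] + e[2] + e[4]
        return math.inf if d == 0 else (e[0] + e[3]) / d

    def interval(self, statistic: str) -> tuple[float, float]:
        samples = {"tir": self.tir_samples,
                   "ratio": self.ratio_samples}[statistic]
        if samples.size == 0:
            return (math.nan, math.nan)
        lo, hi = self.percentile_bounds
        # order statistics, not interpolation: samples may contain +inf
        # (batches with no type-2 switch), and interpolating between an
        # infinite and a finite sample is undefined
        return (float(np.percentile(samples, lo, method="lower")),
                float(np.percentile(samples, hi, method="higher")))

    def significant(self, observed: float, statistic: str) -> bool:
        """True when the observed value falls outside the 2.5-97.5%
        interval of the null samples."""
        lo, hi = self.interval(statistic)
        if math.isnan(lo):
            return False
        return bool(observed < lo or observed > hi)


def permutation_null(tree: IndexedTree,
                     polymorphic_columns: np.ndarray,
                     n_permutations: int = 100_000,
                     seed: int = 0,
                     batch_size: int | None = None,
                     n_samples: int = 1000) -> PermutationNull:
    """Analyze artificial column pairs drawn from the polymorphic pool.

    Each permutation draws two distinct columns uniformly (columns may
    come from different genes), forms their joint states and runs the full
    block/switch/typing pipeline. ``polymorphic_columns`` is an
    (n_columns, n_nodes) array of resolved per-node states (-1 =
    UNRESOLVED).
    """
    pool = np.asarray(polymorphic_columns)
    n_cols = pool.shape[0]
    if n_cols < 2:
        raise ValueError("need at least 2 polymorphic columns")
    rng = np.random.default_rng(seed)
    cols = [row.tolist() for row in pool]
    counts = np.zeros((n_permutations, 5), dtype=np.int32)
    for k in range(n_permutations):
        i = int(rng.integers(n_cols))
        j = int(rng.integers(n_cols - 1))
        if j >= i:
            j += 1
        a, b = cols[i], cols[j]
        js = [x * 4 + y if (x >= 0 and y >= 0) else -1
              for x, y in zip(a, b)]
        counts[k] = switch_type_counts(tree, js)
    if batch_size is None or batch_size < 1:
        batch_size = 1
    tir_s, ratio_s = [], []
    n_und_t = n_und_r = 0
    for _ in range(n_samples):
        idx = rng.integers(n_permutations, size=batch_size)
        tot = counts[idx].sum(axis=0)
        if tot[0] + tot[1] + tot[2] == 0:
            n_und_t += 1
        else:
            tir_s.append(tir(int(tot[0]), int(tot[1]), int(tot[2])))
        if tot.sum() == 0:
            n_und_r += 1
        else:
            ratio_s.append(intermediate_observed_ratio(tot))
    return PermutationNull(
        n_permutations=n_permutations, seed=seed, type_counts=counts,
        batch_size=batch_size, n_samples=n_samples,
        tir_samples=np.asarray(tir_s, float),
        ratio_samples=np.asarray(ratio_s, float),
        n_undefined_tir=n_und_t, n_undefined_ratio=n_und_r)


# ----------------------------------------------------- conservation etc.

def _column_residues(aln: TerminatorAlignment, col: int) -> tuple[set, bool]:
    """(set of residues, any gap present) for one alignment column."""
    res = set()
    gap = False
    for seq in aln.sequences.values():
        ch = seq[col]
        if ch == "-":
            gap = True
        else:
            res.add(ch)
    return res, gap


def _column_variable(aln: TerminatorAlignment, col: int) -> bool:
    """Variable = at least two distinct residue values among strains."""
    res, _ = _column_residues(aln, col)
    return len(res) >= 2


def conservation_summary(alignments: Sequence[TerminatorAlignment]
                         ) -> pd.DataFrame:
    """Per-region invariant fractions and the mismatch/gap split.

    A column is invariant when all strains carry the same residue and no
    gap; non-conserved columns split into mismatch-driven (>=2 residues)
    and gap-only (single residue plus gaps).
    """
    rows = []
    for region in ("stem", "loop", "polyU"):
        n = inv = mism = gaponly = 0
        for aln in alignments:
            for col, cls in enumerate(aln.region_classes):
                if cls != region:
                    continue
                n += 1
                res, gap = _column_residues(aln, col)
                if len(res) >= 2:
                    mism += 1
                elif gap:
                    gaponly += 1
                else:
                    inv += 1
        nv = mism + gaponly
        rows.append(dict(
            region=region, n_columns=n,
            invariant_fraction=inv / n if n else math.nan,
            variable_mismatch_fraction=mism / nv if nv else math.nan,
            variable_gap_fraction=gaponly / nv if nv else math.nan))
    return pd.DataFrame(rows)


def _sym_root(code: int) -> tuple[str, bool]:
    """Symmetrized ancestral pair label and whether columns were swapped."""
    s = pair_string(code)
    lab = _WC_SYM.get(s)
    if lab is None:
        return s, False
    return lab, lab != s


def pair_fate_table(alignments: Sequence[TerminatorAlignment],
                    reconstructions: Mapping[str, "GeneReconstruction"]
                    ) -> pd.DataFrame:
    """Accounting of nucleotide changes at interacting column pairs.

    For every pair whose root (last common ancestor of all strains) state
    is resolved to AU, GC or GU (strand-symmetrized): counts of invariant
    pairs, single-side-substituted pairs by side and destination pair
    (multiple substitutions at one column collapse to 'multiple'), and
    both-sides-substituted pairs with the subcount carrying a WC switch.
    Pairs with an unresolved root are counted under 'unresolved_root'.
    """
    rows: Counter = Counter()
    for aln in alignments:
        rec = reconstructions[aln.gene_id]
        res = rec.resolved
        tree = rec.tree
        for (l, r) in aln.column_pairs:
            rl, rr = int(res[l, 0]), int(res[r, 0])
            if rl < 0 or rr < 0:
                rows[("any", "unresolved_root", "")] += 1
                continue
            code = rl * 4 + rr
            anc, swapped = _sym_root(code)
            if anc not in ("AU", "GC", "GU"):
                rows[(anc, "other_root", "")] += 1
                continue
            var_l = _column_variable(aln, l)
            var_r = _column_variable(aln, r)
            if swapped:
                var_a, var_b = var_r, var_l
                col_a, col_b = r, l
            else:
                var_a, var_b = var_l, var_r
                col_a, col_b = l, r
            if not var_a and not var_b:
                rows[(anc, "invariant", "")] += 1
            elif var_a != var_b:
                side = "first" if var_a else "second"
                col = col_a if var_a else col_b
                nev = _n_column_events(tree, res, col)
                if nev == 1:
                    dest = _destination_pair(tree, res, l, r, swapped)
                    rows[(anc, f"single_{side}", dest)] += 1
                else:
                    rows[(anc, f"single_{side}", "multiple")] += 1
            else:
                js = _joint_list(res, l, r)
                n_switch = int(switch_type_counts(tree, js).sum())
                rows[(anc, "both", "with_wc_switch" if n_switch else
                      "without_wc_switch")] += 1
    return pd.DataFrame(
        [dict(ancestral_pair=a, category=c, destination=d, count=n)
         for (a, c, d), n in sorted(rows.items())])


def _joint_list(res: np.ndarray, l: int, r: int) -> list[int]:
    a = res[l].tolist()
    b = res[r].tolist()
    return [x * 4 + y if (x >= 0 and y >= 0) else -1 for x, y in zip(a, b)]


def _n_column_events(tree: IndexedTree, res: np.ndarray, col: int) -> int:
    states = res[col]
    n = 0
    for i in range(1, tree.n_nodes):
        p = tree._parent[i]
        if states[i] >= 0 and states[p] >= 0 and states[i] != states[p]:
            n += 1
    return n


def _destination_pair(tree: IndexedTree, res: np.ndarray, l: int, r: int,
                      swapped: bool) -> str:
    """Resulting pair after the single substitution, symmetrized."""
    states_l, states_r = res[l], res[r]
    for i in range(1, tree.n_nodes):
        p = tree._parent[i]
        for states, other, first in ((states_l, states_r, True),
                                     (states_r, states_l, False)):
            if states[i] >= 0 and states[p] >= 0 and states[i] != states[p]:
                if other[i] < 0:
                    return "unknown"
                code = (states[i] * 4 + other[i]) if first \
                    else (other[i] * 4 + states[i])
                return pair_string(_swap(code) if swapped else code)
    return "unknown"


def positional_variability(alignments: Sequence[TerminatorAlignment],
                           reconstructions: Mapping[str, "GeneReconstruction"]
                           ) -> dict[str, tuple[np.ndarray, float]]:
    """Variable/invariant stem-position tables with Fisher p-values.

    Tables (rows = categories, columns = [variable, invariant] nucleotide
    columns): external vs internal positions stratified by ancestral pair
    (AU, GC, GU); inner vs outer external positions (pairs pooled); and
    right vs left arm of the outer external position.
    """
    strat = {anc: np.zeros((2, 2), int) for anc in ("AU", "GC", "GU")}
    inner_outer = np.zeros((2, 2), int)
    arm = np.zeros((2, 2), int)
    for aln in alignments:
        rec = reconstructions[aln.gene_id]
        classes = classify_stem_positions(aln.structure)
        for k, (l, r) in enumerate(aln.column_pairs):
            rank = classes[k].pair_rank if k in classes else "internal"
            rl, rr = int(rec.resolved[l, 0]), int(rec.resolved[r, 0])
            anc = None
            if rl >= 0 and rr >= 0:
                anc, _ = _sym_root(rl * 4 + rr)
            for col, which_arm in ((l, "left"), (r, "right")):
                var = _column_variable(aln, col)
                j = 0 if var else 1
                if anc in strat:
                    i = 0 if rank.startswith("external") else 1
                    strat[anc][i, j] += 1
                if rank == "external_inner":
                    inner_outer[0, j] += 1
                elif rank == "external_outer":
                    inner_outer[1, j] += 1
                    arm[0 if which_arm == "right" else 1, j] += 1
    out = {}
    for anc, tab in strat.items():
        out[f"external_vs_internal_{anc}"] = (tab, fisher_two_tailed(tab))
    out["inner_vs_outer_external"] = (inner_outer,
                                      fisher_two_tailed(inner_outer))
    out["right_vs_left_outer_arm"] = (arm, fisher_two_tailed(arm))
    return out


# -------------------------------------------------------- bidirectional

@dataclass
class BidirectionalResult:
    """Orientation classes, coincidence calls and Fisher comparisons."""

    pairs: pd.DataFrame            # gene_a, gene_b, orientation, category
    category_by_gene: dict[str, str]
    exclusions: dict[str, int]
    tables: dict[str, np.ndarray]
    p_values: dict[str, float]


def _revcomp(seq: str) -> str:
    comp = {"A": "U", "U": "A", "G": "C", "C": "G", "N": "N", "-": "-"}
    return "".join(comp[c] for c in reversed(seq))


def _terminators_coincide(a: TerminatorAlignment,
                          b: TerminatorAlignment) -> bool:
    """Same stem structure read on opposite strands."""
    ra, rb = a.ungapped_reference, b.ungapped_reference
    if len(ra) != len(rb) or _revcomp(ra) != rb:
        return False
    L = len(ra)
    mirrored = sorted((L - 1 - r, L - 1 - l) for l, r in a.structure.pairs)
    return tuple(mirrored) == tuple(sorted(b.structure.pairs))


def _revcomp_forms_terminator(aln: TerminatorAlignment,
                              thresholds: FilterThresholds) -> bool:
    """Does the reverse complement of the reference stem still qualify?

    The mirrored stem of the reverse-complement sequence must satisfy the
    energy and complementarity criteria (a hairpin's reverse complement
    pairs mirror positions, so this checks the same pairs on the other
    strand).
    """
    from .structure import StemStructure, stem_energy

    seq = _revcomp(aln.ungapped_reference)
    L = len(seq)
    pairs = tuple(sorted((L - 1 - r, L - 1 - l)
                         for l, r in aln.structure.pairs))
    lo, hi = aln.structure.loop_span
    st = StemStructure(pairs=pairs, loop_span=(L - hi, L - lo), length=L)
    n_comp = sum(1 for l, r in pairs
                 if seq[l] + seq[r] in COMPLEMENTARY_PAIRS)
    if n_comp < thresholds.min_complementary_pairs:
        return False
    if n_comp / len(pairs) < thresholds.min_complementary_fraction:
        return False
    return stem_energy(seq, st) <= thresholds.min_stem_energy


def _variable_pair_counts(aln: TerminatorAlignment) -> tuple[int, int]:
    """(pairs with exactly one variable column, remaining pairs)."""
    var = inv = 0
    for l, r in aln.column_pairs:
        if _column_variable(aln, l) != _column_variable(aln, r):
            var += 1
        else:
            inv += 1
    return var, inv


def bidirectional_analysis(annotations: pd.DataFrame,
                           alignments: Sequence[TerminatorAlignment],
                           max_gap: int = 200,
                           thresholds: FilterThresholds | None = None
                           ) -> BidirectionalResult:
    """Classify adjacent gene pairs and compare terminator conservation.

    Adjacent genes are cooriented (end-to-head) or convergent
    (end-to-end). Convergent pairs with terminators predicted for both
    genes are checked for coincidence (same stem on opposite strands);
    single-terminator convergent pairs are kept when the reverse
    complement of the known terminator forms a valid stem, lies within
    ``max_gap`` of the second gene and not inside it. Coinciding
    terminators' column pairs are counted once per gene. Fisher tests
    compare the fraction of column pairs with exactly one variable
    nucleotide in each convergent category against cooriented terminators.

    ``annotations`` needs columns gene_id, start, end, strand and the
    terminator interval (term_start/term_end, -1 when absent).
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    if "strand" not in annotations.columns:
        raise ValueError("annotations must carry a strand column")
    by_gene = {a.gene_id: a for a in alignments}
    ann = annotations.sort_values("start").reset_index(drop=True)
    pair_rows = []
    category: dict[str, str] = {}
    exclusions = Counter()
    for k in range(len(ann) - 1):
        g1, g2 = ann.iloc[k], ann.iloc[k + 1]
        s1, s2 = g1["strand"], g2["strand"]
        if s1 == s2:
            orient = "cooriented"
        elif (s1, s2) == ("+", "-"):
            orient = "convergent"
        else:
            orient = "divergent"
        cat = ""
        if orient == "convergent":
            a1 = by_gene.get(g1["gene_id"])
            a2 = by_gene.get(g2["gene_id"])
            if a1 is not None and a2 is not None:
                if _terminators_coincide(a1, a2):
                    cat = "coinciding"
                    category[g1["gene_id"]] = "coinciding"
                    category[g2["gene_id"]] = "coinciding"
                else:
                    cat = "both_separate"
                    category[g1["gene_id"]] = "convergent_separate"
                    category[g2["gene_id"]] = "convergent_separate"
            elif a1 is not None or a2 is not None:
                own, other = (g1, g2) if a1 is not None else (g2, g1)
                aln = a1 if a1 is not None else a2
                ts, te = int(own["term_start"]), int(own["term_end"])
                os_, oe = int(other["start"]), int(other["end"])
                if ts >= os_ and te <= oe:
                    cat = "excluded_inside"
                    exclusions["inside_second_gene"] += 1
                elif not _revcomp_forms_terminator(aln, thresholds):
                    cat = "excluded_no_structure"
                    exclusions["no_terminator_structure"] += 1
                else:
                    gap = os_ - te if te <= os_ else ts - oe
                    if gap > max_gap:
                        cat = "excluded_too_far"
                        exclusions["too_far"] += 1
                    else:
                        cat = "single_shared"
                        category[own["gene_id"]] = "single_shared"
            else:
                cat = "no_terminators"
        pair_rows.append(dict(gene_a=g1["gene_id"], gene_b=g2["gene_id"],
                              orientation=orient, category=cat))
        if orient == "cooriented":
            for g in (g1, g2):
                if g["gene_id"] in by_gene:
                    category.setdefault(g["gene_id"], "cooriented")

    def pooled(cat_name: str) -> tuple[int, int]:
        var = inv = 0
        for gid, c in category.items():
            if c == cat_name and gid in by_gene:
                v, i = _variable_pair_counts(by_gene[gid])
                var += v
                inv += i
        return var, inv

    base = pooled("cooriented")
    tables, pvals = {}, {}
    for cat_name in ("coinciding", "convergent_separate", "single_shared"):
        v, i = pooled(cat_name)
        tab = np.array([[v, i], list(base)])
        tables[cat_name] = tab
        pvals[cat_name] = fisher_two_tailed(tab)
    return BidirectionalResult(
        pairs=pd.DataFrame(pair_rows), category_by_gene=category,
        exclusions=dict(exclusions), tables=tables, p_values=pvals)
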