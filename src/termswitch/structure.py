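"""Terminator hairpin structures.

An intrinsic (rho-independent) transcription terminator is an RNA hairpin —
a helical stem closed by a short loop — followed by a poly-U tract. This
module represents the stem as an ordered list of paired positions, parses
dot-bracket strings into that representation, scores stem stability with a
nearest-neighbor stacking table, and classifies stem positions into the
external (outermost and loop-adjacent) and internal pair ranks used by the
positional-variability analysis.

Coordinates are 0-based; intervals are half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

__all__ = [
    "MIN_STEM_PAIRS", "MAX_STEM_PAIRS",
    "MalformedStructureError", "StemLengthError",
    "StemStructure", "PositionClass",
    "parse_dot_bracket", "stem_energy", "classify_stem_positions",
    "DEFAULT_STACK_TABLE", "complementary", "WC_PAIRS", "WOBBLE_PAIRS",
]

MIN_STEM_PAIRS = 5
MAX_STEM_PAIRS = 19

WC_PAIRS = frozenset({"AU", "UA", "GC", "CG"})
WOBBLE_PAIRS = frozenset({"GU", "UG"})
COMPLEMENTARY_PAIRS = WC_PAIRS | WOBBLE_PAIRS


def complementary(left: str, right: str) -> bool:
    """True for WC (AU/UA/GC/CG) and wobble (GU/UG) nucleotide pairs."""
    return (left + right) in COMPLEMENTARY_PAIRS


# Simplified nearest-neighbor stacking energies (kcal/mol) for two
# adjacent complementary pairs. Each pair class contributes a fixed
# half-stack strength (GC-type 1.65, AU-type 0.55, GU 0.25), roughly
# matching the magnitudes of measured WC/GU stacking terms. The table is
# only used for the -5 kcal/mol stability filter, not for folding.
_PAIR_STRENGTH = {"GC": 1.65, "CG": 1.65, "AU": 0.55, "UA": 0.55,
                  "GU": 0.25, "UG": 0.25}

DEFAULT_STACK_TABLE: Mapping[tuple[str, str], float] = {
    (p1, p2): -(s1 + s2)
    for p1, s1 in _PAIR_STRENGTH.items()
    for p2, s2 in _PAIR_STRENGTH.items()
}


class MalformedStructureError(ValueError):
    """Unbalanced or non-hairpin dot-bracket input."""


class StemLengthError(ValueError):
    """Stem size outside the accepted 5-19 bp range."""

    def __init__(self, length: int):
        self.length = length
        super().__init__(
            f"stem of {length} pairs outside allowed range "
            f"[{MIN_STEM_PAIRS}, {MAX_STEM_PAIRS}]")


@dataclass(frozen=True)
class StemStructure:
    """Paired-position annotation of one terminator hairpin.

    ``pairs`` are (left, right) positions into the ungapped reference
    terminator, outermost pair first; ``loop_span`` and ``polyU_span`` are
    half-open intervals. ``length`` is the reference sequence length, kept
    so the dot-bracket string can be reconstructed.
    """

    pairs: tuple[tuple[int, int], ...]
    loop_span: tuple[int, int]
    length: int
    polyU_span: Optional[tuple[int, int]] = None

    def __post_init__(self):
        prev = None
        for (l, r) in self.pairs:
            if not (0 <= l < r < self.length):
                raise MalformedStructureError(f"bad pair ({l},{r})")
            if prev is not None and not (l > prev[0] and r < prev[1]):
                raise MalformedStructureError(
                    "pairs must be properly nested, outermost first")
            prev = (l, r)
        il, ir = self.pairs[-1]
        lo, hi = self.loop_span
        if not (il < lo and hi <= ir):
            raise MalformedStructureError(
                "loop must lie strictly inside the innermost pair")

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def left_positions(self) -> list[int]:
        return [l for l, _ in self.pairs]

    @property
    def right_positions(self) -> list[int]:
        return [r for _, r in self.pairs]

    def to_dot_bracket(self) -> str:
        chars = ["."] * self.length
        for l, r in self.pairs:
            chars[l] = "("
            chars[r] = ")"
        return "".join(chars)


def parse_dot_bracket(structure_string: str, sequence: str) -> StemStructure:
    """Parse a single-hairpin dot-bracket annotation.

    Raises :class:`MalformedStructureError` on unbalanced brackets or
    multi-stem input, and :class:`StemLengthError` when the stem has fewer
    than 5 or more than 19 pairs. Poly-U detection is not performed here.
    """
    if len(structure_string) != len(sequence):
        raise MalformedStructureError(
            "structure and sequence lengths differ")
    bad = set(structure_string) - set("().")
    if bad:
        raise MalformedStructureError(f"illegal characters {sorted(bad)}")
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure_string):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise MalformedStructureError("unbalanced ')'")
            pairs.append((stack.pop(), i))
    if stack:
        raise MalformedStructureError("unbalanced '('")
    if not pairs:
        raise MalformedStructureError("no base pairs")
    pairs.sort()  # outermost first for a single nested stem
    prev = None
    for l, r in pairs:
        if prev is not None and not (l > prev[0] and r < prev[1]):
            raise MalformedStructureError(
                "structure is not a single nested hairpin")
        prev = (l, r)
    if not (MIN_STEM_PAIRS <= len(pairs) <= MAX_STEM_PAIRS):
        raise StemLengthError(len(pairs))
    il, ir = pairs[-1]
    return StemStructure(pairs=tuple(pairs), loop_span=(il + 1, ir),
                         length=len(structure_string))


def _stack_value(stack_table, pair1: str, pair2: str,
                 mismatch_penalty: float) -> float:
    if pair1 in COMPLEMENTARY_PAIRS and pair2 in COMPLEMENTARY_PAIRS:
        try:
            return stack_table[(pair1, pair2)]
        except KeyError:
            return stack_table[(pair2, pair1)]
    return mismatch_penalty


def stem_energy(sequence: str, structure: StemStructure,
                stack_table: Mapping[tuple[str, str], float] | None = None,
                mismatch_penalty: float = 0.0) -> float:
    """Stacking-energy score of a stem (kcal/mol; more negative = stabler).

    Sums table values over consecutive, directly adjacent pairs (left
    positions and right positions both contiguous); a bulge breaks the
    stack and contributes nothing. A stack involving a non-complementary
    pair contributes ``mismatch_penalty`` (default 0).
    """
    if stack_table is None:
        stack_table = DEFAULT_STACK_TABLE
    nts = []
    for l, r in structure.pairs:
        if r >= len(sequence):
            raise IndexError(f"pair position {r} outside sequence")
        nts.append(sequence[l] + sequence[r])
    total = 0.0
    for k in range(len(structure.pairs) - 1):
        (l1, r1), (l2, r2) = structure.pairs[k], structure.pairs[k + 1]
        if l2 == l1 + 1 and r2 == r1 - 1:  # directly stacked
            total += _stack_value(stack_table, nts[k], nts[k + 1],
                                  mismatch_penalty)
    return total


@dataclass(frozen=True)
class PositionClass:
    """Rank of a stem pair and arm of each of its nucleotides."""

    pair_rank: str                      # external_outer | external_inner |
                                        # internal | external_degenerate
    left_arm: str = field(default="left")
    right_arm: str = field(default="right")


def classify_stem_positions(structure: StemStructure
                            ) -> dict[int, PositionClass]:
    """Classify stem pairs: outermost pair is external_outer, the
    loop-adjacent pair external_inner, all others internal.

    The nucleotide with the smaller coordinate of a pair sits on the left
    (5') arm, the larger on the right (3', poly-U-proximal) arm. A
    single-pair stem gets the degenerate all-external rank.
    """
    n = structure.n_pairs
    if n == 1:
        return {0: PositionClass(pair_rank="external_degenerate")}
    out = {}
    for k in range(n):
        if k == 0:
            rank = "external_outer"
        elif k == n - 1:
            rank = "external_inner"
        else:
            rank = "internal"
        out[k] = PositionClass(pair_rank=rank)
    return out
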