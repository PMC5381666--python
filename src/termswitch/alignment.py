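"""Structure-annotated terminator alignments and quality filters.

A :class:`TerminatorAlignment` holds the gapped per-strain sequences of one
orthologous terminator region together with the interacting-column-pair
annotation projected from the reference hairpin structure. The filters
implement the per-strain stem-quality criteria (stacking energy, number and
fraction of complementary pairs, unpaired fraction per arm) and the
alignment-level 70%-identity rule; ``retain_column_pairs`` drops column
pairs whose modal dinucleotide is not complementary.

Alphabet is RNA {A,C,G,U}; DNA input is transliterated on read. Gaps are
'-' and ambiguity codes (N, ...) count as non-complementary and as
mismatches.
"""

from __future__ import annotations

import math
import os
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from Bio import SeqIO

from .structure import (StemStructure, complementary, stem_energy,
                        DEFAULT_STACK_TABLE, COMPLEMENTARY_PAIRS)

__all__ = [
    "FilterThresholds", "TerminatorAlignment",
    "pairwise_identity", "apply_alignment_filters", "retain_column_pairs",
    "read_structure_file", "read_alignment_directory", "normalize_rna",
]

GAP = "-"


def normalize_rna(seq: str) -> str:
    """Uppercase and transliterate T to U."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class FilterThresholds:
    """Stem and alignment quality cutoffs.

    Defaults: stems must score at most -5 kcal/mol, carry >= 5
    complementary (WC or GU) pairs covering >= 70% of interacting column
    pairs, leave <= 30% of each arm unpaired, and every non-reference
    strain must be >= 70% identical to the reference.
    """

    min_stem_energy: float = -5.0
    min_complementary_pairs: int = 5
    min_complementary_fraction: float = 0.70
    max_unpaired_fraction_per_arm: float = 0.30
    min_identity: float = 0.70

    def __post_init__(self):
        for name in ("min_complementary_fraction",
                     "max_unpaired_fraction_per_arm", "min_identity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.min_complementary_pairs < 1:
            raise ValueError("min_complementary_pairs must be >= 1")


@dataclass(frozen=True)
class TerminatorAlignment:
    """Gapped per-strain sequences plus interacting-column annotation."""

    gene_id: str
    sequences: Mapping[str, str]
    reference_strain: str
    structure: StemStructure
    column_pairs: tuple[tuple[int, int], ...] = field(default=())
    region_classes: tuple[str, ...] = field(default=())

    def __post_init__(self):
        lens = {len(s) for s in self.sequences.values()}
        if len(lens) != 1:
            raise ValueError("all sequences must have the same length")
        if self.reference_strain not in self.sequences:
            raise ValueError("reference strain missing from alignment")
        for l, r in self.column_pairs:
            if not (0 <= l < r < self.length):
                raise ValueError(f"bad column pair ({l},{r})")
        cols = [c for p in self.column_pairs for c in p]
        if len(cols) != len(set(cols)):
            raise ValueError("a column may appear in at most one pair")
        ref = self.ungapped_reference
        if len(ref) != self.structure.length:
            raise ValueError("ungapped reference does not match structure")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    @property
    def strains(self) -> list[str]:
        return list(self.sequences)

    @property
    def ungapped_reference(self) -> str:
        return self.sequences[self.reference_strain].replace(GAP, "")

    def reference_position_to_column(self) -> list[int]:
        """Column index of each ungapped reference position."""
        out = []
        for i, ch in enumerate(self.sequences[self.reference_strain]):
            if ch != GAP:
                out.append(i)
        return out

    @classmethod
    def from_structure(cls, gene_id: str, sequences: Mapping[str, str],
                       reference_strain: str, structure: StemStructure
                       ) -> "TerminatorAlignment":
        """Project the reference hairpin onto alignment columns.

        Interacting column pairs are the columns holding the reference's
        paired positions; region classes are assigned per column (stem,
        loop, polyU, flank — insertion columns relative to the reference
        are classed as flank).
        """
        sequences = {k: normalize_rna(v) for k, v in sequences.items()}
        probe = cls(gene_id=gene_id, sequences=sequences,
                    reference_strain=reference_strain, structure=structure)
        pos2col = probe.reference_position_to_column()
        column_pairs = tuple((pos2col[l], pos2col[r])
                             for l, r in structure.pairs)
        classes = ["flank"] * probe.length
        for l, r in structure.pairs:
            classes[pos2col[l]] = "stem"
            classes[pos2col[r]] = "stem"
        for p in range(*structure.loop_span):
            classes[pos2col[p]] = "loop"
        if structure.polyU_span is not None:
            for p in range(*structure.polyU_span):
                classes[pos2col[p]] = "polyU"
        return replace(probe, column_pairs=column_pairs,
                       region_classes=tuple(classes))

    def strain_pairs(self, strain: str) -> list[str]:
        """Dinucleotides of one strain at the interacting column pairs."""
        seq = self.sequences[strain]
        return [seq[l] + seq[r] for l, r in self.column_pairs]


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Fraction of matching comparable columns between two gapped rows.

    Gap-gap columns are excluded; a gap against a base counts as a
    mismatch, as does any ambiguity code. Returns NaN when no column is
    comparable.
    """
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    matches = compared = 0
    for a, b in zip(seq_a, seq_b):
        if a == GAP and b == GAP:
            continue
        compared += 1
        if a == b and a in "ACGU":
            matches += 1
    if compared == 0:
        return math.nan
    return matches / compared


def _strain_stem_energy(aln: TerminatorAlignment, strain: str,
                        stack_table, mismatch_penalty: float = 0.0) -> float:
    """Stacking energy of one strain's projection of the reference stem.

    Pairs are stacked when stacked in the reference structure; a pair that
    is non-complementary (or gapped) in this strain contributes the
    mismatch penalty to its stacks.
    """
    pairs_nt = aln.strain_pairs(strain)
    spairs = aln.structure.pairs
    total = 0.0
    for k in range(len(spairs) - 1):
        (l1, r1), (l2, r2) = spairs[k], spairs[k + 1]
        if l2 == l1 + 1 and r2 == r1 - 1:
            p1, p2 = pairs_nt[k], pairs_nt[k + 1]
            if p1 in COMPLEMENTARY_PAIRS and p2 in COMPLEMENTARY_PAIRS:
                try:
                    total += stack_table[(p1, p2)]
                except KeyError:
                    total += stack_table[(p2, p1)]
            else:
                total += mismatch_penalty
    return total


def apply_alignment_filters(aln: TerminatorAlignment,
                            thresholds: FilterThresholds | None = None,
                            stack_table=None
                            ) -> tuple[dict[str, bool], bool]:
    """Evaluate the four per-strain stem criteria and the identity rule.

    Per strain: (i) stem stacking energy <= min_stem_energy, (ii) at least
    ``min_complementary_pairs`` complementary pairs among interacting
    columns, (iii) complementary pairs in at least
    ``min_complementary_fraction`` of interacting column pairs, (iv) at
    most ``max_unpaired_fraction_per_arm`` unpaired nucleotides on each
    arm. The whole alignment is retained only if every strain passes all
    four and every non-reference strain is at least ``min_identity``
    identical to the reference.
    """
    if thresholds is None:
        thresholds = FilterThresholds()
    if stack_table is None:
        stack_table = DEFAULT_STACK_TABLE
    kept: dict[str, bool] = {}
    n_pairs = len(aln.column_pairs)
    for strain in aln.strains:
        pairs_nt = aln.strain_pairs(strain)
        n_comp = sum(1 for p in pairs_nt if p in COMPLEMENTARY_PAIRS)
        ok = True
        energy = _strain_stem_energy(aln, strain, stack_table)
        if energy > thresholds.min_stem_energy:
            ok = False
        if n_comp < thresholds.min_complementary_pairs:
            ok = False
        if n_pairs and n_comp / n_pairs < thresholds.min_complementary_fraction:
            ok = False
        for arm in (0, 1):  # left, right
            n_res = n_unp = 0
            for p in pairs_nt:
                if p[arm] in "ACGU":
                    n_res += 1
                    if p not in COMPLEMENTARY_PAIRS:
                        n_unp += 1
            if n_res and n_unp / n_res > thresholds.max_unpaired_fraction_per_arm:
                ok = False
        kept[strain] = ok
    retained = all(kept.values())
    if retained:
        ref = aln.sequences[aln.reference_strain]
        for strain in aln.strains:
            if strain == aln.reference_strain:
                continue
            ident = pairwise_identity(ref, aln.sequences[strain])
            if not (ident >= thresholds.min_identity):
                retained = False
                break
    return kept, retained


def retain_column_pairs(aln: TerminatorAlignment) -> TerminatorAlignment:
    """Drop column pairs whose most common dinucleotide is not WC or GU.

    Only strains with unambiguous residues at both columns are counted.
    Frequency ties are resolved in favor of retention: the pair is kept if
    any tied mode is complementary. Idempotent.
    """
    kept = []
    for (l, r) in aln.column_pairs:
        counts = Counter()
        for seq in aln.sequences.values():
            p = seq[l] + seq[r]
            if p[0] in "ACGU" and p[1] in "ACGU":
                counts[p] += 1
        if not counts:
            continue
        top = max(counts.values())
        modes = [p for p, c in counts.items() if c == top]
        if any(p in COMPLEMENTARY_PAIRS for p in modes):
            kept.append((l, r))
    return replace(aln, column_pairs=tuple(kept))


# -- file input ----------------------------------------------------------

def read_structure_file(path: str
                        ) -> dict[str, tuple[str, str,
                                             tuple[int, int] | None]]:
    """Read the dot-bracket structure file.

    One record per gene: ``gene_id <TAB> structure <TAB> ref_sequence``
    plus an optional fourth column with the poly-U tract as a half-open
    ``start:end`` interval ('-' = none). Returns gene_id ->
    (structure_string, reference_sequence, polyU_span or None).
    """
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) == 3:
                gene_id, struct, seq = fields
                polyU = None
            elif len(fields) == 4:
                gene_id, struct, seq, pu = fields
                if pu == "-":
                    polyU = None
                else:
                    lo, hi = pu.split(":")
                    polyU = (int(lo), int(hi))
            else:
                raise ValueError(
                    f"structure file {path}: expected 3 or 4 tab-separated "
                    f"columns, got {len(fields)}")
            out[gene_id] = (struct, normalize_rna(seq), polyU)
    return out


def read_alignment_directory(manifest_path: str, structures_path: str
                             ) -> list[TerminatorAlignment]:
    """Load per-gene FASTA alignments listed in a manifest TSV.

    Manifest columns: gene_id, file (relative to the manifest), and
    reference_strain. Structures come from the companion dot-bracket file.
    """
    from .structure import parse_dot_bracket

    structures = read_structure_file(structures_path)
    base = os.path.dirname(os.path.abspath(manifest_path))
    out = []
    with open(manifest_path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("gene_id\t"):
                continue
            gene_id, fname, ref = line.split("\t")
            seqs = {rec.id: normalize_rna(str(rec.seq))
                    for rec in SeqIO.parse(os.path.join(base, fname), "fasta")}
            struct_str, struct_seq, polyU = structures[gene_id]
            structure = parse_dot_bracket(struct_str, struct_seq)
            if polyU is not None:
                structure = replace(structure, polyU_span=polyU)
            out.append(TerminatorAlignment.from_structure(
                gene_id, seqs, ref, structure))
    return out
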