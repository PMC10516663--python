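"""Alignment-based validation of structure models.

Covariation analysis is the computational test of a proposed helix: a
base pair is supported when homologous sequences maintain Watson-Crick
or G.U complementarity at the two aligned columns, and *covariant* when
they do so through different base-pair identities (compensatory
substitution).  This module provides deterministic pairwise global
alignment, percent identity, per-pair covariation classes over a
multiple alignment, column conservation statistics, and concordance of
a structure model with chemical-probing reactivities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from Bio import Align

from .descriptor import StructureAnnotation
from .energetics import pair_kind
from .seqio import CoordinateError, GenomeRecord


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class PairwiseAlignment:
    seq_a: str  # gapped
    seq_b: str
    score: float

    def __post_init__(self) -> None:
        if len(self.seq_a) != len(self.seq_b):
            raise AlignmentError("gapped rows differ in length")
        if any(a == "-" and b == "-" for a, b in zip(self.seq_a, self.seq_b)):
            raise AlignmentError("gap/gap column")


@dataclass(frozen=True)
class PairSupport:
    pair_id: int
    columns: tuple[int, int]  # 0-based alignment columns
    support: int  # members with a WC/GU pair at the columns
    identities: tuple[str, ...]  # distinct complementary pair identities seen
    klass: str  # invariant | covariant | inconsistent


@dataclass(frozen=True)
class CovariationReport:
    n_members: int
    per_pair: tuple[PairSupport, ...]
    strong_threshold: int

    @property
    def invariant_pair_count(self) -> int:
        return sum(1 for p in self.per_pair if p.klass == "invariant")

    @property
    def covariant_pair_count(self) -> int:
        return sum(1 for p in self.per_pair if p.klass == "covariant")

    @property
    def inconsistent_pair_count(self) -> int:
        return sum(1 for p in self.per_pair if p.klass == "inconsistent")

    @property
    def supported_pair_count(self) -> int:
        return sum(1 for p in self.per_pair if p.support >= self.strong_threshold)


@dataclass(frozen=True)
class ConservationStats:
    fraction_invariant_columns: float
    pairwise_identity_matrix: tuple[tuple[float, ...], ...]


_ALIGNER = None


def _aligner(match: float = 1.0, mismatch: float = -1.0,
             gap_open: float = -5.0, gap_extend: float = -1.0) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def align_pair(a: GenomeRecord | str, b: GenomeRecord | str, *,
               match: float = 1.0, mismatch: float = -1.0,
               gap_open: float = -5.0, gap_extend: float = -1.0) -> PairwiseAlignment:
    """Global (Needleman-Wunsch) alignment; the first optimal traceback of
    the dynamic-programming aligner is taken, so output is deterministic."""
    sa = a.seq if isinstance(a, GenomeRecord) else a
    sb = b.seq if isinstance(b, GenomeRecord) else b
    if not sa or not sb:
        raise AlignmentError("cannot align empty sequence")
    aln = _aligner(match, mismatch, gap_open, gap_extend).align(sa, sb)[0]
    return PairwiseAlignment(seq_a=aln[0], seq_b=aln[1], score=float(aln.score))


def percent_identity(aln: PairwiseAlignment) -> float:
    """100 x matches / columns, counting only columns ungapped in both
    rows (a fixed, documented identity definition)."""
    pairs = [
        (x, y) for x, y in zip(aln.seq_a, aln.seq_b) if x != "-" and y != "-"
    ]
    if not pairs:
        raise AlignmentError("no ungapped columns: identity undefined")
    matches = sum(1 for x, y in pairs if x == y)
    return 100.0 * matches / len(pairs)


def map_structure_columns(reference_row: str,
                          annotation: StructureAnnotation) -> list[tuple[int, int, int]]:
    """Map each reference pair (0-based sequence positions) to alignment
    columns of the gapped reference row; returns (pair_id, col_i, col_j)."""
    col_of: dict[int, int] = {}
    seq_pos = 0
    for col, ch in enumerate(reference_row):
        if ch != "-":
            col_of[seq_pos] = col
            seq_pos += 1
    out = []
    for pid, (i, j, _) in enumerate(annotation.pairs):
        if i not in col_of or j not in col_of:
            raise CoordinateError(f"pair ({i},{j}) outside the reference row")
        out.append((pid, col_of[i], col_of[j]))
    return out


def covariation_report(rows: list[str], annotation: StructureAnnotation,
                       strong_frac: float = 0.85,
                       reference_index: int = 0) -> CovariationReport:
    """Classify every reference base pair across an alignment.

    A pair is *invariant* when every member forms the same complementary
    pair identity; *covariant* when all members pair but with >= 2
    identities, or when support reaches the strong threshold
    ``floor(strong_frac * n)`` with >= 2 identities; otherwise
    *inconsistent*.  Support counts members whose bases at the two
    columns form a WC or G.U pair.  The default fraction 0.85 reproduces
    the ">= 22 of 26 members" convention at n = 26.
    """
    n = len(rows)
    if n < 2:
        raise AlignmentError("covariation needs >= 2 members")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise AlignmentError("alignment rows differ in length")
    strong = math.floor(strong_frac * n + 1e-9)
    per_pair = []
    for pid, ci, cj in map_structure_columns(rows[reference_index], annotation):
        idents: list[str] = []
        support = 0
        for row in rows:
            x, y = row[ci], row[cj]
            if x != "-" and y != "-" and pair_kind(x, y) is not None:
                support += 1
                ident = x + y
                if ident not in idents:
                    idents.append(ident)
        if support == n and len(idents) == 1:
            klass = "invariant"
        elif (support == n and len(idents) >= 2) or (
            support >= strong and len(idents) >= 2
        ):
            klass = "covariant"
        else:
            klass = "inconsistent"
        per_pair.append(
            PairSupport(pair_id=pid, columns=(ci, cj), support=support,
                        identities=tuple(idents), klass=klass)
        )
    return CovariationReport(n_members=n, per_pair=tuple(per_pair), strong_threshold=strong)


def conservation_stats(rows: list[str]) -> ConservationStats:
    """Fraction of fully ungapped columns with one base identity, plus an
    all-vs-all percent-identity matrix (100 on the diagonal)."""
    if len(rows) < 2:
        raise AlignmentError("need >= 2 rows")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise AlignmentError("alignment rows differ in length")
    full_cols = 0
    invariant = 0
    for c in range(width):
        column = [r[c] for r in rows]
        if "-" in column:
            continue
        full_cols += 1
        if len(set(column)) == 1:
            invariant += 1
    frac = invariant / full_cols if full_cols else 0.0
    n = len(rows)
    mat = [[100.0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            mat[i][j] = mat[j][i] = _row_identity(rows[i], rows[j])
    return ConservationStats(
        fraction_invariant_columns=frac,
        pairwise_identity_matrix=tuple(tuple(r) for r in mat),
    )


def _row_identity(a: str, b: str) -> float:
    cols = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not cols:
        raise AlignmentError("no ungapped columns between rows")
    return 100.0 * sum(1 for x, y in cols if x == y) / len(cols)


def probe_concordance(annotation: StructureAnnotation,
                      reactive_positions: list[int]) -> float:
    """Fraction of chemically reactive positions (1-based) that the model
    leaves unpaired.  Wobble pairs count as paired; positions must lie
    within the annotated span."""
    if not reactive_positions:
        raise AlignmentError("empty reactive-position list: concordance undefined")
    span_lo = min(iv.start for iv in annotation.element_coords.values())
    span_hi = max(annotation.start_codon.end,
                  max(iv.end for iv in annotation.element_coords.values()))
    paired = set()
    for i, j, _ in annotation.pairs:
        paired.update((i + 1, j + 1))
    unpaired = 0
    for pos in reactive_positions:
        if not (span_lo <= pos <= span_hi):
            raise CoordinateError(f"reactive position {pos} outside model span")
        if pos not in paired:
            unpaired += 1
    return unpaired / len(reactive_positions)
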