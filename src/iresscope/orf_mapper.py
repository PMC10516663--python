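"""Six-frame translation, ORF detection and dicistronic genome layout.

Dicistrovirus genomes carry two long ORFs: ORF1 (helicase-protease-
polymerase polyprotein) and ORF2 (capsid polyprotein), separated by the
intergenic region (IGR) that hosts the IRES.  Because IGR IRESs initiate
ORF2 at a non-AUG codon, ORF2 is detected here as a long stop-free
reading frame; its true start is fixed only once an IRES match assigns
the initiation codon.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from Bio.Data import CodonTable

from .seqio import CoordinateError, GenomeRecord, Interval, reverse_complement

_STANDARD = CodonTable.unambiguous_rna_by_id[1]
_CODON_TABLE: dict[str, str] = dict(_STANDARD.forward_table)
for _stop in _STANDARD.stop_codons:
    _CODON_TABLE[_stop] = "*"


class NoLayoutError(ValueError):
    """Raised when a record does not contain a qualifying dicistronic layout."""


@dataclass(frozen=True)
class OrfAnnotation:
    """An open reading frame.

    ``start_kind`` distinguishes AUG-initiated ORFs from stop-to-stop open
    frames (``frame_open``) and frames whose start was later pinned by an
    IRES match (``IRES_assigned``).
    """

    interval: Interval
    frame: int
    strand: str
    protein: str
    start_kind: str  # AUG | frame_open | IRES_assigned

    def __len__(self) -> int:
        return len(self.interval)


@dataclass(frozen=True)
class DicistronicLayout:
    orf1: OrfAnnotation
    orf2: OrfAnnotation
    igr: Interval

    def __post_init__(self) -> None:
        if self.orf1.interval.end >= self.orf2.interval.start:
            raise CoordinateError("ORF1 must end before ORF2 starts")


@dataclass(frozen=True)
class MapParams:
    min_orf_aa: int = 150
    igr_min: int = 100
    igr_max: int = 400
    min_genome_len: int = 600
    require_ygdd: bool = False  # RdRp proxy motif in ORF1


def translate_codon(codon: str) -> str:
    return _CODON_TABLE.get(codon, "X")


def translate_frame(record: GenomeRecord, frame: int, strand: str = "+") -> str:
    """Translate one frame with the standard code; stops as '*', ambiguous
    codons as 'X'; a trailing partial codon is dropped."""
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    seq = record.seq if strand == "+" else reverse_complement(record.seq)
    out = []
    for i in range(frame, len(seq) - 2, 3):
        out.append(translate_codon(seq[i : i + 3]))
    return "".join(out)


def find_orfs(record: GenomeRecord, min_aa: int, strand: str = "+") -> list[OrfAnnotation]:
    """Report AUG-initiated ORFs and stop-to-stop open frames per frame.

    AUG ORFs run from the first AUG after the previous stop to the next
    stop (or to the end of the frame if no stop follows: then the length
    counts complete codons only).  Open frames (``frame_open``) span the
    stretch of stop-free codons between consecutive stops.  Intervals are
    reported in + coordinates of the forward record for strand '+'; for
    strand '-' they refer to the reverse complement and are flagged by
    the strand field.
    """
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = record.seq if strand == "+" else reverse_complement(record.seq)
    orfs: list[OrfAnnotation] = []
    for frame in (0, 1, 2):
        codons = [(i, seq[i : i + 3]) for i in range(frame, len(seq) - 2, 3)]
        aas = [translate_codon(c) for _, c in codons]
        # segment into stop-free runs
        run_start = 0
        for idx in range(len(aas) + 1):
            at_end = idx == len(aas)
            if at_end or aas[idx] == "*":
                run = list(range(run_start, idx))
                if run:
                    _emit_runs(orfs, record, codons, aas, run, frame, strand, min_aa)
                run_start = idx + 1
    orfs.sort(key=lambda o: (o.interval.start, o.interval.end, o.frame))
    return orfs


def _emit_runs(orfs, record, codons, aas, run, frame, strand, min_aa) -> None:
    protein = "".join(aas[i] for i in run)
    start_nt = codons[run[0]][0]
    end_nt = codons[run[-1]][0] + 3
    if len(run) >= min_aa:
        orfs.append(
            OrfAnnotation(
                interval=Interval.from_zero_based(start_nt, end_nt, strand),
                frame=frame,
                strand=strand,
                protein=protein,
                start_kind="frame_open",
            )
        )
    # AUG ORF inside the run
    for k, i in enumerate(run):
        if codons[i][1] == "AUG":
            if len(run) - k >= min_aa:
                orfs.append(
                    OrfAnnotation(
                        interval=Interval.from_zero_based(codons[i][0], end_nt, strand),
                        frame=frame,
                        strand=strand,
                        protein=protein[k:],
                        start_kind="AUG",
                    )
                )
            break


def map_dicistronic(record: GenomeRecord, params: MapParams | None = None,
                    strand: str = "+") -> DicistronicLayout:
    """Find the dicistronic ORF1/IGR/ORF2 layout of a genome.

    Candidate pairs are non-overlapping open frames in genome order whose
    gap (the putative IGR) lies within ``igr_min``..``igr_max``.  Ties are
    broken by maximal combined length, then smallest IGR, then 5'-most
    position — deterministic by construction.
    """
    params = params or MapParams()
    if len(record.seq) < params.min_genome_len:
        raise NoLayoutError(
            f"record {record.id!r} shorter than min_genome_len {params.min_genome_len}"
        )
    frames = [o for o in find_orfs(record, params.min_orf_aa, strand=strand)
              if o.start_kind == "frame_open"]
    best = None
    for a in frames:
        for b in frames:
            gap = b.interval.start - a.interval.end - 1
            if gap < params.igr_min or gap > params.igr_max:
                continue
            orf1 = a
            if params.require_ygdd and "YGDD" not in orf1.protein:
                continue
            key = (-(len(a.interval) + len(b.interval)), gap, a.interval.start)
            if best is None or key < best[0]:
                best = (key, orf1, b)
    if best is None:
        raise NoLayoutError(f"record {record.id!r}: no qualifying ORF pair")
    _, orf1, orf2 = best
    igr = Interval(orf1.interval.end + 1, orf2.interval.start - 1, strand)
    return DicistronicLayout(orf1=orf1, orf2=orf2, igr=igr)


def assign_orf2_start(layout: DicistronicLayout, start_codon: Interval) -> DicistronicLayout:
    """Pin ORF2's start to the IRES-assigned initiation codon."""
    orf2 = layout.orf2
    if start_codon.start < layout.igr.start or start_codon.end > orf2.interval.end:
        raise CoordinateError("start codon outside IGR/ORF2 span")
    new_interval = Interval(start_codon.start, orf2.interval.end, orf2.strand)
    trimmed = (start_codon.start - orf2.interval.start) // 3
    new = replace(
        orf2,
        interval=new_interval,
        start_kind="IRES_assigned",
        protein=orf2.protein[trimmed:] if start_codon.start >= orf2.interval.start else orf2.protein,
    )
    igr = Interval(layout.igr.start, start_codon.start - 1, layout.igr.strand) \
        if start_codon.start > layout.igr.start else layout.igr
    return DicistronicLayout(orf1=layout.orf1, orf2=new, igr=igr)


def extract_igr(record: GenomeRecord, layout: DicistronicLayout,
                flank_into_orf2: int = 75) -> tuple[GenomeRecord, int, bool]:
    """Extract the IGR plus a flank into ORF2.

    The default 75 nt flank mirrors reverse-transcription primer placement
    61-75 nt downstream of the putative initiation codon.  Returns
    ``(subrecord, offset0, truncated)``: local position ``i`` (0-based)
    corresponds to genome 0-based ``offset0 + i``.
    """
    start0 = layout.igr.start0
    end0 = layout.igr.end0 + flank_into_orf2
    truncated = False
    if end0 > len(record.seq):
        end0 = len(record.seq)
        truncated = True
    sub = record.subrecord(start0, end0, suffix="igr")
    return sub, start0, truncated
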