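"""Sequence and annotation I/O with fixed coordinate conventions.

All external coordinates (FASTA headers, GFF3, reports) are 1-based
inclusive, matching the virology convention in which a triplet written
``GCU 6906-6908`` spans three nucleotides.  Internally every interval is
0-based half-open.  :class:`Interval` stores the external convention and
provides the conversion.

Sequences are normalized to the RNA alphabet on input (T -> U, upper
case); the original alphabet is remembered so genomic DNA can be written
back out as DNA.  IUPAC ambiguity codes are preserved but are treated as
non-pairing by all structure operations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

IUPAC_RNA = set("ACGURYSWKMBDHVN")

#: Bracket alphabets for layered dot-bracket output, in layer order.
LAYER_BRACKETS = [("(", ")"), ("[", "]"), ("{", "}"), ("<", ">")]


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input (names the offending record)."""


class CoordinateError(ValueError):
    """Raised when an interval falls outside its record."""


class StructureValidityError(ValueError):
    """Raised for conflicting or non-complementary base-pair sets."""


@dataclass(frozen=True)
class GenomeRecord:
    """A nucleotide sequence normalized to the RNA alphabet.

    ``source_alphabet`` records whether the input used T (DNA) or U (RNA)
    so round trips preserve the original lettering.
    """

    id: str
    seq: str
    description: str = ""
    source_alphabet: str = "RNA"

    def __post_init__(self) -> None:
        if not self.seq:
            raise FastaFormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - IUPAC_RNA
        if bad:
            raise FastaFormatError(
                f"record {self.id!r}: non-IUPAC characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.seq)

    def subrecord(self, start0: int, end0: int, suffix: str = "sub") -> "GenomeRecord":
        """Slice [start0, end0) (0-based half-open) into a new record."""
        if not (0 <= start0 < end0 <= len(self.seq)):
            raise CoordinateError(
                f"slice {start0}:{end0} outside record {self.id!r} of length {len(self.seq)}"
            )
        return replace(self, id=f"{self.id}|{suffix}", seq=self.seq[start0:end0])


@dataclass(frozen=True)
class Interval:
    """1-based inclusive interval on a strand, the reporting convention of the virology literature."""

    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise CoordinateError(f"invalid interval {self.start}-{self.end}")
        if self.strand not in "+-":
            raise CoordinateError(f"invalid strand {self.strand!r}")

    @classmethod
    def from_zero_based(cls, start0: int, end0: int, strand: str = "+") -> "Interval":
        return cls(start0 + 1, end0, strand)

    @property
    def start0(self) -> int:
        """0-based inclusive start."""
        return self.start - 1

    @property
    def end0(self) -> int:
        """0-based exclusive end."""
        return self.end

    def __len__(self) -> int:
        return self.end - self.start + 1

    def shift(self, offset: int) -> "Interval":
        return Interval(self.start + offset, self.end + offset, self.strand)


def normalize(seq: str) -> tuple[str, str]:
    """Upper-case and transcribe to RNA; return (rna_seq, source_alphabet)."""
    up = seq.upper().replace(" ", "")
    alphabet = "DNA" if "T" in up else "RNA"
    return up.replace("T", "U"), alphabet


def reverse_complement(seq: str) -> str:
    comp = str.maketrans("ACGUN", "UGCAN")
    return seq.translate(comp)[::-1]


def read_fasta(path) -> list[GenomeRecord]:
    """Read FASTA into normalized :class:`GenomeRecord` objects.

    T is transcribed to U, case folded to upper; duplicate ids are an
    error because downstream reports key on the record id.
    """
    records: list[GenomeRecord] = []
    seen: set[str] = set()
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise FastaFormatError(f"{path}: {exc}") from exc
    for rec in parsed:
        if not rec.id:
            raise FastaFormatError(f"{path}: record with empty header")
        if rec.id in seen:
            raise FastaFormatError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        rna, alphabet = normalize(str(rec.seq))
        if not rna:
            raise FastaFormatError(f"{path}: record {rec.id!r} has empty sequence")
        records.append(
            GenomeRecord(id=rec.id, seq=rna, description=rec.description, source_alphabet=alphabet)
        )
    if not records:
        # Distinguish "no entries" from Biopython silently yielding nothing
        # for non-FASTA text.
        with open(path) as fh:
            head = fh.read(1)
        if head and head != ">":
            raise FastaFormatError(f"{path}: not FASTA (first byte {head!r})")
    return records


def read_aligned_fasta(path) -> list[tuple[str, str]]:
    """Read a pre-aligned FASTA: gapped rows ('-' kept), RNA-normalized.

    Returns (id, gapped_seq) tuples; all rows must share one length.
    """
    rows: list[tuple[str, str]] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gapped = str(rec.seq).upper().replace("T", "U")
        bad = set(gapped) - IUPAC_RNA - {"-", "."}
        if bad:
            raise FastaFormatError(f"{path}: row {rec.id!r} has {sorted(bad)}")
        rows.append((rec.id, gapped.replace(".", "-")))
    if rows and len({len(s) for _, s in rows}) != 1:
        raise FastaFormatError(f"{path}: aligned rows differ in length")
    return rows


def write_fasta(records: Iterable[GenomeRecord], path, width: int = 70) -> None:
    """Write records, restoring U->T for records that came in as DNA."""
    seqrecs = []
    for r in records:
        seq = r.seq.replace("U", "T") if r.source_alphabet == "DNA" else r.seq
        seqrecs.append(SeqRecord(Seq(seq), id=r.id, description=r.description or ""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


# ---------------------------------------------------------------------------
# GFF3


def _gff3_escape(value: str) -> str:
    return (
        value.replace("%", "%25")
        .replace(";", "%3B")
        .replace("=", "%3D")
        .replace(",", "%2C")
        .replace("\t", "%09")
    )


def write_gff3(records: Sequence[GenomeRecord], features, path) -> None:
    """Write features as GFF3 (1-based inclusive, 9 columns).

    ``features`` is an iterable of ``(record_id, Interval, type, attributes)``
    where attributes is a dict; a feature with a ``Parent`` attribute is
    emitted as a child row.  Intervals are validated against their record.
    """
    lengths = {r.id: len(r.seq) for r in records}
    lines = ["##gff-version 3"]
    for rid in lengths:
        lines.append(f"##sequence-region {rid} 1 {lengths[rid]}")
    for record_id, interval, ftype, attributes in features:
        if record_id not in lengths:
            raise CoordinateError(f"feature on unknown record {record_id!r}")
        if interval.end > lengths[record_id]:
            raise CoordinateError(
                f"feature {ftype} {interval.start}-{interval.end} exceeds "
                f"record {record_id!r} length {lengths[record_id]}"
            )
        attrs = ";".join(f"{k}={_gff3_escape(str(v))}" for k, v in attributes.items())
        lines.append(
            "\t".join(
                [
                    record_id,
                    "iresscope",
                    ftype,
                    str(interval.start),
                    str(interval.end),
                    ".",
                    interval.strand,
                    ".",
                    attrs or ".",
                ]
            )
        )
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w") as fh:
            fh.write(text)


def validate_gff3(text: str) -> list[str]:
    """Structural GFF3 checker (independent of the writer).

    Returns a list of problems; empty list means the document is valid.
    Checks: version pragma, 9 tab-separated columns, integer 1-based
    coordinates with start <= end, declared sequence-region bounds, strand
    field, and that every Parent attribute references a declared ID.
    """
    problems: list[str] = []
    lines = text.rstrip("\n").split("\n")
    if not lines or not lines[0].startswith("##gff-version 3"):
        problems.append("missing ##gff-version 3 pragma")
    regions: dict[str, int] = {}
    ids: set[str] = set()
    parents: list[tuple[int, str]] = []
    for n, line in enumerate(lines, 1):
        if line.startswith("##sequence-region"):
            parts = line.split()
            if len(parts) == 4:
                regions[parts[1]] = int(parts[3])
            continue
        if line.startswith("#") or not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            problems.append(f"line {n}: {len(cols)} columns, expected 9")
            continue
        seqid, _source, _type, start, end, _score, strand, _phase, attrs = cols
        try:
            s, e = int(start), int(end)
        except ValueError:
            problems.append(f"line {n}: non-integer coordinates")
            continue
        if not (1 <= s <= e):
            problems.append(f"line {n}: bad coordinate order {s}-{e}")
        if seqid in regions and e > regions[seqid]:
            problems.append(f"line {n}: end {e} beyond sequence-region {regions[seqid]}")
        if strand not in "+-.?":
            problems.append(f"line {n}: bad strand {strand!r}")
        for item in attrs.split(";"):
            if item.startswith("ID="):
                ids.add(item[3:])
            elif item.startswith("Parent="):
                parents.append((n, item[7:]))
    for n, parent in parents:
        if parent not in ids:
            problems.append(f"line {n}: Parent {parent!r} references no ID")
    return problems


# ---------------------------------------------------------------------------
# Layered dot-bracket for pseudoknotted structures


@dataclass(frozen=True)
class LayeredDotBracket:
    """A sequence plus one bracket string per non-crossing layer.

    Within a layer the brackets are balanced and non-crossing; pairs in
    different layers may cross (that is what makes it a pseudoknot).
    """

    sequence: str
    layers: tuple[str, ...]

    def __post_init__(self) -> None:
        for layer in self.layers:
            if len(layer) != len(self.sequence):
                raise StructureValidityError("layer length != sequence length")

    def text(self) -> str:
        return "\n".join([self.sequence, *self.layers]) + "\n"


def _crosses(a: tuple[int, int], b: tuple[int, int]) -> bool:
    (i, j), (k, l) = sorted([a, b])
    return i < k < j < l


def layer_pairs(pairs: Sequence[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Greedy minimal-ish layering: assign each pair (by ascending opening
    position) to the first layer it does not cross.

    For the descriptor structures produced here (at most two mutually
    crossing helix families) the greedy assignment is minimal.
    """
    seen: set[int] = set()
    norm = []
    for i, j in pairs:
        i, j = min(i, j), max(i, j)
        if i == j:
            raise StructureValidityError(f"self-pair at {i}")
        for p in (i, j):
            if p in seen:
                raise StructureValidityError(f"position {p} in two pairs")
            seen.add(p)
        norm.append((i, j))
    layers: list[list[tuple[int, int]]] = []
    for pair in sorted(norm):
        for layer in layers:
            if not any(_crosses(pair, q) for q in layer):
                layer.append(pair)
                break
        else:
            layers.append([pair])
    return layers


def write_dotbracket(sequence: str, pairs: Sequence[tuple[int, int]]) -> LayeredDotBracket:
    """Serialize a (possibly pseudoknotted) pair set, 0-based pair indices."""
    layered = layer_pairs(pairs)
    if len(layered) > len(LAYER_BRACKETS):
        raise StructureValidityError(f"{len(layered)} layers exceed bracket alphabets")
    strings = []
    for layer, (op, cl) in zip(layered, LAYER_BRACKETS):
        chars = ["."] * len(sequence)
        for i, j in layer:
            if j >= len(sequence):
                raise CoordinateError(f"pair ({i},{j}) outside sequence")
            chars[i], chars[j] = op, cl
        strings.append("".join(chars))
    return LayeredDotBracket(sequence=sequence, layers=tuple(strings))


def parse_dotbracket(db: LayeredDotBracket | str) -> list[tuple[int, int]]:
    """Recover the 0-based pair set from layered dot-bracket text."""
    if isinstance(db, str):
        lines = [l for l in db.strip().split("\n") if l]
        db = LayeredDotBracket(sequence=lines[0], layers=tuple(lines[1:]))
    pairs: list[tuple[int, int]] = []
    for layer in db.layers:
        stacks: dict[str, list[int]] = {op: [] for op, _ in LAYER_BRACKETS}
        closers = {cl: op for op, cl in LAYER_BRACKETS}
        for pos, ch in enumerate(layer):
            if ch in stacks:
                stacks[ch].append(pos)
            elif ch in closers:
                stack = stacks[closers[ch]]
                if not stack:
                    raise StructureValidityError(f"unbalanced {ch!r} at {pos}")
                pairs.append((stack.pop(), pos))
            elif ch != ".":
                raise StructureValidityError(f"unexpected character {ch!r}")
        for op, stack in stacks.items():
            if stack:
                raise StructureValidityError(f"unclosed {op!r} at {stack[-1]}")
    return sorted(pairs)


def read_positions(path) -> list[int]:
    """Read a plain-text list of 1-based positions (one per line)."""
    out = []
    with open(path) as fh:
        for n, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                value = int(line)
            except ValueError:
                raise FastaFormatError(f"{path}:{n}: not an integer: {line!r}")
            if value < 1:
                raise CoordinateError(f"{path}:{n}: positions are 1-based, got {value}")
            out.append(value)
    return out
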