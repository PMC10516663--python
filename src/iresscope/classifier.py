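"""Typing of IGR IRES structure annotations (types 6a-6e).

The five classes differ in overall length and in the presence of the
PKIII pseudoknot and its optional stem-loops:

========  ==========================================  ============
type      architecture                                length (nt)
========  ==========================================  ============
6a        PKI + PKII + PKIII with SLIV and SLV        176-193
6b        as 6a, plus SLIII on PKI                    195-205
6c        PKI + PKII, no PKIII                        126-132
6d        PKI + PKII + PKIII with SLIV, no SLV        161-168
6e        PKI + PKII + compact H-type PKIII,          142-154
          no SLIV/SLV
========  ==========================================  ============

Lengths include the ORF2 initiation codon.  The printed ranges are
empirical and pairwise disjoint; lengths falling in the gaps between
them give an ``unclassified`` call with a near-type hint rather than a
forced assignment.  Initiation-codon compatibility (6a/6b use GCU, GCA
or CAA; 6e uses GCU, ACU, ACC, UCU, UCA or UCG) is reported as evidence
but is never decisive on its own.
"""

from __future__ import annotations

from dataclasses import dataclass

from .descriptor import StructureAnnotation
from .orf_mapper import translate_codon

#: length ranges (inclusive, nt including the initiation codon)
DEFAULT_LENGTH_RANGES: dict[str, tuple[int, int]] = {
    "6a": (176, 193),
    "6b": (195, 205),
    "6c": (126, 132),
    "6d": (161, 168),
    "6e": (142, 154),
}

#: architecture: (needs PKIII, SLIII, SLIV, SLV)
ARCHITECTURE: dict[str, tuple[bool, bool, bool, bool]] = {
    "6a": (True, False, True, True),
    "6b": (True, True, True, True),
    "6c": (False, False, False, False),
    "6d": (True, False, True, False),
    "6e": (True, False, False, False),
}

CODON_SETS: dict[str, frozenset[str]] = {
    "6a": frozenset({"GCU", "GCA", "CAA"}),
    "6b": frozenset({"GCU", "GCA", "CAA"}),
    "6c": frozenset({"GCU", "GCA", "CAA", "ACU", "UCU"}),
    "6d": frozenset({"GCU", "GCA", "CAA", "ACU", "UCU"}),
    "6e": frozenset({"GCU", "ACU", "ACC", "UCU", "UCA", "UCG"}),
}


class RangeConfigError(ValueError):
    """Raised when custom length ranges overlap (ambiguous classification)."""


@dataclass(frozen=True)
class IresTypeCall:
    type: str  # 6a..6e or "unclassified"
    length_nt: int
    evidence: tuple[str, ...]

    @property
    def classified(self) -> bool:
        return self.type != "unclassified"


def validate_ranges(ranges: dict[str, tuple[int, int]]) -> None:
    """Refuse overlapping length ranges: classification must be a function."""
    items = sorted(ranges.items(), key=lambda kv: kv[1])
    for (ta, (a1, a2)), (tb, (b1, b2)) in zip(items, items[1:]):
        if a2 >= b1:
            raise RangeConfigError(
                f"length ranges for {ta} ({a1}-{a2}) and {tb} ({b1}-{b2}) overlap"
            )


def _architecture_flags(annotation: StructureAnnotation) -> tuple[bool, bool, bool, bool]:
    has_pk3 = bool(annotation.pk_groups.get("PKIII"))
    sl = annotation.optional_stemloops
    return has_pk3, sl.get("SLIII", False), sl.get("SLIV", False), sl.get("SLV", False)


def classify_type(annotation: StructureAnnotation, length_nt: int,
                  ranges: dict[str, tuple[int, int]] | None = None) -> IresTypeCall:
    """Assign an IGR IRES type from architecture and length.

    Deterministic and total: every annotation yields either a type with
    its satisfied rules as evidence, or ``unclassified`` with itemized
    violations (including a near-type hint when only the length misses).
    """
    ranges = ranges or DEFAULT_LENGTH_RANGES
    validate_ranges(ranges)
    flags = _architecture_flags(annotation)
    evidence: list[str] = []
    arch_matches = [t for t, want in ARCHITECTURE.items() if want == flags]
    length_matches = [
        t for t, (lo, hi) in ranges.items() if lo <= length_nt <= hi
    ]
    codon = annotation.start_triplet
    for t in sorted(set(arch_matches) & set(length_matches)):
        evidence.append(f"architecture matches {t}")
        evidence.append(f"length {length_nt} within {ranges[t][0]}-{ranges[t][1]}")
        if codon in CODON_SETS[t]:
            aa = translate_codon(codon)
            evidence.append(f"start codon {codon} ({aa}) typical of {t}")
        else:
            evidence.append(f"start codon {codon} atypical for {t}")
        return IresTypeCall(type=t, length_nt=length_nt, evidence=tuple(evidence))
    # unclassified: explain
    if arch_matches:
        hint = arch_matches[0]
        lo, hi = ranges[hint]
        evidence.append(f"architecture matches {hint}")
        evidence.append(
            f"length {length_nt} outside {hint} range {lo}-{hi} (near-type hint: {hint})"
        )
    else:
        pk3, sl3, sl4, sl5 = flags
        evidence.append(
            "architecture matches no type "
            f"(PKIII={pk3}, SLIII={sl3}, SLIV={sl4}, SLV={sl5})"
        )
    if length_matches and not arch_matches:
        evidence.append(f"length {length_nt} compatible with {length_matches[0]}")
    return IresTypeCall(type="unclassified", length_nt=length_nt, evidence=tuple(evidence))


def codon_check(triplet: str, ires_type: str) -> tuple[bool, str]:
    """Is ``triplet`` a known initiation codon for the type?  Returns the
    membership plus an amino-acid annotation string."""
    t = triplet.upper().replace("T", "U")
    if len(t) != 3 or any(b not in "ACGU" for b in t):
        raise ValueError(f"not an RNA triplet: {triplet!r}")
    if ires_type not in CODON_SETS:
        raise ValueError(f"unknown IRES type {ires_type!r}")
    member = t in CODON_SETS[ires_type]
    aa = translate_codon(t)
    return member, f"{t} ({aa})" + ("" if member else f" not in {ires_type} codon set")
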