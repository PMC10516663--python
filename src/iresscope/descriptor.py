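"""IRES structural descriptors and descriptor-constrained matching.

A descriptor is a grammar for an IRES class: an ordered linear layout of
helix strands, loops and the initiation codon, plus per-element length
bounds, pairing constraints (Watson-Crick everywhere, G.U wobble where
allowed, mandated pairs such as the invariant junction wobble) and loop
consensus motifs.  ``match_descriptor`` finds every placement of the
grammar on a sequence by backtracking from the initiation codon (the PKI
anchor at the 3' end) toward the 5' border, pruning on complementarity,
motif and length-budget constraints.  Matches are scored by pairing
count, motif support and nearest-neighbor free energy.

The default descriptor encodes the compact Wenling-class (type 6e)
architecture: PKII (P1.1/P1.2/P1.3), an H-type PKIII (P2.1/P2.2) without
SLIV/SLV stem-loops, and the 3'-terminal PKI (P3.1/P3.2) abutting a
non-AUG initiation codon.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field, replace
from importlib import resources

from .energetics import default_model, evaluate_structure, pair_kind, rank_matches
from .seqio import CoordinateError, GenomeRecord, Interval, layer_pairs

IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "U": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


class DescriptorConfigError(ValueError):
    """Raised for invalid or unsatisfiable descriptor configuration."""


def iupac_match(base: str, code: str) -> bool:
    """Whether a concrete base satisfies an IUPAC consensus code.

    Ambiguity codes in the *sequence* never satisfy a motif position
    (conservative treatment of uncertain bases).
    """
    return base in IUPAC_SETS.get(code, "")


@dataclass(frozen=True)
class HelixElement:
    name: str
    min_bp: int
    max_bp: int
    allow_wobble: bool = True
    #: (offset, kind) pairs that are mandated; offset counts from the
    #: outermost pair (0) or from the innermost (-1), kind is 'GU' or 'WC'.
    required_pairs: tuple[tuple[int, str], ...] = ()

    def __post_init__(self) -> None:
        if not (1 <= self.min_bp <= self.max_bp <= 15):
            raise DescriptorConfigError(
                f"helix {self.name}: bounds {self.min_bp}..{self.max_bp} outside 1..15"
            )


@dataclass(frozen=True)
class LoopElement:
    name: str
    min_len: int
    max_len: int
    motif: str | None = None
    max_mismatch: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.min_len <= self.max_len):
            raise DescriptorConfigError(f"loop {self.name}: bad bounds")
        if self.motif and len(self.motif) > self.max_len:
            raise DescriptorConfigError(f"loop {self.name}: motif longer than loop")


@dataclass(frozen=True)
class IresDescriptor:
    name: str
    layout: tuple[str, ...]  # tokens: "<helix>:5", "<helix>:3", loop name, "codon"
    helices: dict[str, HelixElement]
    loops: dict[str, LoopElement]
    pk_groups: dict[str, tuple[str, ...]]
    domains: dict[str, tuple[str, ...]]
    total_len_range: tuple[int, int]
    allowed_start_codons: frozenset[str]
    pk3_is_h_type: bool = True
    score_weights: tuple[float, float, float] = (1.0, 2.0, 0.1)

    def __post_init__(self) -> None:
        self.validate()

    # -- structural sanity ------------------------------------------------
    def validate(self) -> None:
        lo, hi = self.total_len_range
        # full IGR IRES classes span 126-205 nt; the lower bound also
        # admits reduced test grammars
        if not (20 <= lo <= hi <= 260):
            raise DescriptorConfigError(f"total_len_range {self.total_len_range}")
        names = [t for t in self.layout if t != "codon"]
        seen5, seen3 = set(), set()
        for tok in names:
            if tok.endswith(":5"):
                seen5.add(tok[:-2])
            elif tok.endswith(":3"):
                seen3.add(tok[:-2])
        if seen5 != set(self.helices) or seen3 != set(self.helices):
            raise DescriptorConfigError("layout strands do not cover every helix twice")
        loop_toks = [t for t in names if ":" not in t]
        if sorted(loop_toks) != sorted(self.loops) or len(loop_toks) != len(set(loop_toks)):
            raise DescriptorConfigError("layout loops do not match loop elements")
        if self.layout[-1] != "codon" or self.layout.count("codon") != 1:
            raise DescriptorConfigError("layout must end with the single codon token")
        for h in self.helices.values():
            i5 = self.layout.index(f"{h.name}:5")
            i3 = self.layout.index(f"{h.name}:3")
            if i5 >= i3:
                raise DescriptorConfigError(f"helix {h.name}: 5' strand after 3' strand")
        if self.crossing_layer_count() > 3:
            raise DescriptorConfigError("pairing plan needs more than 3 layers")
        lo_sum, hi_sum = self.span_bounds()
        if hi < lo_sum or lo > hi_sum:
            raise DescriptorConfigError(
                f"total_len_range {self.total_len_range} incompatible with "
                f"element bounds [{lo_sum}, {hi_sum}]"
            )

    def crossing_layer_count(self) -> int:
        arcs = []
        for h in self.helices:
            arcs.append((self.layout.index(f"{h}:5"), self.layout.index(f"{h}:3")))
        return len(layer_pairs(arcs))

    def span_bounds(self) -> tuple[int, int]:
        lo = hi = 3  # codon
        for tok in self.layout[:-1]:
            if tok.endswith(":5") or tok.endswith(":3"):
                h = self.helices[tok[:-2]]
                lo += h.min_bp
                hi += h.max_bp
            else:
                l = self.loops[tok]
                lo += l.min_len
                hi += l.max_len
        return lo, hi


def load_descriptor(path=None) -> IresDescriptor:
    """Load a descriptor TOML file (packaged type 6e by default)."""
    if path is None:
        raw = (resources.files("iresscope.data") / "ires6e.toml").read_bytes()
        cfg = tomllib.loads(raw.decode())
    else:
        with open(path, "rb") as fh:
            cfg = tomllib.load(fh)
    try:
        helices = {
            h["name"]: HelixElement(
                name=h["name"],
                min_bp=h["min_bp"],
                max_bp=h["max_bp"],
                allow_wobble=h.get("allow_wobble", True),
                required_pairs=tuple((int(o), str(k)) for o, k in h.get("required_pairs", [])),
            )
            for h in cfg["helix"]
        }
        loops = {
            l["name"]: LoopElement(
                name=l["name"],
                min_len=l["min_len"],
                max_len=l["max_len"],
                motif=l.get("motif"),
                max_mismatch=l.get("max_mismatch", 0),
            )
            for l in cfg["loop"]
        }
        score = cfg.get("score", {})
        return IresDescriptor(
            name=cfg["name"],
            layout=tuple(cfg["layout"]),
            helices=helices,
            loops=loops,
            pk_groups={k: tuple(v) for k, v in cfg["pk_groups"].items()},
            domains={str(k): tuple(v) for k, v in cfg["domains"].items()},
            total_len_range=tuple(cfg["total_len"]),
            allowed_start_codons=frozenset(cfg["start_codons"]),
            pk3_is_h_type=cfg.get("pk3_is_h_type", True),
            score_weights=(
                score.get("w_bp", 1.0), score.get("w_motif", 2.0), score.get("w_energy", 0.1),
            ),
        )
    except (KeyError, TypeError) as exc:
        raise DescriptorConfigError(f"invalid descriptor config: {exc}") from exc


def default_descriptor_6e() -> IresDescriptor:
    return load_descriptor()


# ---------------------------------------------------------------------------
# Annotations and matches


@dataclass(frozen=True)
class StructureAnnotation:
    """A concrete fold: element coordinates, pairs, pseudoknot and domain
    grouping, and the initiation codon.

    Coordinates are 1-based inclusive on the annotated record; ``pairs``
    holds 0-based positions plus the pair kind (WC or GU).
    """

    element_coords: dict[str, Interval]
    pairs: tuple[tuple[int, int, str], ...]
    pk_groups: dict[str, tuple[str, ...]]
    domains: dict[str, tuple[str, ...]]
    start_codon: Interval
    start_triplet: str
    optional_stemloops: dict[str, bool] = field(
        default_factory=lambda: {"SLIII": False, "SLIV": False, "SLV": False}
    )

    def pair_positions(self) -> list[tuple[int, int]]:
        return [(i, j) for i, j, _ in self.pairs]

    def shift(self, offset0: int) -> "StructureAnnotation":
        """Translate all coordinates by ``offset0`` (0-based shift)."""
        return replace(
            self,
            element_coords={k: v.shift(offset0) for k, v in self.element_coords.items()},
            pairs=tuple((i + offset0, j + offset0, k) for i, j, k in self.pairs),
            start_codon=self.start_codon.shift(offset0),
        )


@dataclass(frozen=True)
class IresMatch:
    annotation: StructureAnnotation
    score: float
    delta_g: float
    record_id: str
    genome_interval: Interval


@dataclass(frozen=True)
class ToeprintRule:
    """Reverse-transcriptase stop windows for a ribosome whose P site holds
    the codon:anticodon mimic: +16..+18 from the +1 nucleotide, with a
    weaker +19..+21 set for complexes with PKI in the E site (counting the
    +1 nucleotide as position 1)."""

    p_site_offsets: tuple[int, int] = (16, 18)
    alternate_offsets: tuple[int, int] = (19, 21)


@dataclass(frozen=True)
class MatchParams:
    score_min: float = float("-inf")
    best_only: bool = False
    #: only the 3'-most ``search_window`` nt of the sequence are scanned;
    #: PKI abuts ORF2, so the codon anchor lies near the 3' end.
    search_window: int = 260
    max_solutions: int = 2000


def motif_best_mismatch(segment: str, motif: str) -> int:
    """Fewest mismatches of the consensus over all placements in segment."""
    if len(motif) > len(segment):
        return len(motif)
    best = len(motif)
    for off in range(len(segment) - len(motif) + 1):
        mm = sum(
            0 if iupac_match(segment[off + k], motif[k]) else 1
            for k in range(len(motif))
        )
        best = min(best, mm)
    return best


def _helix_pairs_ok(seq: str, i5: int, j5: int, i3: int, j3: int,
                    helix: HelixElement) -> list[tuple[int, int, str]] | None:
    """Check antiparallel pairing between strands [i5,j5) and [i3,j3)."""
    n = j5 - i5
    out = []
    for k in range(n):
        a, b = i5 + k, j3 - 1 - k
        kind = pair_kind(seq[a], seq[b])
        if kind is None or (kind == "GU" and not helix.allow_wobble):
            return None
        out.append((a, b, kind))
    for off, want in helix.required_pairs:
        k = off if off >= 0 else n + off
        if not (0 <= k < n):
            return None
        if out[k][2] != want:
            return None
    return out


def match_descriptor(record: GenomeRecord, descriptor: IresDescriptor | None = None,
                     params: MatchParams | None = None) -> list[IresMatch]:
    """All descriptor placements on ``record``, ranked.

    Backtracking proceeds 3'->5': enumerate allowed initiation codons
    within the search window, anchor PKI immediately 5' of the codon, and
    extend across the layout enforcing complementarity, wobble policy,
    mandated pairs, motif consensus and length budgets.  Deterministic:
    identical input yields byte-identical ordering (score desc, then dG,
    then 5'-most, then shortest).
    """
    descriptor = descriptor or default_descriptor_6e()
    params = params or MatchParams()
    seq = record.seq
    win_start = max(0, len(seq) - params.search_window)
    lo_total, hi_total = descriptor.total_len_range
    tokens = descriptor.layout[:-1]  # strip codon; walk right-to-left

    # cumulative length budget for tokens[0..k]
    min_pref = [0]
    max_pref = [0]
    for tok in tokens:
        if ":" in tok:
            h = descriptor.helices[tok[:-2]]
            lo, hi = h.min_bp, h.max_bp
        else:
            l = descriptor.loops[tok]
            lo, hi = l.min_len, l.max_len
        min_pref.append(min_pref[-1] + lo)
        max_pref.append(max_pref[-1] + hi)

    solutions: list[IresMatch] = []

    def backtrack(idx: int, end: int, placed: dict[str, tuple[int, int]],
                  pairs: list[tuple[int, int, str]], motif_hits: int,
                  codon_start: int) -> None:
        if len(solutions) >= params.max_solutions:
            return
        if idx < 0:
            total_len = (codon_start + 3) - end
            if lo_total <= total_len <= hi_total:
                _emit(end, placed, pairs, motif_hits, codon_start)
            return
        tok = tokens[idx]
        # prune: remaining tokens must fit the total-length window
        used = (codon_start + 3) - end
        if used + min_pref[idx + 1] > hi_total:
            return
        if used + max_pref[idx + 1] < lo_total:
            return
        if tok.endswith(":3"):
            h = descriptor.helices[tok[:-2]]
            for n in range(h.min_bp, h.max_bp + 1):
                start = end - n
                if start < win_start:
                    break
                placed[tok] = (start, end)
                backtrack(idx - 1, start, placed, pairs, motif_hits, codon_start)
                del placed[tok]
        elif tok.endswith(":5"):
            h = descriptor.helices[tok[:-2]]
            i3, j3 = placed[f"{h.name}:3"]
            n = j3 - i3
            start = end - n
            if start < win_start:
                return
            got = _helix_pairs_ok(seq, start, end, i3, j3, h)
            if got is None:
                return
            placed[tok] = (start, end)
            pairs.extend(got)
            backtrack(idx - 1, start, placed, pairs, motif_hits, codon_start)
            del pairs[len(pairs) - n :]
            del placed[tok]
        else:
            l = descriptor.loops[tok]
            for n in range(l.min_len, l.max_len + 1):
                start = end - n
                if start < win_start:
                    break
                hits = 0
                if l.motif:
                    mm = motif_best_mismatch(seq[start:end], l.motif)
                    if mm > l.max_mismatch:
                        continue
                    hits = len(l.motif) - mm
                placed[tok] = (start, end)
                backtrack(idx - 1, start, placed, pairs, motif_hits + hits, codon_start)
                del placed[tok]

    def _emit(start: int, placed: dict[str, tuple[int, int]],
              pairs: list[tuple[int, int, str]], motif_hits: int,
              codon_start: int) -> None:
        element_coords: dict[str, Interval] = {}
        for tok, (a, b) in placed.items():
            name = tok.split(":")[0]
            key = tok if ":" in tok else name
            element_coords[key] = Interval.from_zero_based(a, b)
        annotation = StructureAnnotation(
            element_coords=element_coords,
            pairs=tuple(sorted(pairs)),
            pk_groups=dict(descriptor.pk_groups),
            domains=dict(descriptor.domains),
            start_codon=Interval.from_zero_based(codon_start, codon_start + 3),
            start_triplet=seq[codon_start : codon_start + 3],
        )
        dg = evaluate_structure(seq, [(i, j) for i, j, _ in pairs]).total
        w_bp, w_motif, w_energy = descriptor.score_weights
        score = round(w_bp * len(pairs) + w_motif * motif_hits - w_energy * dg, 3)
        solutions.append(
            IresMatch(
                annotation=annotation,
                score=score,
                delta_g=dg,
                record_id=record.id,
                genome_interval=Interval.from_zero_based(start, codon_start + 3),
            )
        )

    # enumerate codon anchors from the 3' end
    for codon_start in range(len(seq) - 3, win_start - 1, -1):
        triplet = seq[codon_start : codon_start + 3]
        if triplet not in descriptor.allowed_start_codons:
            continue
        if codon_start - win_start < min_pref[-1]:
            continue
        backtrack(len(tokens) - 1, codon_start, {}, [], 0, codon_start)

    ranked = rank_matches([m for m in solutions if m.score >= params.score_min])
    if params.best_only and ranked:
        return ranked[:1]
    return ranked


# ---------------------------------------------------------------------------
# Independent validation (shares no logic with the search)


def validate_match(record: GenomeRecord, match: IresMatch,
                   descriptor: IresDescriptor) -> list[str]:
    """Re-check every descriptor constraint directly on an annotation.

    Returns a list of violations (empty = valid).  Written against the
    annotation only, so it serves as an independent checker for the
    backtracking engine.
    """
    seq = record.seq
    problems: list[str] = []
    ann = match.annotation
    coords = ann.element_coords

    # layout contiguity, element presence and bounds
    expected_order = [t for t in descriptor.layout]
    pos = None
    for tok in expected_order:
        if tok == "codon":
            iv = ann.start_codon
        else:
            key = tok if ":" in tok else tok
            if key not in coords:
                problems.append(f"missing element {tok}")
                continue
            iv = coords[key]
        if pos is not None and iv.start != pos + 1:
            problems.append(f"{tok} not contiguous (starts {iv.start}, expected {pos + 1})")
        pos = iv.end
    # length bounds
    for h in descriptor.helices.values():
        for side in ("5", "3"):
            key = f"{h.name}:{side}"
            if key in coords and not (h.min_bp <= len(coords[key]) <= h.max_bp):
                problems.append(f"{key} length {len(coords[key])} outside bounds")
    for l in descriptor.loops.values():
        if l.name in coords and not (l.min_len <= len(coords[l.name]) <= l.max_len):
            problems.append(f"{l.name} length {len(coords[l.name])} outside bounds")
    # helix pairing
    pair_set = {(i, j): k for i, j, k in ann.pairs}
    for h in descriptor.helices.values():
        k5, k3 = f"{h.name}:5", f"{h.name}:3"
        if k5 not in coords or k3 not in coords:
            continue
        a, b = coords[k5].start0, coords[k5].end0
        c, d = coords[k3].start0, coords[k3].end0
        if (b - a) != (d - c):
            problems.append(f"{h.name}: unequal strand lengths")
            continue
        kinds = []
        for k in range(b - a):
            i, j = a + k, d - 1 - k
            kind = pair_kind(seq[i], seq[j])
            if kind is None:
                problems.append(f"{h.name}: non-complementary pair at {i + 1},{j + 1}")
            elif kind == "GU" and not h.allow_wobble:
                problems.append(f"{h.name}: wobble pair not allowed at {i + 1},{j + 1}")
            elif pair_set.get((i, j)) != kind:
                problems.append(f"{h.name}: pair ({i + 1},{j + 1}) absent from pair list")
            kinds.append(kind)
        for off, want in h.required_pairs:
            k = off if off >= 0 else len(kinds) + off
            if not (0 <= k < len(kinds)) or kinds[k] != want:
                problems.append(f"{h.name}: required pair {off} is not {want}")
    # motifs
    for l in descriptor.loops.values():
        if l.motif and l.name in coords:
            iv = coords[l.name]
            if motif_best_mismatch(seq[iv.start0 : iv.end0], l.motif) > l.max_mismatch:
                problems.append(f"{l.name}: motif {l.motif} not found")
    # codon
    if ann.start_triplet not in descriptor.allowed_start_codons:
        problems.append(f"start codon {ann.start_triplet} not allowed")
    if seq[ann.start_codon.start0 : ann.start_codon.end0] != ann.start_triplet:
        problems.append("start codon triplet does not match sequence")
    # total length
    lo, hi = descriptor.total_len_range
    if not (lo <= len(match.genome_interval) <= hi):
        problems.append(f"total length {len(match.genome_interval)} outside {lo}..{hi}")
    # H-type PKIII: no stem-loops inside PKIII loops
    if descriptor.pk3_is_h_type and any(ann.optional_stemloops.values()):
        problems.append("optional stem-loops present in an H-type PKIII descriptor")
    return problems


# ---------------------------------------------------------------------------
# Reporting helpers


def report_borders(match: IresMatch) -> tuple[int, int, int]:
    """(5' border, 3' border, length) of an IRES, the 3' border being the
    last nucleotide of the initiation codon (length counts the codon)."""
    five = match.genome_interval.start
    three = match.annotation.start_codon.end
    return five, three, three - five + 1


def predict_toeprints(match: IresMatch, rule: ToeprintRule | None = None) -> dict[str, Interval]:
    """Toeprint windows in genome coordinates.

    Position +16 is the 16th nucleotide counting the +1 nucleotide of the
    initiation codon as 1, so +1 at genome position p puts the P-site
    window at p+15 .. p+17.
    """
    rule = rule or ToeprintRule()
    plus1 = match.annotation.start_codon.start
    lo, hi = rule.p_site_offsets
    alo, ahi = rule.alternate_offsets
    return {
        "p_site": Interval(plus1 + lo - 1, plus1 + hi - 1),
        "alternate": Interval(plus1 + alo - 1, plus1 + ahi - 1),
    }


def apply_mutation(record: GenomeRecord, edits: list[tuple[int, str]]) -> GenomeRecord:
    """Return a copy with 1-based point substitutions applied."""
    seq = list(record.seq)
    for pos, base in edits:
        if not (1 <= pos <= len(seq)):
            raise CoordinateError(f"edit position {pos} outside record of length {len(seq)}")
        seq[pos - 1] = base.upper().replace("T", "U")
    return replace(record, seq="".join(seq))
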