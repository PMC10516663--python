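"""Ground-truthed synthetic data with the statistical structure the
pipeline assumes.

Generates descriptor-satisfying IRES elements, dicistronic genomes
(long ORF1, an intergenic region carrying the IRES, ORF2 in the frame
set by the initiation codon), clades evolved from a common ancestor with
structure-preserving (compensatory) substitutions, and composition-
matched decoys (dinucleotide-preserving Euler shuffles).

All sampling is driven by one explicit :class:`numpy.random.Generator`
(PCG64) threaded through every call — no global state — so outputs are
byte-identical across runs and platforms for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .descriptor import (
    IresDescriptor,
    IresMatch,
    IUPAC_SETS,
    StructureAnnotation,
    default_descriptor_6e,
    validate_match,
)
from .seqio import GenomeRecord, Interval

BASES = "ACGU"
STOPS = ("UAA", "UAG", "UGA")

COMPLEMENTS = {"A": ["U"], "C": ["G"], "G": ["C", "U"], "U": ["A", "G"]}
WC_ONLY = {"A": ["U"], "C": ["G"], "G": ["C"], "U": ["A"]}


class GenerationError(RuntimeError):
    """Raised when a descriptor cannot be satisfied after bounded retries."""


@dataclass(frozen=True)
class GeneratorParams:
    orf1_len_codons: tuple[int, int] = (180, 280)
    orf2_len_codons: tuple[int, int] = (180, 280)
    utr5_len: tuple[int, int] = (20, 50)
    utr3_len: tuple[int, int] = (15, 40)
    igr_padding: tuple[int, int] = (20, 70)
    substitution_rate: float = 0.05
    compensation_prob: float = 0.9
    n_taxa: int = 26
    include_ygdd: bool = True
    wobble_prob: float = 0.1
    freeze_motifs: bool = True

    def __post_init__(self) -> None:
        for p in (self.substitution_rate, self.compensation_prob, self.wobble_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")


@dataclass(frozen=True)
class SampledIres:
    record: GenomeRecord
    annotation: StructureAnnotation
    #: 0-based [start, end) spans of concrete motif placements (frozen
    #: during clade evolution by default)
    motif_spans: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class GenomeTruth:
    record: GenomeRecord
    orf1: Interval
    orf2: Interval
    igr: Interval
    ires_interval: Interval
    annotation: StructureAnnotation  # genome coordinates
    motif_spans: tuple[tuple[int, int], ...]


@dataclass(frozen=True)
class Substitution:
    member: int
    position: int  # 0-based
    base_from: str
    base_to: str
    compensated: bool


@dataclass(frozen=True)
class CladeTruth:
    ancestor: GenomeRecord
    members: tuple[GenomeRecord, ...]
    true_structures: tuple[StructureAnnotation, ...]
    ires_intervals: tuple[Interval, ...]
    substitution_log: tuple[Substitution, ...]


def _rand_bases(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def _concretize(rng: np.random.Generator, code: str) -> str:
    options = IUPAC_SETS[code]
    return options[rng.integers(0, len(options))]


def _sample_lengths(rng: np.random.Generator, descriptor: IresDescriptor,
                    tries: int = 200) -> dict[str, int]:
    """Element lengths whose total (with the codon) hits total_len_range."""
    lo, hi = descriptor.total_len_range
    names = []
    bounds = []
    for tok in descriptor.layout[:-1]:
        if tok.endswith(":5"):
            h = descriptor.helices[tok[:-2]]
            names.append(h.name)
            bounds.append((h.min_bp, h.max_bp, 2))  # helices count twice
        elif ":" not in tok:
            l = descriptor.loops[tok]
            names.append(l.name)
            bounds.append((l.min_len, l.max_len, 1))
    for _ in range(tries):
        lengths = {
            n: int(rng.integers(a, b + 1)) for n, (a, b, _) in zip(names, bounds)
        }
        total = 3 + sum(lengths[n] * m for n, (_, _, m) in zip(names, bounds))
        if lo <= total <= hi:
            return lengths
    raise GenerationError(
        f"could not satisfy total_len_range {descriptor.total_len_range}"
    )


def sample_ires(descriptor: IresDescriptor | None = None,
                rng: np.random.Generator | None = None,
                wobble_prob: float = 0.1) -> SampledIres:
    """Draw one sequence + true structure satisfying the descriptor.

    Helices are filled 5'-strand first and closed with complementary
    bases (wobble with probability ``wobble_prob`` where permitted);
    motif consensus strings are placed at a random offset within their
    loop with degenerate positions sampled; remaining loop positions are
    uniform.  The result is self-checked with the independent validator.
    """
    descriptor = descriptor or default_descriptor_6e()
    rng = rng or np.random.default_rng(0)
    for _ in range(50):
        out = _try_sample(descriptor, rng, wobble_prob)
        if out is not None:
            return out
    raise GenerationError("descriptor sampling failed after bounded retries")


def _try_sample(descriptor, rng, wobble_prob) -> SampledIres | None:
    lengths = _sample_lengths(rng, descriptor)
    segments: dict[str, str] = {}
    motif_spans: list[tuple[int, int]] = []
    # fill 5' strands and loops
    for tok in descriptor.layout[:-1]:
        name = tok[:-2] if ":" in tok else tok
        if tok.endswith(":5"):
            segments[tok] = _rand_bases(rng, lengths[name])
        elif ":" not in tok:
            l = descriptor.loops[name]
            seg = list(_rand_bases(rng, lengths[name]))
            if l.motif:
                off = int(rng.integers(0, lengths[name] - len(l.motif) + 1))
                for k, code in enumerate(l.motif):
                    seg[off + k] = _concretize(rng, code)
                motif_spans.append((name, off, off + len(l.motif)))
            segments[tok] = "".join(seg)
    # close helices (3' strand complements the 5' strand, antiparallel)
    for h in descriptor.helices.values():
        strand5 = list(segments[f"{h.name}:5"])
        n = len(strand5)
        forced: dict[int, str] = {}
        for off, want in h.required_pairs:
            k = off if off >= 0 else n + off
            if want == "GU":
                strand5[k] = "G" if rng.random() < 0.5 else "U"
                forced[k] = "U" if strand5[k] == "G" else "G"
            else:
                forced[k] = WC_ONLY[strand5[k]][0]
        segments[f"{h.name}:5"] = "".join(strand5)
        comp = []
        for k, base in enumerate(strand5):
            if k in forced:
                comp.append(forced[k])
                continue
            choices = COMPLEMENTS[base] if h.allow_wobble else WC_ONLY[base]
            if len(choices) > 1 and rng.random() >= wobble_prob:
                choices = WC_ONLY[base]
            comp.append(choices[int(rng.integers(0, len(choices)))])
        segments[f"{h.name}:3"] = "".join(reversed(comp))
    # choose codon and assemble
    codons = sorted(descriptor.allowed_start_codons)
    codon = codons[int(rng.integers(0, len(codons)))]
    seq_parts: list[str] = []
    coords: dict[str, Interval] = {}
    abs_motifs: list[tuple[int, int]] = []
    pos = 0
    for tok in descriptor.layout:
        part = codon if tok == "codon" else segments[tok]
        start = pos
        pos += len(part)
        seq_parts.append(part)
        if tok != "codon":
            coords[tok if ":" in tok else tok] = Interval.from_zero_based(start, pos)
            for mname, a, b in motif_spans:
                if tok == mname:
                    abs_motifs.append((start + a, start + b))
        else:
            codon_iv = Interval.from_zero_based(start, pos)
    seq = "".join(seq_parts)
    seq = _break_helix_extensions(seq, descriptor, coords, codon_iv, abs_motifs, rng)
    if seq is None:
        return None
    pairs = []
    from .energetics import pair_kind

    for h in descriptor.helices.values():
        a, b = coords[f"{h.name}:5"].start0, coords[f"{h.name}:5"].end0
        c, d = coords[f"{h.name}:3"].start0, coords[f"{h.name}:3"].end0
        for k in range(b - a):
            i, j = a + k, d - 1 - k
            pairs.append((i, j, pair_kind(seq[i], seq[j])))
    annotation = StructureAnnotation(
        element_coords=coords,
        pairs=tuple(sorted(pairs)),
        pk_groups=dict(descriptor.pk_groups),
        domains=dict(descriptor.domains),
        start_codon=codon_iv,
        start_triplet=codon,
    )
    record = GenomeRecord(id="synthetic_ires", seq=seq)
    match = IresMatch(
        annotation=annotation, score=0.0, delta_g=0.0,
        record_id=record.id, genome_interval=Interval.from_zero_based(0, len(seq)),
    )
    if validate_match(record, match, descriptor):
        return None  # rare accidental violation; caller retries
    return SampledIres(record=record, annotation=annotation,
                       motif_spans=tuple(sorted(abs_motifs)))


def _break_helix_extensions(seq: str, descriptor, coords, codon_iv,
                            abs_motifs, rng) -> str | None:
    """Mutate loop bases so no helix can be extended by a fortuitous
    complementary flank; keeps the sampled structure locally maximal so
    the matcher's best placement is the embedded truth."""
    from .energetics import pair_kind

    seq_l = list(seq)
    loop_positions: set[int] = set()
    for tok, iv in coords.items():
        if ":" not in tok:
            loop_positions.update(range(iv.start0, iv.end0))
    for a, b in abs_motifs:
        loop_positions.difference_update(range(a, b))
    for _ in range(30):
        dirty = False
        for h in descriptor.helices.values():
            a5, b5 = coords[f"{h.name}:5"].start0, coords[f"{h.name}:5"].end0
            a3, b3 = coords[f"{h.name}:3"].start0, coords[f"{h.name}:3"].end0
            for p, q in ((a5 - 1, b3), (b5, a3 - 1)):
                if p < 0 or q >= len(seq_l) or p >= q:
                    continue
                kinds_ok = pair_kind(seq_l[p], seq_l[q])
                if kinds_ok == "GU" and not h.allow_wobble:
                    continue
                if kinds_ok:
                    target = p if p in loop_positions else (q if q in loop_positions else None)
                    if target is None:
                        return None  # both flanks constrained; resample
                    other = seq_l[q] if target == p else seq_l[p]
                    options = [b for b in BASES if pair_kind(b, other) is None]
                    seq_l[target] = options[int(rng.integers(0, len(options)))]
                    dirty = True
        if not dirty:
            return "".join(seq_l)
    return None


# ---------------------------------------------------------------------------
# Genome embedding


def _random_orf(rng: np.random.Generator, n_codons: int, include_ygdd: bool) -> str:
    codons = []
    while len(codons) < n_codons:
        c = _rand_bases(rng, 3)
        if c not in STOPS:
            codons.append(c)
    if include_ygdd:
        # helicase-protease-polymerase proxy: YGDD tetrapeptide mid-ORF
        at = n_codons // 2
        codons[at : at + 4] = ["UAU", "GGU", "GAU", "GAU"]
    return "".join(codons)


def _pad_without_stops_matter(rng: np.random.Generator, n: int) -> str:
    return _rand_bases(rng, n)


def _draw_pad(ires, params, rng) -> str | None:
    """Draw IGR padding such that the ORF2-frame open run (which creeps
    5' from the initiation codon to the last in-frame stop) begins at
    least 100 nt after ORF1, the mapper's minimum IGR width.

    The IRES interior may or may not contain an in-frame stop; when it
    does not, the pad is lengthened and a stop is planted in the codon's
    frame so the open frame cannot reach back to ORF1.
    """
    seq = ires.record.seq
    c = ires.annotation.start_codon.start0
    last_internal = None
    for q in range(c % 3, c - 2, 3):
        if seq[q : q + 3] in STOPS:
            last_internal = q
    lo, hi = params.igr_padding
    if last_internal is not None:
        # gap = pad_len + last_internal + 3 must reach 100
        need = max(lo, 100 - last_internal - 3)
        if need > max(hi, need):
            return None
        pad_len = int(rng.integers(need, max(hi, need) + 1))
        return _rand_bases(rng, pad_len)
    # no internal stop: plant one in the codon's frame near the pad 5' end
    pad_len = int(rng.integers(104, 140))
    pad = list(_rand_bases(rng, pad_len))
    # offset s in the pad is in the codon frame iff (s - pad_len - c) % 3 == 0
    s = 100
    while (s - pad_len - c) % 3 != 0:
        s += 1
    if s + 3 > pad_len:
        return None
    pad[s : s + 3] = STOPS[int(rng.integers(0, 3))]
    return "".join(pad)


def _frame_open_run(seq: str, anchor0: int, frame_of: int) -> Interval:
    """Stop-to-stop open frame (1-based interval) containing anchor0 in the
    frame of position ``frame_of`` (0-based)."""
    frame = frame_of % 3
    codon_starts = range(frame, len(seq) - 2, 3)
    starts = [i for i in codon_starts]
    # locate the run boundaries around the anchor codon
    idx = (anchor0 - frame) // 3
    lo = idx
    while lo > 0 and seq[starts[lo - 1] : starts[lo - 1] + 3] not in STOPS:
        lo -= 1
    hi = idx
    while hi + 1 < len(starts) and seq[starts[hi + 1] : starts[hi + 1] + 3] not in STOPS:
        hi += 1
    return Interval.from_zero_based(starts[lo], starts[hi] + 3)


def embed_genome(ires: SampledIres, params: GeneratorParams | None = None,
                 rng: np.random.Generator | None = None) -> GenomeTruth:
    """Embed a sampled IRES in a dicistronic genome; return ground truth.

    Layout: 5' UTR, ORF1 (AUG..stop, optional YGDD), IGR padding, the
    IRES (PKI abutting the ORF2 initiation codon), ORF2 continuing in the
    codon's frame to a stop, 3' UTR.  Truth ORF intervals are the
    stop-to-stop open frames the mapper reports; drawing is retried until
    the gap between them lies inside the mapper's IGR window.
    """
    params = params or GeneratorParams()
    rng = rng or np.random.default_rng(0)
    for _ in range(60):
        truth = _try_embed(ires, params, rng)
        if truth is not None:
            return truth
    raise GenerationError("genome embedding failed after bounded retries")


def _try_embed(ires, params, rng) -> GenomeTruth | None:
    utr5 = _rand_bases(rng, int(rng.integers(*params.utr5_len)))
    n1 = int(rng.integers(*params.orf1_len_codons))
    orf1_body = _random_orf(rng, n1, params.include_ygdd)
    stop1 = STOPS[int(rng.integers(0, 3))]
    # stop in ORF1's frame right before the AUG keeps the open frame
    # aligned with the annotated ORF
    utr5 = utr5 + STOPS[int(rng.integers(0, 3))]
    ires_seq = ires.record.seq
    pad = _draw_pad(ires, params, rng)
    if pad is None:
        return None
    # ORF2: continue in the initiation codon's frame (codon is its first
    # codon, already at the 3' end of the IRES)
    n2 = int(rng.integers(*params.orf2_len_codons))
    orf2_tail = _random_orf(rng, n2, include_ygdd=False)
    stop2 = STOPS[int(rng.integers(0, 3))]
    utr3 = _rand_bases(rng, int(rng.integers(*params.utr3_len)))

    orf1_start = len(utr5)
    orf1 = "AUG" + orf1_body + stop1
    # the IRES 5' helix must not be extendable into the pad, or the
    # scanner would report a border 5' of the embedded truth
    from .energetics import pair_kind

    first_helix = ires.annotation.element_coords.get("P1.1:3")
    if first_helix is not None and pad:
        q_base = ires_seq[first_helix.end0] if first_helix.end0 < len(ires_seq) else None
        if q_base is not None and pair_kind(pad[-1], q_base) is not None:
            options = [b for b in BASES if pair_kind(b, q_base) is None]
            pad = pad[:-1] + options[int(rng.integers(0, len(options)))]
    genome = utr5 + orf1 + pad + ires_seq + orf2_tail + stop2 + utr3
    ires_start = len(utr5) + len(orf1) + len(pad)
    codon0 = ires_start + ires.annotation.start_codon.start0

    record = GenomeRecord(id="synthetic_genome", seq=genome)
    orf1_iv = Interval.from_zero_based(orf1_start, orf1_start + 3 + len(orf1_body))
    orf2_iv = _frame_open_run(genome, codon0, codon0)
    gap = orf2_iv.start - orf1_iv.end - 1
    if not (100 <= gap <= 400):
        return None
    # the ORF2 open frame must not reach back past the IGR start
    if orf2_iv.start0 <= orf1_iv.end0:
        return None
    igr_iv = Interval(orf1_iv.end + 1, orf2_iv.start - 1)
    return GenomeTruth(
        record=record,
        orf1=orf1_iv,
        orf2=orf2_iv,
        igr=igr_iv,
        ires_interval=Interval.from_zero_based(ires_start, ires_start + len(ires_seq)),
        annotation=ires.annotation.shift(ires_start),
        motif_spans=tuple((a + ires_start, b + ires_start) for a, b in ires.motif_spans),
    )


# ---------------------------------------------------------------------------
# Clade evolution


def evolve_clade(ancestor: SampledIres, params: GeneratorParams | None = None,
                 rng: np.random.Generator | None = None) -> CladeTruth:
    """Evolve ``n_taxa`` members independently from the ancestor.

    Each position mutates with ``substitution_rate``; a substitution that
    hits a paired position is accompanied, with ``compensation_prob``, by
    a partner change restoring complementarity (the restoring base chosen
    uniformly among WC and G.U options, so pairs become covariant rather
    than invariant).  Motif placements are frozen by default.
    """
    params = params or GeneratorParams()
    rng = rng or np.random.default_rng(0)
    if params.n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    seq0 = ancestor.record.seq
    partner = {}
    for i, j, _ in ancestor.annotation.pairs:
        partner[i] = j
        partner[j] = i
    frozen: set[int] = set()
    if params.freeze_motifs:
        for a, b in ancestor.motif_spans:
            frozen.update(range(a, b))
        cs = ancestor.annotation.start_codon
        frozen.update(range(cs.start0, cs.end0))

    from .energetics import pair_kind

    members: list[GenomeRecord] = []
    structures: list[StructureAnnotation] = []
    log: list[Substitution] = []
    for m in range(params.n_taxa):
        seq = list(seq0)
        touched: set[int] = set()
        hit = rng.random(len(seq)) < params.substitution_rate
        for i in range(len(seq)):
            if not hit[i] or i in frozen or i in touched:
                continue
            old = seq[i]
            if i in partner:
                if rng.random() < params.compensation_prob:
                    new = BASES[int(rng.integers(0, 4))]
                    while new == old:
                        new = BASES[int(rng.integers(0, 4))]
                    j = partner[i]
                    restoring = COMPLEMENTS[new]
                    jb = restoring[int(rng.integers(0, len(restoring)))]
                    seq[i] = new
                    log.append(Substitution(m, i, old, new, True))
                    if jb != seq[j]:
                        log.append(Substitution(m, j, seq[j], jb, True))
                        seq[j] = jb
                    touched.update((i, j))
                    continue
            new = BASES[int(rng.integers(0, 4))]
            while new == old:
                new = BASES[int(rng.integers(0, 4))]
            seq[i] = new
            log.append(Substitution(m, i, old, new, False))
            touched.add(i)
        mseq = "".join(seq)
        members.append(GenomeRecord(id=f"member_{m:02d}", seq=mseq))
        pairs = tuple(
            (i, j, pair_kind(mseq[i], mseq[j]) or "none")
            for i, j, _ in ancestor.annotation.pairs
        )
        structures.append(
            StructureAnnotation(
                element_coords=dict(ancestor.annotation.element_coords),
                pairs=pairs,
                pk_groups=dict(ancestor.annotation.pk_groups),
                domains=dict(ancestor.annotation.domains),
                start_codon=ancestor.annotation.start_codon,
                start_triplet=mseq[
                    ancestor.annotation.start_codon.start0 : ancestor.annotation.start_codon.end0
                ],
            )
        )
    span = Interval.from_zero_based(0, len(seq0))
    return CladeTruth(
        ancestor=ancestor.record,
        members=tuple(members),
        true_structures=tuple(structures),
        ires_intervals=tuple(span for _ in members),
        substitution_log=tuple(log),
    )


def replay_log(ancestor: GenomeRecord, log, member: int) -> str:
    """Re-apply a member's substitutions to the ancestor (truth check)."""
    seq = list(ancestor.seq)
    for sub in log:
        if sub.member == member:
            if seq[sub.position] != sub.base_from:
                raise ValueError(
                    f"log mismatch at {sub.position}: {seq[sub.position]} != {sub.base_from}"
                )
            seq[sub.position] = sub.base_to
    return "".join(seq)


# ---------------------------------------------------------------------------
# Decoys


def make_decoy(seq: str, rng: np.random.Generator | None = None,
               max_tries: int = 200) -> str:
    """Dinucleotide-preserving shuffle (random Eulerian walk on the
    dinucleotide multigraph, same first and last base)."""
    if len(seq) < 20:
        raise ValueError("decoy source must be >= 20 nt")
    rng = rng or np.random.default_rng(0)
    edges: dict[str, list[str]] = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    n_edges = len(seq) - 1
    for _ in range(max_tries):
        pool = {k: list(v) for k, v in edges.items()}
        for k in pool:
            rng.shuffle(pool[k])
        walk = [seq[0]]
        node = seq[0]
        while pool.get(node):
            node = pool[node].pop()
            walk.append(node)
        if len(walk) == n_edges + 1:
            out = "".join(walk)
            if out != seq:
                return out
    # fully degenerate input (e.g. homopolymer): identity is the only walk
    return seq
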