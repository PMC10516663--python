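# Methods

## The descriptor model

An IRES class is modeled as a linear grammar over a nucleotide sequence:
an ordered layout of helix strands (each helix contributes a 5′ and a 3′
strand), loops and the initiation codon, with per-element length bounds.
A placement assigns an interval to every element, contiguously, with the
codon 3′-terminal. Constraints:

- both strands of a helix must pair antiparallel, Watson–Crick
  everywhere, G·U wobble where the helix permits it; ambiguity codes
  (N etc.) never satisfy a pair or motif position;
- helices may carry mandated pairs at fixed offsets (the packaged 6e
  descriptor requires a G·U wobble at the innermost pair of P1.1, the
  junction of the P1 helices with the L1.1 loops; the requirement can be
  removed in the TOML config);
- loops may carry an IUPAC consensus motif that must occur within the
  loop with at most a configured number of mismatches;
- the total span, codon included, must fall inside the class length
  window (142–154 nt for type 6e).

### The packaged type 6e architecture

The default descriptor encodes three pseudoknots:

- **PKII / domain 1** — P1.2 crossed by P1.3, both enclosed by the
  long-range helix P1.1; the L1.1a and L1.1b loops sit at the P1.1
  junction and carry class-conserved motifs, and L1.2a/L1.2b absorb most
  of the natural length variation. A merged L1.2 loop is the degenerate
  case of one of them at zero length.
- **PKIII / domain 2** — a compact H-type pseudoknot (P2.1 crossed by
  P2.2, about five base pairs each) with no SLIV/SLV stem–loops,
  preceded by the single-stranded S1 element.
- **PKI / domain 3** — the tRNA-anticodon/mRNA mimic: hairpin P3.1 whose
  loop pairs downstream as P3.2, abutting the ORF2 initiation codon
  (GCU/ACU/ACC/UCU/UCA/UCG for this class).

The pairing plan needs two crossing layers; the serializer guarantees at
most three for any descriptor it accepts. The loop consensus strings
shipped in `data/ires6e.toml` (L1.1a `GAUNU`-like, L1.1b `AGCU`, and the
PKIII-loop motifs) are package defaults chosen to represent the
class-conserved positions reported for these loops; they are plain
configuration and should be replaced wholesale when a curated alignment
of the class is available.

### Matching

The search backtracks from the 3′ anchor: enumerate allowed codons in
the search window, place PKI immediately 5′ of the codon, and extend
element by element toward the 5′ border. Because layout order puts each
helix's 3′ strand before (in search order) its 5′ strand,
complementarity is checked the moment a helix closes, which prunes the
search hard (a random 5-bp helix closes with probability ≈ 0.007).
Remaining-length bounds prune placements that cannot reach the class
window. Every emitted placement is scored

score = w_bp · (base pairs) + w_motif · (matched motif positions) − w_energy · ΔG

with defaults w_bp = 1.0, w_motif = 2.0, w_energy = 0.1 per kcal/mol —
tuning knobs stored in the descriptor config, not measured constants.
Ties are broken by lower ΔG, then 5′-most, then shortest; the ordering
is fully deterministic. An independent validator (sharing no code with
the search) re-checks every constraint on emitted annotations; the test
suite also compares the matcher against an exhaustive placement
enumeration on reduced grammars.

The default scan threshold (score ≥ 40) is far below a typical true
match (≈ 70–78 on generated 6e elements: ~40 bp + ~16 motif positions +
2–3 from ΔG) and far above anything observed on dinucleotide-shuffled
decoys, which essentially never complete all seven helices (0/100 at
threshold in the regression test, asserted as ≤ 2 to absorb seed
sensitivity).

## Energy model

`energetics` evaluates a *given* structure (it never folds): Turner-style
nearest-neighbor tables at 37 °C, 1999 vintage, shipped as a plain-text
file with a provenance header. Terms: helix stacks; hairpin loops
(initiation by size, terminal mismatch for loops ≥ 4 nt, tetraloop
bonuses, a +0.5 terminal-AU/GU adjustment for triloops); bulges
(initiation, with the flanking stack preserved across single-nucleotide
bulges and AU/GU closure penalties otherwise); generic internal loops
(initiation + Ninio asymmetry, capped, + AU/GU closure penalties); an
affine multiloop term (3.4 + 0.4 per branch). Loops beyond 30 nt use
logarithmic extrapolation.

Simplifications, deliberate: no coaxial stacking, no dangling ends, no
exterior-loop terms, no 1×1/1×2/2×2 internal-loop lookup tables and no
sequence-dependent internal-loop mismatches. Matches are ranked
relatively, so only consistency matters; on pseudoknot-free hairpin
stems (stacks + hairpin loop) the evaluation is exact against the
published tables. The worked-example hairpin (10-bp stem, GUGA
tetraloop) evaluates to −25.80 kcal/mol with this set; the 2004-vintage
parameters give −22.90 for the same structure, which is why the 1999
vintage is the packaged default. The table file can be regenerated
entry-by-entry from an independent implementation via
`scripts/derive_nn_params.py`; one gauge choice is involved (hairpin
initiation(5) anchored at 5.70 kcal/mol, since only the sum of
initiation and terminal mismatch is observable for loops ≥ 4) and cancels
in every evaluated energy.

Pseudoknots are scored as the sum of their greedy non-crossing layers
with zero junction penalty. This is a ranking device, not a pseudoknot
thermodynamic model.

## Comparative validation

Percent identity is 100 × matches / columns over columns ungapped in
both rows — identity definitions are program-specific, so this one is
fixed and documented. Pairwise alignment is global dynamic programming
(match +1, mismatch −1, gap open −5, extend −1) through Biopython's
`PairwiseAligner`, taking its first optimal traceback for determinism.

Covariation: for each base pair of a reference structure mapped to
alignment columns, support counts members whose two bases form a WC or
G·U pair. Classes: *invariant* (all members, one identity), *covariant*
(all members with ≥ 2 identities, or support at least the strong
threshold with ≥ 2 identities), otherwise *inconsistent*. The strong
threshold is floor(f·n) with f = 0.85 by default, which reproduces the
"≥ 22 of 26 members" convention at n = 26 (a ceiling rule would give
23). Both the raw support and the set of observed identities are
reported per pair, so stricter or looser readings of "covariant" can be
recovered from the output.

Probe concordance is the fraction of chemically reactive positions that
the model leaves unpaired; wobble pairs count as paired, and positions
outside the model span are an error rather than silently ignored.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
with one explicit PCG64 generator (`numpy.random.Generator`) threaded
through every call — no global state, byte-identical output for a fixed
seed.

- `sample_ires` draws element lengths (rejection sampling into the class
  window), fills motifs at random offsets (sampling degenerate
  positions), closes helices with complementary strands (10% wobble
  where allowed, mandated pairs honored), then mutates loop flanks so no
  helix can be extended by a fortuitous complementary neighbor — the
  sampled structure is locally maximal and the matcher's best placement
  is the embedded truth. Samples are self-checked with the independent
  validator.
- `embed_genome` wraps an IRES as: 5′ UTR, AUG-initiated ORF1 (~180–280
  codons, YGDD tetrapeptide mid-ORF as an RdRp proxy), IGR padding, the
  IRES, ORF2 continuing in the codon's frame, 3′ UTR. Truth ORF
  intervals are the stop-to-stop open frames the mapper reports. The
  ORF2 frame's last stop before the codon determines how far the
  provisional ORF2 reaches back into the IGR; padding is drawn (and, for
  IRESs with no internal in-frame stop, a stop is planted in the pad) so
  the ORF1–ORF2 gap stays inside the mapper's 100–400 nt window.
- `evolve_clade` mutates each member independently at a per-site rate
  (default 0.05, 26 taxa); a substitution hitting a paired position is
  compensated with the configured probability by setting the partner to
  a restoring base chosen uniformly among WC and G·U options — pairs
  therefore become covariant rather than invariant. Motif positions and
  the codon are frozen by default. The full substitution log is
  returned and replaying it reproduces every member exactly.
- `make_decoy` is a dinucleotide-preserving Euler-walk shuffle
  (composition-matched negative controls).

What the generator does **not** emulate: indels (clade alignments are
therefore trivial and exact), codon-usage or selection structure in the
ORFs, sequencing error, and real IGR base composition beyond uniform
random with embedded motifs. Passing round-trip tests therefore show
the machinery is self-consistent at realistic sizes and noise levels,
not that the descriptor's sensitivity/specificity transfer unchanged to
real transcriptome assemblies.

## Numerical and design choices

- Coordinates: 1-based inclusive externally (reports, GFF3), 0-based
  half-open internally; the borders report counts the initiation codon,
  so a 5′ border at 1044 with codon ending 1191 is a 148-nt IRES.
- Toeprint windows: position +16 is the 16th nucleotide counting the +1
  nucleotide of the codon as 1; P-site window +16…+18, alternate
  +19…+21.
- Dot-bracket layering is greedy by ascending opening position; minimal
  for helix-family structures (checked against brute force in tests) and
  never more than three layers for descriptor output.
- ORF2 detection is stop-to-stop, not AUG-anchored (initiation is
  non-AUG); ORF-pair ties resolve by combined length, then smaller IGR,
  then 5′-most. The minimum ORF length (150 codons) is a screening
  default exposed as a flag, not a measured constant.
- Classifier length gaps (133–141, 155–160, 169–175, 194) yield
  `unclassified` with a near-type hint — the ranges are empirical, not
  definitional. Architecture conflicts in the literature about types
  6c/6d (whether 6c lacks PKII or PKIII, whether 6d's missing stem–loop
  sits on PKII or PKIII) are resolved here as: 6c = PKI + PKII without
  PKIII; 6d = PKIII with SLIV but no SLV. Codon sets for 6c/6d are
  supersets of the 6a/6b set; codon compatibility is reported as
  evidence but never decides a call.
- The scan stage extracts the IGR plus a flank long enough for a
  full-length IRES beyond the provisional ORF2 border (which is a
  stop-free-frame boundary, not the codon) and searches the whole
  extract; the standalone `extract_igr` default flank stays at 75 nt,
  matching primer placement 61–75 nt downstream of the codon.
- Reverse-strand scanning is available via sequence reverse complement
  in `orf_mapper` (several natural records are antisense assemblies);
  the pipeline default scans the + strand only.

## Known limitations

- The descriptor motifs are configuration defaults, not a curated
  class alignment; sensitivity on real sequences depends on replacing
  them.
- The energy model's internal-loop terms are generic; do not use the
  absolute ΔG of internally-looped structures for thermodynamic claims.
- Pseudoknot energies are layer sums; they order candidate placements
  but have no physical junction term.
- The matcher's worst case is exponential in principle; in practice the
  complementarity and length-budget pruning keep 260-nt windows around a
  quarter of a second, but adversarial low-complexity sequences (long
  complementary repeats) can be slow — `MatchParams.max_solutions`
  bounds the enumeration.
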