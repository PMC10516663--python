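# Default structural descriptor for type 6e (Wenling-class) IGR IRESs.
#
# Architecture: three pseudoknots.  Domain 1 (PKII) is built from P1.1,
# P1.2 and P1.3, with P1.3 crossing P1.2 and the long-range P1.1 closing
# the domain; the invariant G.U wobble sits on P1.1's innermost pair, at
# the junction with the L1.1a/L1.1b loops.  Domain 2 (PKIII) is a compact
# H-type pseudoknot (P2.1 crossed by P2.2) with no SLIV/SLV stem-loops,
# preceded by the single-stranded S1 element.  Domain 3 (PKI) is the
# tRNA-anticodon/mRNA mimic: hairpin P3.1 whose loop pairs downstream as
# P3.2, abutting the ORF2 initiation codon.
#
# Loop consensus motifs are package defaults chosen to represent the
# class-conserved L1.1a/L1.1b and PKIII sequences; they are configurable
# and can be replaced wholesale from curated alignments.

name = "6e"
total_len = [142, 154]
start_codons = ["GCU", "ACU", "ACC", "UCU", "UCA", "UCG"]
pk3_is_h_type = true

layout = [
    "P1.1:5", "L1.1a", "P1.2:5", "L1.2a", "P1.3:5", "L1.2b", "P1.2:3",
    "S1", "P2.1:5", "L2.1a", "P2.2:5", "L2.1b", "P2.1:3", "L2.2", "P2.2:3",
    "P1.3:3", "L1.1b", "P1.1:3",
    "P3.1:5", "L3.1a", "P3.2:5", "L3.2", "P3.1:3", "P3.2:3", "codon",
]

[pk_groups]
PKI = ["P3.1", "P3.2"]
PKII = ["P1.1", "P1.2", "P1.3"]
PKIII = ["P2.1", "P2.2"]

[domains]
1 = ["P1.1", "L1.1a", "P1.2", "L1.2a", "P1.3", "L1.2b", "L1.1b"]
2 = ["S1", "P2.1", "L2.1a", "P2.2", "L2.1b", "L2.2"]
3 = ["P3.1", "L3.1a", "P3.2", "L3.2"]

[score]
w_bp = 1.0
w_motif = 2.0
w_energy = 0.1

[[helix]]
name = "P1.1"
min_bp = 3
max_bp = 5
allow_wobble = true
# innermost pair (offset -1) is the invariant junction wobble; relax by
# removing this entry
required_pairs = [[-1, "GU"]]

[[helix]]
name = "P1.2"
min_bp = 5
max_bp = 11
allow_wobble = true

[[helix]]
name = "P1.3"
min_bp = 4
max_bp = 6
allow_wobble = true

[[helix]]
name = "P2.1"
min_bp = 4
max_bp = 6
allow_wobble = true

[[helix]]
name = "P2.2"
min_bp = 4
max_bp = 6
allow_wobble = true

[[helix]]
name = "P3.1"
min_bp = 5
max_bp = 7
allow_wobble = true

[[helix]]
name = "P3.2"
min_bp = 4
max_bp = 6
allow_wobble = true

[[loop]]
name = "L1.1a"
min_len = 5
max_len = 9
motif = "GAUUU"
max_mismatch = 0

[[loop]]
name = "L1.2a"
min_len = 3
max_len = 8

[[loop]]
name = "L1.2b"
min_len = 3
max_len = 8

[[loop]]
name = "S1"
min_len = 4
max_len = 10

[[loop]]
name = "L2.1a"
min_len = 3
max_len = 6
motif = "ACA"
max_mismatch = 0

[[loop]]
name = "L2.1b"
min_len = 2
max_len = 5

[[loop]]
name = "L2.2"
min_len = 4
max_len = 8
motif = "AUCA"
max_mismatch = 1

[[loop]]
name = "L1.1b"
min_len = 4
max_len = 8
motif = "AGCU"
max_mismatch = 0

[[loop]]
name = "L3.1a"
min_len = 3
max_len = 7

[[loop]]
name = "L3.2"
min_len = 4
max_len = 8
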