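# Nearest-neighbor RNA free-energy parameters, 37 C, kcal/mol.
# Turner-group 1999 vintage; entries transcribed by solving
# single-feature probe structures evaluated with ViennaRNA
# (RNAeval -d0, rna_turner1999.par).  Regenerate with
# scripts/derive_nn_params.py.  Hairpin initiation(5) anchored
# at 5.70 to fix the initiation/mismatch gauge.
TERMINAL_AU 0.50
LXC 1.0676
NINIO 0.50 3.00
INTERNAL_AU 0.70
BULGE_AU 0.50
MULTI 3.40 0.40 0.00
STACK
CG CG   -3.30
CG GC   -2.40
CG AU   -2.10
CG UA   -2.10
CG GU   -1.40
CG UG   -2.10
GC CG   -3.40
GC GC   -3.30
GC AU   -2.40
GC UA   -2.20
GC GU   -1.50
GC UG   -2.50
AU CG   -2.20
AU GC   -2.10
AU AU   -0.90
AU UA   -1.10
AU GU   -0.60
AU UG   -1.40
UA CG   -2.40
UA GC   -2.10
UA AU   -1.30
UA UA   -0.90
UA GU   -1.00
UA UG   -1.30
GU CG   -2.50
GU GC   -2.10
GU AU   -1.30
GU UA   -1.40
GU GU   -0.50
GU UG    1.30
UG CG   -1.50
UG GC   -1.40
UG AU   -1.00
UG UA   -0.60
UG GU    0.30
UG UG   -0.50
HAIRPIN
3    5.70
4    5.70
5    5.70
6    5.50
7    6.00
8    5.70
9    6.50
10    6.60
11    6.70
12    6.80
13    6.88
14    6.96
15    7.04
16    7.11
17    7.17
18    7.23
19    7.29
20    7.35
21    7.40
22    7.45
23    7.50
24    7.54
25    7.59
26    7.63
27    7.67
28    7.71
29    7.75
30    7.79
TSTACKH
CG A A   -1.60
CG A C   -1.60
CG A G   -1.50
CG A U   -1.90
CG C A   -1.10
CG C C   -1.00
CG C G   -3.00
CG C U   -0.90
CG G A   -2.30
CG G C   -2.10
CG G G   -1.70
CG G U   -1.20
CG U A   -1.80
CG U C   -1.50
CG U G   -1.90
CG U U   -2.10
GC A A   -1.20
GC A C   -1.60
GC A G   -1.40
GC A U   -2.20
GC C A   -1.20
GC C C   -0.80
GC C G   -2.50
GC C U   -0.60
GC G A   -2.50
GC G C   -3.00
GC G G   -1.50
GC G U   -1.30
GC U A   -2.00
GC U C   -1.10
GC U G   -2.30
GC U U   -1.60
AU A A   -0.40
AU A C   -0.60
AU A G   -0.40
AU A U   -0.40
AU C A   -0.20
AU C C   -0.30
AU C G   -1.60
AU C U   -0.30
AU G A   -1.20
AU G C   -1.30
AU G G   -0.30
AU G U    0.10
AU U A   -0.40
AU U C   -0.40
AU U G   -0.70
AU U U   -1.20
UA A A   -0.60
UA A C   -0.40
UA A G   -0.70
UA A U   -0.60
UA C A   -0.30
UA C C   -0.20
UA C G   -1.30
UA C U   -0.10
UA G A   -1.50
UA G C   -1.30
UA G G   -0.80
UA G U   -0.30
UA U A   -0.40
UA U C   -0.20
UA U G   -0.60
UA U U   -0.90
GU A A    0.10
GU A C   -0.60
GU A G   -0.40
GU A U   -0.40
GU C A   -0.20
GU C C   -0.30
GU C G   -1.60
GU C U   -0.30
GU G A   -1.00
GU G C   -1.20
GU G G   -0.40
GU G U   -0.10
GU U A   -0.40
GU U C   -0.40
GU U G   -0.50
GU U U   -1.20
UG A A   -0.60
UG A C   -0.40
UG A G   -0.70
UG A U   -0.60
UG C A   -0.30
UG C C   -0.20
UG C G   -1.80
UG C U   -0.10
UG G A   -0.90
UG G C   -1.30
UG G G   -0.40
UG G U   -0.80
UG U A   -0.70
UG U C   -0.20
UG U G   -0.70
UG U U   -0.90
TETRALOOP
AGAAAU   -2.00
AGCAAU   -1.50
AGUAAU   -1.50
AGUGAU   -1.50
CGAAAG   -3.00
CGAAGG   -2.50
CGAGAG   -2.00
CGCAAG   -3.00
CGCGAG   -2.50
CGGAAG   -3.00
CGGGAG   -1.50
CGUAAG   -2.00
CGUGAG   -3.00
CUAACG   -2.00
CUACGG   -2.50
CUUCGG   -3.00
GGAAAC   -3.00
GGAAGC   -1.50
GGAGAC   -3.00
GGCAAC   -2.50
GGCGAC   -1.50
GGGAAC   -1.50
GGGAGC   -1.50
GGGGAC   -3.00
GGUGAC   -3.00
GUGAAC   -1.50
UGAAAA   -1.50
UGAAAG   -2.00
UGAGAG   -2.50
UGGAAA   -1.50
BULGE
1    3.80
2    2.80
3    3.20
4    3.60
5    4.00
6    4.40
7    4.59
8    4.70
9    4.80
10    4.90
11    5.00
12    5.10
13    5.19
14    5.27
15    5.34
16    5.41
17    5.48
18    5.54
19    5.60
20    5.65
21    5.71
22    5.76
23    5.80
24    5.85
25    5.89
26    5.94
27    5.98
28    6.02
29    6.05
30    6.09
INTERNAL
4    1.70
5    1.80
6    2.00
7    2.20
8    2.30
9    2.40
10    2.50
11    2.60
12    2.70
13    2.78
14    2.86
15    2.94
16    3.01
17    3.07
18    3.13
19    3.19
20    3.25
21    3.30
22    3.35
23    3.40
24    3.45
25    3.49
26    3.53
27    3.57
28    3.61
29    3.65
30    3.69
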