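# Compact dangle-free nearest-neighbor RNA energy table (kcal/mol, 37 C).
# Grammar: scalar entries are 'key value'; a bare section name starts a
# table.  'stacking' rows are 'outer_pair inner_pair dG' where outer is the
# 5'-side closing pair (i,j) and inner the stacked pair (i+1,j-1).  Loop
# initiation rows are 'size dG'; sizes beyond the table are extrapolated as
# dG(max) + loop_extrapolation * ln(size/max).

gas_constant 0.0019872
temperature 310.15
terminal_au_penalty 0.5
multiloop_offset 3.4
multiloop_branch 0.4
multiloop_unpaired 0.0
loop_extrapolation 1.08

stacking
AU AU -0.90
AU CG -2.20
AU GC -2.10
AU UA -1.10
AU GU -0.60
AU UG -1.40
CG AU -2.10
CG CG -3.30
CG GC -2.40
CG UA -2.10
CG GU -1.40
CG UG -2.10
GC AU -2.40
GC CG -3.40
GC GC -3.30
GC UA -2.20
GC GU -1.50
GC UG -2.50
UA AU -1.30
UA CG -2.40
UA GC -2.10
UA UA -0.90
UA GU -1.00
UA UG -1.30
GU AU -1.30
GU CG -2.50
GU GC -2.10
GU UA -1.40
GU GU -0.50
GU UG 1.30
UG AU -1.00
UG CG -1.50
UG GC -1.40
UG UA -0.60
UG GU 0.30
UG UG -0.50


hairpin_initiation
3 5.40
4 5.60
5 5.70
6 5.40
7 6.00
8 5.50
9 6.40
10 6.51
11 6.62
12 6.71
13 6.80
14 6.88
15 6.95
16 7.02
17 7.09
18 7.15
19 7.21
20 7.26
21 7.32
22 7.37
23 7.41
24 7.46
25 7.50
26 7.55
27 7.59
28 7.63
29 7.66
30 7.70

bulge_initiation
1 3.80
2 2.80
3 3.20
4 3.60
5 4.00
6 4.40
7 4.57
8 4.71
9 4.84
10 4.95
11 5.05
12 5.15
13 5.24
14 5.32
15 5.39
16 5.46
17 5.52
18 5.59
19 5.64
20 5.70
21 5.75
22 5.80
23 5.85
24 5.90
25 5.94
26 5.98
27 6.02
28 6.06
29 6.10
30 6.14

internal_initiation
2 4.10
3 5.10
4 4.90
5 5.30
6 5.70
7 5.87
8 6.01
9 6.14
10 6.25
11 6.35
12 6.45
13 6.54
14 6.62
15 6.69
16 6.76
17 6.82
18 6.89
19 6.94
20 7.00
21 7.05
22 7.10
23 7.15
24 7.20
25 7.24
26 7.28
27 7.32
28 7.36
29 7.40
30 7.44
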