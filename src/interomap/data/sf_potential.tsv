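# hydrogen-bond/electrostatic contact potential v1 (donor-acceptor/charge complementarity)
# symmetric residue-pair contact scores; rows/cols in header order
       A      R      N      D      C      Q      E      G      H      I      L      K      M      F      P      S      T      W      Y      V
A   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
R   0.00  -0.50   0.75   2.50   0.00   0.75   2.50   0.00   1.50   0.00   0.00  -0.50   0.00   0.00   0.00   0.75   0.75   0.00   0.75   0.00
N   0.00   0.75   0.50   0.50   0.00   0.50   0.50   0.00   1.00   0.00   0.00   0.25   0.00   0.00   0.00   0.50   0.50   0.25   0.50   0.00
D   0.00   2.50   0.50  -0.50   0.00   0.50  -0.50   0.00   1.00   0.00   0.00   1.50   0.00   0.00   0.00   0.50   0.50   0.50   0.50   0.00
C   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
Q   0.00   0.75   0.50   0.50   0.00   0.50   0.50   0.00   1.00   0.00   0.00   0.25   0.00   0.00   0.00   0.50   0.50   0.25   0.50   0.00
E   0.00   2.50   0.50  -0.50   0.00   0.50  -0.50   0.00   1.00   0.00   0.00   1.50   0.00   0.00   0.00   0.50   0.50   0.50   0.50   0.00
G   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
H   0.00   1.50   1.00   1.00   0.00   1.00   1.00   0.00   2.00   0.00   0.00   0.50   0.00   0.00   0.00   1.00   1.00   0.50   1.00   0.00
I   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
L   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
K   0.00  -0.50   0.25   1.50   0.00   0.25   1.50   0.00   0.50   0.00   0.00  -0.50   0.00   0.00   0.00   0.25   0.25   0.00   0.25   0.00
M   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
F   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
P   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
S   0.00   0.75   0.50   0.50   0.00   0.50   0.50   0.00   1.00   0.00   0.00   0.25   0.00   0.00   0.00   0.50   0.50   0.25   0.50   0.00
T   0.00   0.75   0.50   0.50   0.00   0.50   0.50   0.00   1.00   0.00   0.00   0.25   0.00   0.00   0.00   0.50   0.50   0.25   0.50   0.00
W   0.00   0.00   0.25   0.50   0.00   0.25   0.50   0.00   0.50   0.00   0.00   0.00   0.00   0.00   0.00   0.25   0.25   0.00   0.25   0.00
Y   0.00   0.75   0.50   0.50   0.00   0.50   0.50   0.00   1.00   0.00   0.00   0.25   0.00   0.00   0.00   0.50   0.50   0.25   0.50   0.00
V   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
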