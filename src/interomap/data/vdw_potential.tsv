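# van der Waals contact potential v1 (Kyte-Doolittle packing surrogate)
# symmetric residue-pair contact scores; rows/cols in header order
       A      R      N      D      C      Q      E      G      H      I      L      K      M      F      P      S      T      W      Y      V
A   0.98   0.00   0.16   0.16   1.09   0.16   0.16   0.64   0.20   1.40   1.29   0.09   1.00   1.14   0.45   0.58   0.59   0.56   0.50   1.35
R   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00   0.00
N   0.16   0.00   0.02   0.02   0.17   0.02   0.02   0.10   0.03   0.22   0.20   0.01   0.16   0.18   0.07   0.09   0.09   0.09   0.08   0.21
D   0.16   0.00   0.02   0.02   0.17   0.02   0.02   0.10   0.03   0.22   0.20   0.01   0.16   0.18   0.07   0.09   0.09   0.09   0.08   0.21
C   1.09   0.00   0.17   0.17   1.21   0.17   0.17   0.71   0.22   1.56   1.43   0.10   1.11   1.26   0.50   0.64   0.66   0.62   0.55   1.50
Q   0.16   0.00   0.02   0.02   0.17   0.02   0.02   0.10   0.03   0.22   0.20   0.01   0.16   0.18   0.07   0.09   0.09   0.09   0.08   0.21
E   0.16   0.00   0.02   0.02   0.17   0.02   0.02   0.10   0.03   0.22   0.20   0.01   0.16   0.18   0.07   0.09   0.09   0.09   0.08   0.21
G   0.64   0.00   0.10   0.10   0.71   0.10   0.10   0.42   0.13   0.91   0.84   0.06   0.65   0.74   0.29   0.37   0.38   0.36   0.32   0.88
H   0.20   0.00   0.03   0.03   0.22   0.03   0.03   0.13   0.04   0.29   0.27   0.02   0.21   0.23   0.09   0.12   0.12   0.12   0.10   0.28
I   1.40   0.00   0.22   0.22   1.56   0.22   0.22   0.91   0.29   2.00   1.84   0.13   1.42   1.62   0.64   0.82   0.84   0.80   0.71   1.93
L   1.29   0.00   0.20   0.20   1.43   0.20   0.20   0.84   0.27   1.84   1.70   0.12   1.31   1.50   0.59   0.76   0.78   0.74   0.66   1.78
K   0.09   0.00   0.01   0.01   0.10   0.01   0.01   0.06   0.02   0.13   0.12   0.01   0.09   0.11   0.04   0.05   0.06   0.05   0.05   0.13
M   1.00   0.00   0.16   0.16   1.11   0.16   0.16   0.65   0.21   1.42   1.31   0.09   1.01   1.15   0.46   0.58   0.60   0.57   0.51   1.37
F   1.14   0.00   0.18   0.18   1.26   0.18   0.18   0.74   0.23   1.62   1.50   0.11   1.15   1.32   0.52   0.67   0.68   0.65   0.58   1.57
P   0.45   0.00   0.07   0.07   0.50   0.07   0.07   0.29   0.09   0.64   0.59   0.04   0.46   0.52   0.21   0.26   0.27   0.26   0.23   0.62
S   0.58   0.00   0.09   0.09   0.64   0.09   0.09   0.37   0.12   0.82   0.76   0.05   0.58   0.67   0.26   0.34   0.35   0.33   0.29   0.79
T   0.59   0.00   0.09   0.09   0.66   0.09   0.09   0.38   0.12   0.84   0.78   0.06   0.60   0.68   0.27   0.35   0.36   0.34   0.30   0.82
W   0.56   0.00   0.09   0.09   0.62   0.09   0.09   0.36   0.12   0.80   0.74   0.05   0.57   0.65   0.26   0.33   0.34   0.32   0.28   0.77
Y   0.50   0.00   0.08   0.08   0.55   0.08   0.08   0.32   0.10   0.71   0.66   0.05   0.51   0.58   0.23   0.29   0.30   0.28   0.25   0.69
V   1.35   0.00   0.21   0.21   1.50   0.21   0.21   0.88   0.28   1.93   1.78   0.13   1.37   1.57   0.62   0.79   0.82   0.77   0.69   1.87
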