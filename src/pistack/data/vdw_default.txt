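# Default exp-6 van der Waals parameters for the sigma/pi potential.
# Pair term: k_i k_j (C e^{-alpha R} - A R^-6), kcal/mol with R in Angstrom.
# Calibration set validated against the qualitative surface shapes the
# potential is known for (double-well z = 3.5 A slice of the parallel
# benzene dimer with exaggerated lateral minima, T-shape minimum near
# z ~ 5 A): the scalars give a carbon-carbon pair well of 0.09 kcal/mol
# at R* = 3.8 A.
C 16743.0
alpha 3.2
A 534.93
r_min_guard 1.0
k C 1.0
k H 0.45
k N 0.95
k O 0.95
k F 0.9
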