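# Benzene sigma/pi charge set.
# Per-site q_pi = -0.50 (twelve pi sites summing to the exact -6 pi-electron
# charge) with pi-site pairs at delta = 0.47 A along the ring normal.  The
# C/H sigma split is not an ab initio value: it is calibrated so the model
# quadrupole matches the experimental benzene Theta_zz (~ -8.7 D A); with
# the template geometry that pins C +0.96 / H +0.04 (per-CH total +1.0).
name benzene
delta 0.47
n_pi_electrons 6
# index element q_sigma q_pi
0 C 0.96 -0.50
1 C 0.96 -0.50
2 C 0.96 -0.50
3 C 0.96 -0.50
4 C 0.96 -0.50
5 C 0.96 -0.50
6 H 0.04 -
7 H 0.04 -
8 H 0.04 -
9 H 0.04 -
10 H 0.04 -
11 H 0.04 -
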