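# Hexafluorobenzene sigma/pi charge set (validator exercise; no shipped
# template geometry).  Ring carbons are pi-rich at -0.54 per site; the
# fluorines carry pi-site pairs for their in-pi lone pairs, making
# n_pi_electrons = 18, with per-site charges closing the -18 pi sum.
# Sigma values are documented placeholders chosen for neutrality.
# Atom order: C(0..5), F(6..11).
name hexafluorobenzene
delta 0.47
n_pi_electrons 18
# index element q_sigma q_pi
0 C 1.08 -0.54
1 C 1.08 -0.54
2 C 1.08 -0.54
3 C 1.08 -0.54
4 C 1.08 -0.54
5 C 1.08 -0.54
6 F 1.92 -0.96
7 F 1.92 -0.96
8 F 1.92 -0.96
9 F 1.92 -0.96
10 F 1.92 -0.96
11 F 1.92 -0.96
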