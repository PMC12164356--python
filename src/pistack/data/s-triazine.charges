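# s-Triazine sigma/pi charge set.
# Pi values: ring N -0.53 (pi-rich), ring C -0.47 (pi-poor);
# 2 * 3 * (-0.53) + 2 * 3 * (-0.47) = -6.00 exactly.
# Sigma values are documented placeholders consistent with the benzene
# split (H +0.04) and chosen for neutrality.
# Atom order: N(0) C(1) N(2) C(3) N(4) C(5), then H on C1, C3, C5.
name s-triazine
delta 0.47
n_pi_electrons 6
# index element q_sigma q_pi
0 N 1.10 -0.53
1 C 0.86 -0.47
2 N 1.10 -0.53
3 C 0.86 -0.47
4 N 1.10 -0.53
5 C 0.86 -0.47
6 H 0.04 -
7 H 0.04 -
8 H 0.04 -
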