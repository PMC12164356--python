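# Default Gaussian-Pauli + damped-dispersion parameters.
# Pauli: a e^{-alpha R^2}; dispersion: -[f6(beta R) C6/R^6 + f8(beta R) C8/R^8].
# Calibration set validated against the model's known qualitative behavior
# for the parallel benzene dimer: a double-well slice at z = 3.5 A but a
# single 2-D minimum at x = 0 near z = 3.9 A (on the default scan lattice).
prefactor_form constant
z_floor 3.5
# pair class1 class2 a(kcal/mol) alpha(1/A^2) beta(1/A) C6(kcal A^6/mol) C8(kcal A^8/mol)
pair C C 106500.0 1.00 1.30 1030.0 12360.0
pair C H 29820.0 1.20 1.43 247.0 2470.0
pair H H 8520.0 1.55 1.63 62.0 515.0
pair C N 103000.0 1.02 1.31 960.0 11500.0
pair N N 99000.0 1.05 1.32 890.0 10700.0
pair N H 28500.0 1.22 1.44 230.0 2300.0
pair C O 99500.0 1.05 1.32 900.0 10800.0
pair O O 93000.0 1.10 1.34 790.0 9500.0
pair O H 27000.0 1.25 1.46 215.0 2150.0
pair N O 96000.0 1.07 1.33 840.0 10100.0
pair C F 94000.0 1.08 1.33 820.0 9800.0
pair F F 83000.0 1.15 1.36 650.0 7800.0
pair F H 25000.0 1.28 1.48 195.0 1950.0
pair N F 90500.0 1.10 1.34 760.0 9100.0
pair O F 87800.0 1.12 1.35 715.0 8600.0
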