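# Per-element constants used by the charge-equilibration weight kernels.
# Columns: symbol, Z (atomic number), chi_S (Sanderson electronegativity,
# revised scale, dimensionless), chi_P (Pauling electronegativity,
# dimensionless), r_cov (covalent radius, Angstrom, Cordero et al. 2008;
# C is the sp3 value).
# Only ratios of these quantities within one molecule enter the weights.
symbol,Z,chi_S,chi_P,r_cov
H,1,2.59,2.20,0.31
C,6,2.75,2.55,0.76
N,7,3.19,3.04,0.71
O,8,3.65,3.44,0.66
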