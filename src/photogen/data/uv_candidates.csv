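# 17 candidate molecules with first-excitation wavelengths (nm) from
# vertical-excitation calculations in three environments.
smiles,gas_nm,water_nm,organic_nm
CCC(N)CC,190,178,181
OC1CC1OC(C)C,191,177,180
CCC(N)C(C)C,193,182,185
CC(CN)C(C),193,181,184
CC(C)C(C)CN,197,187,190
CCC(N)CCO,199,181,185
COCC1CCN1,201,189,192
CNC=CCC,231,219,222
CC(C(Cl)N)S=N,226,305,218
C1=C=C=N1,235,235,235
NCCCC1SC1,251,246,247
C=CC=NSN=C,286,288,291
C=C=C=NN=C,468,445,451
CC1CC=C=C1,492,696,605
CC1C=C=NC1,631,644,648
CC1NC(C)=C=C1,733,481,529
CC1=NC=C=N1,749,736,739
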