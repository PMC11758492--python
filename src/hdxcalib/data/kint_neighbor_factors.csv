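# Poly-DL-alanine-referenced neighbour correction factors for backbone amide
# hydrogen exchange (log10 scale), NMR-derived residue-specific model.
# lambda_*: effect of a residue's side chain on its OWN amide.
# rho_*:    effect of a residue's side chain on the NEXT residue's amide.
# acid / base label the catalysis pathway (the water pathway uses the base factors).
# D/E are the deprotonated (carboxylate) forms, H the protonated (imidazolium) form.
# N_TERM is the free protonated alpha-amine (applies rho to residue 2's amide);
# C_TERM_ACID is the deprotonated C-terminal carboxylate (applies lambda to the
# final residue's amide). ACETYL contributes no correction.
# version: 1
residue,lambda_acid,rho_acid,lambda_base,rho_base
A,0.00,0.00,0.00,0.00
C,-0.54,-0.46,0.62,0.55
D,0.90,0.58,0.10,-0.18
E,-0.90,0.31,-0.11,-0.15
F,-0.52,-0.43,-0.24,0.06
G,-0.22,0.22,0.27,0.17
H,-0.80,-0.51,0.80,0.83
I,-0.91,-0.59,-0.73,-0.23
K,-0.56,-0.29,-0.04,0.12
L,-0.57,-0.13,-0.58,-0.21
M,-0.64,-0.28,-0.01,0.11
N,-0.58,-0.13,0.49,0.32
P,0.00,-0.19,0.00,-0.24
Q,-0.47,-0.27,0.06,0.20
R,-0.59,-0.32,0.08,0.22
S,-0.44,-0.39,0.37,0.30
T,-0.79,-0.47,-0.07,0.20
V,-0.74,-0.30,-0.70,-0.14
W,-0.40,-0.44,-0.41,-0.11
Y,-0.41,-0.37,-0.27,0.05
N_TERM,0.00,-1.32,0.00,1.62
C_TERM_ACID,0.96,0.00,-1.80,0.00
ACETYL,0.00,0.00,0.00,0.00
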