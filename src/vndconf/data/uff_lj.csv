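# UFF nonbonded Lennard-Jones parameters (subset)
# element, epsilon (kcal/mol, well depth D_I), sigma (Angstrom, vdW distance x_I)
element,epsilon_kcal_mol,sigma_angstrom
H,0.044,2.886
C,0.105,3.851
N,0.069,3.660
O,0.060,3.500
P,0.305,4.147
S,0.274,4.035
Cl,0.227,3.947
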