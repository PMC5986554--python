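condition,kn_per_s,ke_per_mol_s
alone,3.73e-6,3.378
DOPC,5.97e-6,1.968
Chol,2.74e-6,5.573
7keto,4.4e-6,1.227
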