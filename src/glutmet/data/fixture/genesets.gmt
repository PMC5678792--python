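R1	uptake|synthetic reactant 1	R1G1	R1G2	R1G3	R1G4	R1G5
R2	uptake|synthetic reactant 2	R2G1	R2G2	R2G3	R2G4	R2G5
PROD	synthesis|synthetic product	PRODG1	PRODG2	PRODG3	PRODG4	PRODG5	PRODG6
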