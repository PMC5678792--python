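A1	uptake|Glutamine uptake	SLC1A5	SLC38A1	SLC38A2	SLC38A3	SLC38A5
A2	synthesis|Glutamine synthesis	GLUL
A3	uptake|Glutamate uptake	SLC1A1	SLC1A2	SLC1A3	SLC1A6	SLC1A7
A4	synthesis|Glutamate synthesis	GLS	GLS2	PFAS	GMPS	CAD	CTPS	CTPS2
B1	synthesis|Purine de novo synthesis from glutamine	PPAT
B2	synthesis|Purine synthesis by salvage from adenosine	APRT	ADA	ADK
B3	synthesis|Purine synthesis by salvage from guanosine	APRT	HPRT1
B4	synthesis|Purine synthesis by salvage from inosine	HPRT1
B5	uptake|Adenosine uptake	SLC28A1	SLC28A2	SLC28A3	SLC29A1	SLC29A2	SLC29A3	SLC29A4
B6	uptake|Guanosine uptake	SLC28A2	SLC28A3	SLC29A1	SLC29A2	SLC29A3
B7	uptake|Inosine uptake	SLC28A2	SLC28A3
C1	synthesis|Pyrimidine de novo synthesis from glutamine	CAD
C2	synthesis|Pyrimidine synthesis by salvage from cytidine	UCK1	UCK2	UCKL1
C3	synthesis|Pyrimidine synthesis by salvage from uridine	UCK1	UCK2	UCKL1	UPP1	UPP2	UPRT
C4	uptake|Cytidine uptake	SLC28A1	SLC28A2	SLC28A3	SLC29A1	SLC29A2	SLC29A3
C5	uptake|Uridine uptake	SLC28A1	SLC28A2	SLC28A3	SLC29A1	SLC29A2	SLC29A3
D1	rate_limiting|Glycolysis	HK1	HK2	HK3	HKDC1	GCK	PFKL	PFKM	PFKP	PKLR	PKM2
D2	rate_limiting|Oxidative phosphorylation	ATP5A1	ATP5B	ATP5C1	ATP5D	ATP5E	ATP5F1	ATP5G1	ATP5G2	ATP5G3	ATP5H	ATP5I	ATP5J	ATP5J2	ATP5L	ATP5O
D3	uptake|Glucose uptake	SLC2A1	SLC2A2	SLC2A3	SLC2A4	SLC2A5	SLC2A6	SLC2A8	SLC2A9	SLC2A10	SLC2A12	SLC2A14	SLC5A2	SLC5A1	SLC5A4	SLC5A9	SLC5A10
E1	synthesis|Lipid synthesis	ACACA	ACACB	FASN
E2	uptake|Lipid uptake	FABP1	FABP2	FABP3	FABP4	FABP5	FABP6	FABP7	FABP12	APOBR	CD36	CXCL16	ILDR1	LDLR	LRP1	LRP10	LRP12	LRP2	LRP6	LRP8	OLR1	SCARB1	STAB1	STAB2	VLDLR
F1	synthesis|UDP-GlcNAc synthesis from glutamine	HK1	HK2	HK3	HKDC1	GCK	GFPT1	GFPT2
F2	synthesis|UDP-GlcNAc synthesis from glucosamine	HK1	HK2	HK3	HKDC1	GNPNAT1	PGM3	UAP1	UAP1L1
F3	uptake|Glucosamine uptake	SLC2A2
G1	synthesis|Asparagine synthesis from glutamine	ASNS
G2	uptake|Asparagine uptake	SLC1A5	SLC38A3	SLC38A7
G3	exchange|Exchange of asparagine for other amino acids	SLC1A4	SLC7A1	SLC7A5
H1	synthesis|Proline synthesis from glutamine	ALDH18A1	PYCR1	PYCR2	PYCRL
H2	synthesis|Proline synthesis from arginine	ARG1	ARG2	OAT	PYCR1	PYCR2	PYCRL
H3	uptake|Proline uptake	SLC1A4	SLC6A7	SLC6A15	SLC36A4	SLC36A1	SLC36A2	SLC36A3
H4	uptake|Arginine uptake	SLC7A1	SLC7A2	SLC7A3	PQLC2
H5	synthesis|Arginine synthesis	ASS1
I1	synthesis|Serine synthesis from glutamine	PHGDH	PSAT1	PSPH
I2	uptake|Serine uptake	SLC1A4	SLC1A5	SLC7A1	SLC7A5	SLC7A10	SLC38A7	SERINC1	SERINC2	SERINC3	SERINC4	SERINC5
J1	synthesis|GSH synthesis from glutamate	GCLC	GCLM	GSS
J2	antioxidant|TXN and catalase synthesis	TXN	TXNRD1	TXNRD2	CAD
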