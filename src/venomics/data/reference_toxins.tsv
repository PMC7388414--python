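# Published reference table of mature toxins identified and validated in
# Acanthoscurria rondoniae venom (peptidomic fraction).
# printed_mass: monoisotopic mass (Da) as printed in the source table; for some
# entries this is the observed rather than the sequence-derived theoretical mass.
# modifications: catalog annotations required for the printed mass
# (acetylation = N-terminal acetyl; amidation = C-terminal amide formed by
# loss of the glycine donor when the sequence ends in G).
# family: new cysteine-rich peptide (CRP) family label; blank for short
# peptides and for the previously described U1-TRTX-Agm3a.
toxin_id	printed_mass	sequence	aa	ss_bonds	log_intensity	rank	modifications	is_crp	family
PLPVFV	670.41	PLPVFV	6	0	6.38	15		False
VVVPFVV	757.47	VVVPFVV	7	0	8.54	9		False
VENLAEP	770.39	VENLAEP	7	0	8.78	8		False
VLPPLKF	812.40	VLPPLKF	7	0	7.60	13		False
VPPILKY	828.51	VPPILKY	7	0	5.91	18		False
YPPPPPPPH	997.50	YPPPPPPPH	9	0	6.21	16		False
FETPNNPDGKVTKQE	1702.82	FETPNNPDGKVTKQE	15	0	6.08	17		False
U1-TRTX-Agm3a	3690.49	ACGSFMWKCSERLPCCQEYVCSPQWKWCQNP	31	3	9.49	2		True
U1-TRTX-Ar1a	3852.54	SCVHERETCSKVRGPLCCRGECTCPIYGDCFCYGS	35	4	9.08	4		True	U1-TRTX-Ar1
U1-TRTX-Ar1b	3920.58	SCVYERETCSKVRGPLCCRGECTCPIYGDCFCYGS	35	4	8.05	12	acetylation	True	U1-TRTX-Ar1
U2-TRTX-Ar1a	4876.02	CATENVPCDENRPGDCCSEYECLKPTGHGWWYASYYCYKKKSG	43	3	8.91	6	amidation	True	U2-TRTX-Ar1
U3-TRTX-Ar1a	5439.80	IIECFFSCEIEKDGKSKEGKPCKPKGDKDKDKKCSGGWRCKLKLCLKI	48	3	10.29	10		True	U3-TRTX-Ar1
U3-TRTX-Ar1b	5457.75	IIECFFSCEIEKDGKSKEGKPCKPKGDKDKDKKCSGGWRCKLKMCLKI	48	3	10.54	1		True	U3-TRTX-Ar1
U4-TRTX-Ar1a	6728.19	ECKQLKEKCSNHCDCCGKTVLCATVYVGRNTEMLCKEKRSDDPILNSIGKVINAATKAMSGC	62	4	9.36	3		True	U4-TRTX-Ar1
U4-TRTX-Ar1b	6755.19	ECKQLKEKCNNHCDCCGKTVLCATVYVGRNTEMLCKEKRSDDPILNSIGKVINAATKAMSGC	62	4	8.80	7		True	U4-TRTX-Ar1
U5-TRTX-Ar1a	6928.76	ACTTEADCPNGCCTGGSFHRYCRSYGGEMDQCEPRNDFGSYSTACPCKEEFECSPIKRCQRR	62	5	8.32	11		True	U5-TRTX-Ar1
U6-TRTX-Ar1a	6936.18	NREHCYIPRRRCVTTEQCCKPYDTVNYFVACGKAWPEDKKRKVNKCYICNNELTVCTR	58	4	7.56	14		True	U6-TRTX-Ar1
U7-TRTX-Ar1a	7195.23	ETSCIEELQTCKNSCECCGTTTICSPSWVDGNEIKLCRNEGNKLQKVWHFFQKAYSKMHSCKT	63	4	8.98	5		True	U7-TRTX-Ar1
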