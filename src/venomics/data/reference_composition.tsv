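# Published reference table of amino-acid class composition for the six
# predicted anticancer peptides (Cys excluded for disulfide-bonded CRPs).
# count/percent are the printed values.
peptide_id	class	count	percent
U1-TRTX-Agm3a	tiny	5	20
U1-TRTX-Agm3a	small	10	40
U1-TRTX-Agm3a	aliphatic	3	12
U1-TRTX-Agm3a	aromatic	5	20
U1-TRTX-Agm3a	hydrophobic	13	52
U1-TRTX-Agm3a	hydrophilic	12	48
U1-TRTX-Agm3a	charged	5	20
U1-TRTX-Agm3a	cationic	3	12
U1-TRTX-Agm3a	anionic	2	8
U1-TRTX-Ar1b	tiny	9	33.3
U1-TRTX-Ar1b	small	14	51.9
U1-TRTX-Ar1b	aliphatic	4	14.8
U1-TRTX-Ar1b	aromatic	4	14.8
U1-TRTX-Ar1b	hydrophobic	14	51.9
U1-TRTX-Ar1b	hydrophilic	13	48.1
U1-TRTX-Ar1b	charged	8	29.6
U1-TRTX-Ar1b	cationic	4	14.8
U1-TRTX-Ar1b	anionic	4	14.8
VLPPLKF	tiny	0	0
VLPPLKF	small	3	42.9
VLPPLKF	aliphatic	3	42.9
VLPPLKF	aromatic	1	14.3
VLPPLKF	hydrophobic	6	85.7
VLPPLKF	hydrophilic	1	14.3
VLPPLKF	charged	1	14.3
VLPPLKF	cationic	1	14.3
VLPPLKF	anionic	0	0
PLPVFV	tiny	0	0
PLPVFV	small	4	66.7
PLPVFV	aliphatic	3	50
PLPVFV	aromatic	1	16.7
PLPVFV	hydrophobic	6	100
PLPVFV	hydrophilic	0	0
PLPVFV	charged	0	0
PLPVFV	cationic	0	0
PLPVFV	anionic	0	0
VVVPFVV	tiny	0	0
VVVPFVV	small	6	85.7
VVVPFVV	aliphatic	5	71.4
VVVPFVV	aromatic	1	14.3
VVVPFVV	hydrophobic	7	100
VVVPFVV	hydrophilic	0	0
VVVPFVV	charged	0	0
VVVPFVV	cationic	0	0
VVVPFVV	anionic	0	0
VPPILKY	tiny	0	0
VPPILKY	small	3	42.9
VPPILKY	aliphatic	3	42.9
VPPILKY	aromatic	1	14.3
VPPILKY	hydrophobic	6	85.7
VPPILKY	hydrophilic	1	14.3
VPPILKY	charged	1	14.3
VPPILKY	cationic	1	14.3
VPPILKY	anionic	0	0
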