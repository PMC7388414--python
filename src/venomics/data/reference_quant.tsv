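# Published reference table of relative protein quantification (Hi3, mean
# normalized intensity NI) for Acanthoscurria rondoniae venom.
# percent_printed is the printed one-decimal share of the venom.
accession	peptide_count	mass_kda	description	ni	percent_printed
comp117964_c0_seq1.p1	181	53.3	Ar-CRISP	1.38E+07	27.9
comp90511_c0_seq1.p1	28	10.7	U3-TRTX-Ar1a	1.29E+07	25.9
comp105543_c0_seq1.p3	25	9.4	U5-TRTX-Ar1a	7.29E+06	14.7
comp127239_c0_seq1.p1	101	82.4	Ar-Neprilysin-1	4.16E+06	8.4
comp57753_c0_seq1.p1	13	12.3	U4-TRTX-Ar1a	4.13E+06	8.3
comp90508_c2_seq2.p1	5	15	U2-TRTX-Ar1a	2.51E+06	5.1
comp107050_c0_seq2.p2	12	13	U7-TRTX-Ar1a	1.47E+06	3.0
comp127127_c4_seq1.p1	46	49.8	Ar-Hyaluronidase	7.49E+05	1.5
comp125618_c0_seq2.p1	5	6.9	U1-TRTX-Agm3a	6.81E+05	1.4
comp90482_c0_seq1.p1	26	48.6	PFAM: Serpin (serine protease inhibitor)	4.25E+05	0.9
comp98439_c0_seq1.p1	4	16.3	PFAM: Thyroglobulin type-1 repeat	3.23E+05	0.7
comp117041_c0_seq1.p1	28	42.8	PFAM: Tyrosine phosphatase family	2.45E+05	0.5
comp57865_c0_seq1.p1	7	18.5	Unknown	1.86E+05	0.4
comp99029_c0_seq1.p1	4	10.8	U6-TRTX-Ar1a	1.62E+05	0.3
comp117273_c1_seq1.p1	23	45.1	PFAM: Putative serine esterase (DUF676)	1.46E+05	0.3
comp119317_c0_seq2.p1	20	87.2	PFAM: Peptidase family M13	1.28E+05	0.3
comp116850_c0_seq2.p1	9	53.1	PFAM: Zinc carboxypeptidase	6.93E+04	0.1
comp122884_c0_seq2.p1	5	78.9	PFAM: Peptidase S8 pro-domain	4.99E+04	0.1
comp117075_c0_seq1.p1	3	25.5	PFAM: Tetraspanin family	4.61E+04	0.1
comp115582_c0_seq1.p1	10	76.4	PFAM: Neutral/alkaline nonlysosomal ceramidase	4.30E+04	0.1
comp113427_c0_seq1.p1	11	91.1	PFAM: Fasciclin domain	4.15E+04	0.1
comp87917_c0_seq1.p1	5	12.2	TSA: U3-hexatoxin-Hib [Hadronyche infensa]	1.98E+04	0.0
comp27569_c0_seq1.p1	3	27.4	TSA: putative uncharacterized protein. partial	1.53E+04	0.0
comp126642_c0_seq1.p1	3	46.1	PFAM: Cysteine-rich secretory protein family	1.16E+04	0.0
comp114378_c0_seq1.p1	18	72.2	PFAM: Hemocyanin. copper containing domain	7.96E+03	0.0
comp120272_c1_seq8.p1	3	39.9	TSA: peptidylglycine alpha-hydroxylating monooxygenase	4.76E+03	0.0
comp121853_c0_seq2.p1	6	72.3	PFAM: Angiotensin-converting enzyme	4.54E+03	0.0
comp114378_c0_seq4.p1	17	71.5	PFAM: Hemocyanin. copper containing domain	2.72E+03	0.0
comp117984_c0_seq2.p1	4	31.1	PFAM: Immunoglobulin I-set domain	2.60E+03	0.0
comp57921_c1_seq1.p1	4	44.9	PFAM: Hemocyanin. ig-like domain	7.99E+02	0.0
comp114578_c0_seq3.p1	7	25.1	TSA: tri-cap-1 [Trittame loki]	4.91E+02	0.0
comp114378_c0_seq2.p1	16	73.7	PFAM: Hemocyanin. ig-like domain	1.71E+02	0.0
comp86283_c0_seq1.p1	6	78.4	PFAM: Transferrin	0.00E+00	0.0
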