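# Published reference table of predictor scores for validated Acanthoscurria
# rondoniae toxins and positive-control peptides.  Antimicrobial scores are
# iAMPpred-style probabilities; rf_acp/svm_acp are the two MLACP algorithm
# scores.  is_control marks the positive-control peptides.
peptide_id	antibacterial	antiviral	antifungal	rf_acp	svm_acp	is_control
Gomesin	0.985	0.898	0.973	0.668	0.926	True
Rondonin	0.671	0.301	0.903	0.400	0.447	True
P9	0.997	0.940	0.992	0.479	0.816	True
mBD4	0.990	0.773	0.968	0.371	0.837	True
Aurein 1.2	0.940	0.913	0.917	0.870	0.935	True
HNP-1	0.920	0.920	0.950	0.879	0.938	True
PLPVFV	0.623	0.586	0.515	0.639	0.656	False
VVVPFVV	0.645	0.538	0.432	0.637	0.635	False
VENLAEP	0.083	0.046	0.028	0.296	0.508	False
VLPPLKF	0.801	0.794	0.828	0.632	0.740	False
VPPILKY	0.751	0.410	0.429	0.501	0.528	False
YPPPPPPPH	0.542	0.382	0.406	0.442	0.618	False
FETPNNPDGKVTKQE	0.133	0.143	0.082	0.350	0.164	False
U1-TRTX-Agm3a	0.843	0.696	0.579	0.559	0.878	False
U1-TRTX-Ar1a	0.994	0.968	0.976	0.489	0.862	False
U1-TRTX-Ar1b	0.987	0.966	0.972	0.541	0.903	False
U2-TRTX-Ar1a	0.940	0.685	0.920	0.283	0.624	False
U3-TRTX-Ar1a	0.996	0.918	0.982	0.292	0.360	False
U3-TRTX-Ar1b	0.997	0.924	0.986	0.324	0.381	False
U4-TRTX-Ar1a	0.981	0.770	0.954	0.139	0.121	False
U4-TRTX-Ar1b	0.978	0.742	0.937	0.142	0.128	False
U5-TRTX-Ar1a	0.996	0.858	0.989	0.363	0.519	False
U6-TRTX-Ar1a	0.986	0.826	0.947	0.300	0.538	False
U7-TRTX-Ar1a	0.991	0.855	0.926	0.256	0.302	False
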