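ammonium_fraction	feasible	growth	objective	starch_exchange	tca	mito_atpase	proton_exchange	hco3_exchange
0.0	True	0.1	11.933814149402389	-0.08312500000023715	0.10125000000039083	0.5550000000023535	0.10652777777833863	0.12152777777836211
0.1	True	0.1	11.96903667954778	-0.08268382352932728	0.10036764705868423	0.5557058823521016	0.10811601307169405	0.12011601307168687
0.2	True	0.1	12.004476035024984	-0.08224264705859438	0.09948529411727028	0.5564117647036115	0.10970424836547236	0.11870424836544857
0.30000000000000004	True	0.1	12.04013221632286	-0.0818014705892306	0.09860294117810953	0.5571176470687009	0.1112924836624859	0.1172924836625817
0.4	True	0.1	12.076005221993649	-0.08136029411770394	0.09772058823538894	0.5578235294123381	0.11288071895438465	0.11588071895438933
0.5	True	0.1	12.112095053941673	-0.08091911764865334	0.09683823529674591	0.5585294117805469	0.11446895425214053	0.11446895425229967
0.6000000000000001	True	0.1	12.148401711471001	-0.08047794118038401	0.09595588235937998	0.5592352941564569	0.11605718955172811	0.11305718955212182
0.7000000000000001	True	0.1	12.184925193016436	-0.08003676470909102	0.09507352941704277	0.5599411765024026	0.1176454248441814	0.11164542484450002
0.8	True	0.1	12.221665499000778	-0.07959558823581146	0.09419117647144142	0.5606470588286723	0.11923366013194754	0.11023366013199574
0.9	True	0.1	12.258622631337941	-0.0791544117651847	0.09330882353020077	0.5613529411812274	0.12082189542596825	0.10882189542601953
1.0	True	0.1	12.295796589941437	-0.07871323529698834	0.09242647059295792	0.5620588235578768	0.12241013072573564	0.10741013072602157
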