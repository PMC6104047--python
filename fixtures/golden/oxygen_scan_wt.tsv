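oxygen_uptake	feasible	growth	objective	malate	succinate	glutamate	alanine	ammonia	oxygen
0.0	False								
0.04468615421946191	False								
0.08937230843892383	False								
0.13405846265838572	False								
0.17874461687784765	False								
0.22343077109730958	False								
0.26811692531677145	True	1.1253737709544196	13899.037733189203	0.239559143141174	1.5049663034203936e-11	0.14977583894440533	-0.31858190458795804	1.3623572871509125e-12	0.2681169253167745
0.3128030795362334	True	1.1253737709544196	13854.606891433747	-1.3243298182688886e-13	0.282293526317307	-9.13500986613963e-13	-0.1688060656425034	1.773666642369194e-13	0.3128030795362288
0.3574892337556953	True	1.1253737709544196	14134.652895744453	7.801645166488686e-14	0.2950609989506483	-3.6089158866424697e-13	-0.16880606564216585	8.90953198859592e-14	0.35748923375569436
0.40217538797515723	True	1.1253737709544196	14417.904459287098	-3.348886989185427e-13	0.30782847158605836	-4.798470118097673e-13	-0.16880606564309908	4.382570720508264e-13	0.40217538797515323
0.44686154219461915	True	1.1253737709544196	14704.167930868678	1.6223632386741143e-14	0.32059594421815557	-8.016432716313934e-13	-0.16880606564159664	-5.655142096527493e-14	0.4468615421946157
0.491547696414081	True	1.1253737709544196	14993.400216655733	-8.699720470253911e-14	0.33336341685323523	-4.895064420321772e-13	-0.16880606564223752	-5.379368547449077e-14	0.4915476964140788
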