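oxygen_uptake	feasible	growth	objective	malate	succinate	glutamate	alanine	ammonia	oxygen
0.0	False								
0.04468615421946191	False								
0.08937230843892383	False								
0.13405846265838572	False								
0.17874461687784765	False								
0.22343077109730958	False								
0.26811692531677145	False								
0.3128030795362334	True	1.1253737709544196	14028.908900161261	0.12785619970913145	1.1807901283793363e-11	0.0653603640049579	-0.0653603640055902	-0.16880606564221798	0.31280307953623665
0.3574892337556953	True	1.1253737709544196	14163.740414009475	-8.97259319272832e-14	0.1503700855428909	-7.143315534498642e-13	6.290686193839712e-13	-0.1688060656431723	0.3574892337556911
0.40217538797515723	True	1.1253737709544196	14447.181600824253	-6.272194334551133e-14	0.16313755817680373	-2.534259035491403e-13	3.06763761619361e-13	-0.16880606564333217	0.402175387975151
0.44686154219461915	True	1.1253737709544196	14733.651022399397	-5.335709686165097e-13	0.17590503081124773	-1.7158846979254704e-13	8.981843628458507e-13	-0.1688060656436959	0.4468615421946122
0.491547696414081	True	1.1253737709544196	15023.089258164704	-6.969367792049417e-14	0.18867250344492545	-4.884674750299735e-13	8.570479620747505e-13	-0.1688060656423796	0.4915476964140758
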