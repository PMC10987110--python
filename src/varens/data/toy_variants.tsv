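position	ref	alt	label	SIFT	PolyPhen-2	MLb-LDLr	MutationTaster	REVEL	VARITY
854	R	Y	pathogenic	0.036263771767741204	0.7830766891025054	0.702026994759642	56.54582063395755	0.8281239716621085	0.9448837447376833
154	S	C	pathogenic	0.02552827012773551	0.5181752433156581	0.990909594351593		0.9252489526159403	0.6951392400787176
542	W	V	pathogenic	0.009770138535763695	0.737996469961897	0.9621251454598262		0.8118086043683335	0.6627297174448997
855	M	Q	pathogenic	0.0007085671537332416	0.6603498454627547	0.727531529194672	95.04417860603897	0.9200227907226879	0.8688140337972007
687	D	R	benign	0.9415385532954788	0.1822681671871863	-0.7698424678853569	-84.092875661372	0.08026900499716536	0.10801736178769612
24	Y	R	pathogenic	0.01241806934323697	0.8589845817900394	0.8154827250272032	98.34381599886781	0.8864340886613862	0.8747114030257713
353	H	W	pathogenic	0.0033525825872857684	0.8614813708833632	0.8693779357432022	95.48672440511884	0.6465282461830808	0.7463255136179701
366	H	T	pathogenic	0.002269163264942531	0.9949927448848402	0.8990843870918168	80.26197110432672	0.9008436667405426	0.614226361319735
499	M	L	pathogenic	0.016347506328507566	0.5747651802067049	0.7511010910057891	90.8203835417017	0.9040802204686139	0.8961202675348843
612	Y	S	benign	0.1699712977133233	0.18506794199115417	-0.6026958562167701	-94.4114076668591	0.28892207674011733	0.06045927396429336
664	L	C	benign	0.9722965509176529	0.42934619637056287	-0.8546107862550864	-82.5144925413459	0.021252920486847404	0.17555952078519083
125	C	K	pathogenic	0.031323873667305935	0.701503557718381	0.8250802923542205	74.58634683132654	0.6858315891583797	0.6661256067693909
112	N	S	benign	0.046133531019339036	0.07639772020064127	-0.5982109400427373	-94.52885516144394	0.29679012585749187	0.3783166000205852
432	T	F	benign	0.5417141742536024	0.11366062607699329	-0.8100894729685666	-90.1599359633219	0.1043210727847859	0.17817277142987364
753	P	Y	benign	0.3547331675530493	0.4224421769102218	-0.9831513894572393	-81.671802860433	0.023396992107119458	0.11566138508132273
353	H	K	pathogenic	0.0008304455645933295	0.9407256772086235	0.6979703098392673	65.11437451033481	0.8857109532547823	0.5332695657842927
655	R	G	benign	0.2620655643018128	0.0835121074685066	-0.6194265384423441	-87.42547714394411	0.1743856609720097	0.5110543815586996
134	P	Y	pathogenic	0.014124607233594877	0.5425356066374439	0.9398865328568681	76.66297797199097	0.7643873094997758	0.41711468083906844
462	L	V	pathogenic	0.028734985295259752	0.7745564459201689	0.7742812348372154	82.63782845411195	0.647661283388738	0.7606752946378789
669	Y	D	benign	0.6934629444968765	0.2642279929883673	-0.84990281929836	-94.92358175517315	0.1742971531301623	0.43149935073527096
854	R	H	pathogenic	0.00900837194723414	0.9528381804850474	0.915632933857763	86.54911937600404	0.5257458825384431	0.9287479932229128
264	G	M	pathogenic	0.0207704049266364	0.5314929690633565	0.8996864002994106	96.18480200842691	0.9825791813318252	0.956410190037391
12	W	S	benign	0.3340190876859461	0.2146148704244316	-0.5277704062204664	-50.944515051316245	0.060198589968087024	0.19420923350411148
845	S	P	pathogenic	0.011011040428953178	0.8769501187850541	0.8235898025014585	89.13960738315953	0.8550838483274668	0.8310598989990065
16	V	G	pathogenic	0.01620832303824271	0.845039866566814	0.8352231977762175	63.29054408462436	0.6016730968956001	0.7716892388459446
481	M	I	pathogenic	0.032023432500097426	0.817355187978294	0.8000728719286834	95.7099563550947	0.9188348107332038	0.6537691311032898
71	V	Y	benign	0.32894406658987263	0.19484484543887076	-0.8473965072776307	-80.88179105091314	0.30714830148132444	0.02104266620258896
378	I	M	benign	0.5745690691544163	0.1833385922926262	-0.9109443816527686	-80.1682171777967	0.22960093948359656	0.27013574340366536
619	V	D	pathogenic	0.008442446613599497	0.5797486979986288	0.9737542789096809	82.52921587461161	0.8364010997663973	0.6656516226727837
750	L	H	benign	0.469356150140642	0.3271148916584962	-0.7234224255624531	-70.56759315916545	0.0634641504247774	0.02011944641611721
770	P	R	pathogenic	0.01650676664594397	0.9296203842858775	-0.5223148585001196	72.19125540973354	0.9184687524641968	0.742289146503913
318	I	W	pathogenic	0.01111240818109549	0.731834943501223	0.7270637935623282	83.91106118406358	0.9514632305221058	0.7216906393772364
198	Q	F	pathogenic	0.04165710838597547	0.7953920250078498	0.8284908648259763	79.52564330614636	0.6028772649640775	0.9085173332116764
756	M	N	pathogenic	0.02923722196127554	0.9273594182436578	0.7842704662555192	85.97054212142348	0.9258244401373171	0.740814834517088
226	Q	I	benign	0.7292514145815261	0.041794035741988325	-0.9942565474953258	-83.38738536990053	0.2602945309445808	0.15449854500348964
350	W	G	benign	0.47228084025528017	0.16719011539140574	-0.9529726560309061	-93.25092743317113	0.030883917756449775	0.18975402847222492
353	H	A	benign	0.21435410863543236	0.14004026665993038	-0.7284732154984498	-91.73370664235094	0.0959949069163103	0.2854507144236442
180	K	G	pathogenic	0.01688857651388609	0.6947527210823177	0.8423733301658309	99.53029987498002	0.7401633321034569	0.6138446680583739
125	C	P	pathogenic	0.02732057195287474	0.7105025459958596	0.6789439768435647	82.94266356863714	0.7689705168323369	0.919761883612495
826	P	I	pathogenic	0.030966290552561393	0.9861324200519642	0.9724953670866914		0.717156484298451	0.8246483857853503
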