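position	ref	alt	raw_score	display_score	call	predictors_used
854	R	Y	1.261998	5.185875	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
154	S	C	0.903880	4.707473	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;REVEL;VARITY
542	W	V	1.241679	5.158731	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;REVEL;VARITY
855	M	Q	1.638699	5.689102	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
687	D	R	-2.618596	0.827963	benign	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
24	Y	R	1.906380	6.046690	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
353	H	W	1.632819	5.681247	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
366	H	T	1.595937	5.631977	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
499	M	L	1.420658	5.397825	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
612	Y	S	-2.268159	1.185552	benign	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
664	L	C	-2.239535	1.214761	benign	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
125	C	K	0.853676	4.640407	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
112	N	S	-1.756301	1.707856	benign	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
432	T	F	-2.495571	0.953499	benign	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
753	P	Y	-2.188412	1.266927	benign	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
353	H	K	1.104334	4.975256	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
655	R	G	-1.631111	1.835601	benign	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
134	P	Y	0.447695	4.098066	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
462	L	V	1.166011	5.057648	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
669	Y	D	-1.921770	1.539011	benign	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
854	R	H	1.935976	6.086227	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
264	G	M	1.625459	5.671414	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
12	W	S	-1.720478	1.744410	benign	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
845	S	P	1.768105	5.861972	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
16	V	G	1.219843	5.129561	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
481	M	I	1.280047	5.209987	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
71	V	Y	-2.421528	1.029053	benign	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
378	I	M	-2.157940	1.298020	benign	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
619	V	D	1.107372	4.979314	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
750	L	H	-2.244198	1.210002	benign	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
770	P	R	1.283799	5.214999	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
318	I	W	1.304925	5.243220	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
198	Q	F	1.350788	5.304488	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
756	M	N	1.515800	5.524923	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
226	Q	I	-2.695064	0.749934	benign	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
350	W	G	-2.534162	0.914120	benign	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
353	H	A	-2.096862	1.360345	benign	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
180	K	G	1.125202	5.003132	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
125	C	P	1.378669	5.341734	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;MutationTaster;REVEL;VARITY
826	P	I	1.753344	5.842254	pathogenic	SIFT;PolyPhen-2;MLb-LDLr;REVEL;VARITY
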