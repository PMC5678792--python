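cohort	latent	SIM1_C001	SIM1_C002	SIM1_C003	SIM1_C004	SIM1_C005	SIM1_C006	SIM1_C007	SIM1_C008	SIM1_C009	SIM1_C010	SIM1_C011	SIM1_C012	SIM1_N001	SIM1_N002	SIM1_N003	SIM1_N004	SIM1_N005	SIM1_N006	SIM1_N007	SIM1_N008	SIM1_N009	SIM1_N010	SIM1_N011	SIM1_N012	SIM2_C001	SIM2_C002	SIM2_C003	SIM2_C004	SIM2_C005	SIM2_C006	SIM2_C007	SIM2_C008	SIM2_C009	SIM2_C010	SIM2_C011	SIM2_C012	SIM2_N001	SIM2_N002	SIM2_N003	SIM2_N004	SIM2_N005	SIM2_N006	SIM2_N007	SIM2_N008	SIM2_N009	SIM2_N010	SIM2_N011	SIM2_N012
SIM1	r1	-0.8265612208226194	1.0542767271601652	-0.7631930564115446	-0.3008940227864295	-0.07800803356260066	1.2110849294110815	0.8552399764519316	-0.23345150044697627	1.256487468670927	0.018134491602636083	1.36296589371051	-0.5091400892766871	0.6802839857926856	0.16915872208695543	-0.1528212045877031	0.6214147543799363	-1.6382025653047623	-0.5784055281863214	0.23415940197527313	0.0933314532819807	-1.3386633329449114	-0.5074979552909138	-0.10269127423569818	-0.655867880338009																								
SIM1	r2	0.8745008380503384	0.9015270939610297	0.81264508144994	-0.3462965347418712	1.9441129383303586	-0.47184332113498584	-0.1437395063318101	0.44790984900644004	0.9495026536671229	1.442567094375752	1.9608913401982437	-0.20577759582912106	-1.266736778609652	-0.8909920209636453	0.3585898622948947	-1.0860782226834105	-1.0261534858731474	0.09180450853137773	0.07897339606459468	0.02395845644356408	0.26740173609616374	-0.2980804601691367	-0.2963324366295918	0.16307275502788743																								
SIM1	product	-1.604427255833632	2.202711869273486	-1.3528884142386561	-0.7566463308493205	-0.018456003544908173	1.4863588562414343	1.38493457125736	-1.2203867735488727	1.3676770994305145	1.9405519987101554	3.183784018782694	-0.311616351759366	0.8518844380663464	-1.7794656324061346	1.3485502961393785	-1.235801146202368	-2.1046954992817404	2.0520457450804765	0.26325035884924614	1.566342184466246	-0.49832806957544135	1.8002884732498161	-0.1693189559725402	-0.7607192138701704																								
SIM2	r1																									0.45728027059645765	0.22270374290100914	1.574833483689301	2.1936568883361844	-0.7213565927449841	1.3755641025138958	0.0854332148993927	0.8934353273694456	0.8503891033654322	1.2773330445258848	1.0351492400956608	0.18027092896974578	2.5916452962824947	-0.0756346295279417	0.07231157644169993	0.9852056907664725	0.6885018347566152	-0.20752643897010697	0.5957984769359671	-0.519698738394308	-0.2367584826676154	0.9850985163462718	-0.013771175130387078	0.29244714345974254
SIM2	r2																									1.6209822133080842	0.7053255916908474	0.20932688104795286	-0.5376333576709451	-1.5975858358752741	-0.3019719673049312	-0.2755461063288478	-0.11593723985584997	-0.6457771374389771	-0.14917840210555303	0.363844040631224	0.08245442459049326	-0.05975960203139074	-1.4252143021964778	-1.5513127915155909	0.07490186666114901	1.0030834351905387	0.6271499753248704	-0.3175991908818723	0.0005731089909121988	-2.108154818786309	1.8498323970384918	-0.4664869369529983	-1.2724820545637363
SIM2	product																									2.5699101688057855	-0.5238975822098366	1.9908592021737754	1.4480755103264098	-2.1374157185379903	1.1163828068619113	0.6978003568025555	1.6697575605097692	0.9194908760541974	2.3119823818037073	1.767983117094772	-1.9068462077582686	3.093076652113332	0.20694988995574626	1.2116701459796009	-0.586984953524171	1.1929820214541405	-0.3893565776562714	-0.27367892744821737	-1.8597178243565868	-0.4478723707846778	2.7401944939177985	-0.990248881955474	-0.49227604236719696
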