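protein_change	cdna_change	baseline_activity	baseline_sem	baseline_pct_wt	baseline_pct_wt_sem	max_activity	max_sem	max_pct_wt	max_pct_wt_sem	relative_increase	relative_increase_sem	ec50_uM	ec50_sem_uM	significance	high_range	n
Wild-type	Wild-type	33217	1077	100.0	0.0	38813	1553	117	3	—	—	—	—			24
p.N34S	c.101A>G	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			8
p.P40S	c.118C>T	0.0	0.0	0.0	0.0	6462	940	16.7	2.7	NC	—	592	377			4
p.T41I	c.122C>T	18436	5427	43.1	9.0	29293	3745	70.4	11.1	1.7	0.2	7.6	1.7	*		4
p.H46R	c.137A>G	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.H46Y	c.136C>T	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.R49L	c.146G>T	0.0	0.0	0.0	0.0	370	81	1.2	0.3	NC	—	433	138	*		3
p.F50C	c.149T>G	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.M51K	c.152T>A	1857	358	5.6	0.5	18557	3974	56.1	8.6	9.2	1.8	15.9	4.2	*		3
p.E59K	c.175G>A	1108	40	3.6	0.2	3742	180	12.2	0.7	3.9	0.2	7.2	1.9	**		3
p.E66Q	c.196G>C	14739	710	49.1	3.8	18388	722	61.2	3.8	1.3	0.0	0.5	0.1	**		5
p.L89R	c.266T>G	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.I91T	c.272T>C	0.0	0.0	0.0	0.0	1556	162	5.1	0.8	NC	—	2.3	0.9	*		3
p.D92N	c.274G>A	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.D92Y	c.274G>T	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.C94S	c.281G>C	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			9
p.W95S	c.284G>C	0.0	0.0	0.0	0.0	672	112	2.1	0.4	NC	—	7560	4329			6
p.A97V	c.290C>T	1898	406	5.7	1.3	15832	3968	48.0	12.5	8.3	0.5	6.7	2.2	*		4
p.R100K	c.299G>A	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.R100T	c.299G>C	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.R112C	c.334C>T	0.0	0.0	0.0	0.0	1042	202	3.1	0.6	NC	—	1720	991	*	yes	4
p.R112H	c.335G>A	0.0	0.0	0.0	0.0	5676	590	19.0	1.3	17.1	5.4	19.7	6.2	**		3
p.F113L	c.337T>C	5960	1230	17.3	3.6	23244	1348	67.6	7.4	4.0	0.4	8.0	0.6	**		3
p.F113S	c.338T>C	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.G128E	c.383G>A	10719	883	56.9	11.2	16409	1793	85.8	19.4	1.5	0.1	1.4	0.6	**		8
p.L131P	c.392T>C	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.G138E	c.413G>A	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.C142R	c.424T>C	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.A143P	c.427G>C	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.A143T	c.427G>A	15499	2674	51.9	5.2	23131	3312	83.8	16.0	1.5	0.1	8.4	2.3	***		6
p.G144V	c.431G>T	0.0	0.0	0.0	0.0	5932	890	19.5	2.6	NC	—	93.4	19.0	**		4
p.S148N	c.443G>A	0.0	0.0	0.0	0.0	4003	693	11.9	1.3	NC	—	360	137	*		3
p.S148R	c.444T>G	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.W162R	c.484T>C	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.D170V	c.509A>T	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.G171D	c.512G>A	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			4
p.C172G	c.514T>G	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.C172Y	c.515G>A	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			4
p.G183D	c.548G>A	0.0	0.0	0.0	0.0	22385	1897	75.0	4.2	NC	—	68.8	16.5	**		4
p.G183S	c.547G>A	1888	116	5.9	0.5	27614	4530	84.9	12.5	14.3	1.1	25.2	6.9	*		3
p.C202Y	c.605G>A	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			6
p.P205R	c.614C>G	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			9
p.P205T	c.613C>A	5524	747	18.2	2.8	40178	6172	132	21	7.6	1.5	15.6	4.3	*		4
p.Y207C	c.620A>G	0.0	0.0	0.0	0.0	848	176	2.7	0.8	NC	—	547	351	*		3
p.Y207S	c.620A>C	364	100	1.1	0.4	4195	460	12.8	1.9	13.5	2.4	66.4	26.6	***		5
p.N215S	c.644A>G	4898	814	15.7	2.4	16400	395	53.2	2.4	3.5	0.5	5.0	0.7	***		3
p.H225R	c.674A>G	0.0	0.0	0.0	0.0	4350	366	15.1	1.0	NC	—	502	87	***		3
p.W226R	c.676T>C	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			4
p.R227Q	c.680G>A	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			4
p.S235C	c.704C>G	0.0	0.0	0.0	0.0	1028	146	3.1	0.5	NC	—	628	211	*		5
p.D244N	c.730G>A	13394	820	43.2	1.5	22948	1763	73.9	2.2	1.7	0.0	2.0	0.8	**		3
p.P259R	c.776C>G	8585	1131	28.1	4.6	40724	1869	132	10	4.9	0.5	16.8	2.7	**		3
p.N263S	c.788A>G	1928	436	6.5	1.4	27458	3232	92.3	9.1	14.9	2.2	13.5	1.6	**		3
p.D264V	c.791A>T	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.D266V	c.797A>T	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.G271C	c.811G>T	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			4
p.G271V	c.812G>T	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			5
p.N272K	c.816C>A	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			3
p.S276G	c.826A>G	0.0	0.0	0.0	0.0	4492	41	12.7	2.5	NC	—	24.3	6.8			7
p.Q279E	c.835C>G	5138	854	16.6	2.5	32048	8092	104	25	6.1	0.9	8.8	1.3	*		4
p.W287C	c.861G>C	0.0	0.0	0.0	0.0	5809	973	16.4	1.1	NC	—	6727	2634	*	yes	3
p.A288P	c.862G>C	0.0	0.0	0.0	0.0	4856	650	13.6	2.3	NC	—	51	23	*		3
p.I289F	c.865A>T	0.0	0.0	0.0	0.0	4900	90	14.3	1.4	NC	—	209	5	**		3
p.F295C	c.884T>G	1257	171	4.1	0.3	13482	982	44.0	3.3	12.0	1.4	38.8	9.5	**		3
p.M296I	c.888G>A	5909	802	19.5	3.5	36470	1157	118	5	6.2	1.1	3.0	0.4	**		3
p.M296V	c.886A>G	5575	1837	18.3	6.5	38397	1949	126	14	7.6	1.9	2.5	0.2	**		3
p.L300P	c.899T>C	864	260	2.9	0.9	18584	2654	62.9	9.0	24.5	3.4	16.4	1.8	*		3
p.R301Q	c.902G>A	1854	117	5.6	0.3	27765	1060	83.7	1.9	16.0	1.0	7.7	0.4	***		24
p.V316E	c.947T>A	0.0	0.0	0.0	0.0	542	99	1.8	0.3	NC	—	64.4	31.2	***		7
p.N320Y	c.958A>T	0.0	0.0	0.0	0.0	10181	631	29.6	3.5	NC	—	738	133	**	yes	3
p.G325D	c.974G>A	0.0	0.0	0.0	0.0	8439	1441	26.2	7.2	NC	—	430	144	***	yes	3
p.G328A	c.983G>C	1320	136	3.9	0.1	26534	718	79.0	5.7	21.0	1.9	31.3	3.8	***		3
p.R342Q	c.1025G>A	0.0	0.0	0.0	0.0	1175	137	4.4	0.4	NC	—	95.0	39.3	*		4
p.R356W	c.1066C>T	2352	276	7.6	1.4	23720	2474	75.6	11.6	10.1	1.3	5.4	0.6	*		3
p.E358A	c.1073A>C	639	200	1.8	0.4	8680	902	26.9	4.2	16.0	4.4	16.4	5.4	**		4
p.E358K	c.1072G>A	0.0	0.0	0.0	0.0	1417	136	3.7	0.5	NC	—	281	32	*		4
p.R363C	c.1087C>T	2385	119	7.5	0.7	13603	1559	42.0	3.9	5.5	0.4	3.7	0.3	*		3
p.R363H	c.1088G>A	8302	2086	24.1	6.8	25721	2292	73.4	5.3	3.3	0.5	16.7	6.5	**		4
p.P409A	c.1225C>G	834	116	2.8	0.5	12572	2254	42.0	7.8	15.3	1.6	11.3	1.9	*		3
p.L415P	c.1244T>C	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			7
p.D55V/Q57L	c.164A>T/170C>T	0.0	0.0	0.0	0.0	5557	800	16.9	1.9	NC	—	29.4	10.8	*		4
p.L120P/A121T	c.359T>C/361G>A	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	—	—	—	—			4
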