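study	subject_id	protein_change	cdna_change	hek_baseline_pct_wt	hek_cmax_pct_wt	hek_responsive	pbmc_baseline_pct_normal	post_labels	post_doses	post_values	category
FAB-CL-203&FAB-CL-202	1	p.C94S	c.281G>C	0	0	No	0	Wk 4|Wk 12|Wk 24|Wk 48	150 mg qod|150 mg qod|150 mg qod|150 mg qod	0|0|1|0	Non/limited
FAB-CL-203&FAB-CL-202	2	p.R112C	c.334C>T	0	0	No	0	Wk 4|Wk 12|Wk 24|Wk 48	150 mg qod|150 mg qod|150 mg qod|150 mg qod	2|0|1|2	Non/limited
FAB-CL-203&FAB-CL-202	3	p.P205T	c.613C>A	18.2	62.5	Yes	1	Wk 4|Wk 12|Wk 24|Wk 48	150 mg qod|150 mg qod|150 mg qod|150 mg qod	2|2|6|14	Good
FAB-CL-203&FAB-CL-202	4	p.N215S	c.644A>G	15.7	40.7	Yes	16	Wk 4|Wk 12|Wk 24|Wk 48	150 mg qod|150 mg qod|150 mg qod|150 mg qod	38|48|50|34	Good
FAB-CL-203&FAB-CL-202	5	p.F295C	c.884T>G	4.1	12.3	Yes	0	Wk 4|Wk 12|Wk 24|Wk 48	150 mg qod|150 mg qod|150 mg qod|150 mg qod	1|1|2|1	Non/limited
FAB-CL-203&FAB-CL-202	6	p.P259R	c.776C>G	28.1	67	Yes	1	Wk 4|Wk 12|Wk 24|Wk 48	150 mg qod|150 mg qod|150 mg qod|150 mg qod	10|10|ND|2	Good
FAB-CL-203&FAB-CL-202	7	p.P259R	c.776C>G	28.1	67	Yes	1	Wk 4|Wk 12|Wk 24|Wk 48	150 mg qod|150 mg qod|150 mg qod|150 mg qod	13|11|15|NA	Good
FAB-CL-203&FAB-CL-202	8	p.R301Q	c.902G>A	5.6	49.5	Yes	1	Wk 4|Wk 12|Wk 24|Wk 48	150 mg qod|150 mg qod|150 mg qod|150 mg qod	34|33|32|28	Good
FAB-CL-203&FAB-CL-202	9	p.L415P	c.1244T>C	0	0	No	1	Wk 4|Wk 12|Wk 24|Wk 48	150 mg qod|150 mg qod|150 mg qod|150 mg qod	1|0|1|1	Non/limited
FAB-CL-201	10	p.T41I	c.122C>T	43.1	58.4	Yes	21	Wk 2|Wk 4|Wk 6|Wk 12	25 mg bid|100 mg bid|250 mg bid|50 mg qd	89|122|127|112	Good
FAB-CL-201	11	p.T41I	c.122C>T	43.1	58.4	Yes	30	Wk 2|Wk 4|Wk 6|Wk 12	25 mg bid|100 mg bid|250 mg bid|50 mg qd	74|122|151|112	Good
FAB-CL-201	12	p.M51K	c.152T>A	5.6	25.1	Yes	4	Wk 2|Wk 4|Wk 6|Wk 12	25 mg bid|100 mg bid|250 mg bid|50 mg qd	24|30|20|18	Good
FAB-CL-201	13	p.A97V	c.290C>T	5.7	31.6	Yes	4	Wk 2|Wk 4|Wk 6|Wk 12	25 mg bid|100 mg bid|250 mg bid|50 mg qd	53|66|70|67	Good
FAB-CL-201	14	p.A143T	c.427G>A	52	69.4	Yes	24	Wk 2|Wk 4|Wk 6|Wk 12	25 mg bid|100 mg bid|250 mg bid|50 mg qd	66|60|64|79	Good
FAB-CL-201	15	p.S276G	c.826A>G	0	3.7	Yes	0	Wk 2|Wk 4|Wk 6|Wk 12	25 mg bid|100 mg bid|250 mg bid|50 mg qd	4|8|6|4	Good
FAB-CL-201	16	p.L300P	c.899T>C	2.9	25.6	Yes	1	Wk 2|Wk 4|Wk 6|Wk 12	25 mg bid|100 mg bid|250 mg bid|50 mg qd	7|7|13|2	Good
FAB-CL-201	17	p.G328A	c.983G>C	3.9	22.1	Yes	0	Wk 2|Wk 4|Wk 6|Wk 12	25 mg bid|100 mg bid|250 mg bid|50 mg qd	2|2|6|2	Good
FAB-CL-201 in vivo screen	18	p.G171D	c.512G>A	0	0	No	2	Wk 2	150 mg qd	2	Non/limited
FAB-CL-201 in vivo screen	19	p.H225R	c.674A>G	0	0	No	2	Wk 2	150 mg qd	1	Non/limited
FAB-CL-201 in vivo screen	20	p.G271C	c.811G>T	0	0	No	27	Wk 2	150 mg qd	0	Non/limited
FAB-CL-201 in vivo screen	21	p.R301Q	c.902G>A	5.6	49.5	Yes	2	Wk 2	150 mg qd	12	Good
FAB-CL-201 in vivo screen	22	p.R227Q	c.680G>A	0	0	No	1	Wk 2	150 mg qd	0	Non/limited
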