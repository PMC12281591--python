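# Top-10 compound perturbation signatures from a published LINCS L1000 connectivity screen (A549 cells, herbal-extract query), ranked by summarized NES = nes_up - nes_down.
rank	batch	compound	dose	treat_time	cell	nes_up	p_up	nes_down	p_down	total_nes
1	b40	AMG-232	10 uM	24 h	A549	2.349660	8.05e-26	-3.710580	1.84e-130	6.060239
2	b41	clofarabine	10 uM	48 h	A549	2.491568	2.03e-35	-3.545747	2.21e-113	6.037314
3	b34	AMG-232	10 uM	24 h	A549	2.325613	2.26e-26	-3.688789	5.59e-125	6.014401
4	b42	nutlin-3	10 uM	24 h	A549	2.242212	9.75e-24	-3.736071	5.39e-140	5.978283
5	b32	CX-5461	10 uM	24 h	A549	2.337019	1.17e-28	-3.622920	3.44e-118	5.959940
6	b32	mitoxantrone	1.11 uM	24 h	A549	2.258089	4.12e-23	-3.697765	1.91e-124	5.955854
7	b40	nutlin-3	10 uM	24 h	A549	2.244571	2.78e-24	-3.698417	9.92e-131	5.942989
8	b32	mitoxantrone	0.37 uM	24 h	A549	2.320273	3.24e-27	-3.617512	2.80e-125	5.937785
9	b41	nutlin-3	10 uM	48 h	A549	2.187997	2.33e-22	-3.717155	5.28e-135	5.905152
10	b41	mericitabine	10 uM	48 h	A549	2.314613	4.39e-26	-3.581254	9.96e-112	5.895867
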