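name	refseq_accession	chromosome	exon_count	length_nt	orf_max_nt	disease_link
WBSCR26	NR_026690.1	7	2	471	240	none
SYNLNC01	NR_900001.1	17	4	250	12	imprinting
SYNLNC02	NR_900002.1	1	1	250	42	none
SYNLNC03	NR_900003.1	17	2	250	54	neurodev
SYNLNC04	NR_900004.1	8	6	435	102	cancer
SYNLNC05	NR_900005.1	4	11	462	141	none
SYNLNC06	NR_900006.1	2	7	532	159	none
SYNLNC07	NR_900007.1	14	2	602	195	cancer
SYNLNC08	NR_900008.1	20	11	616	63	neurodev
SYNLNC09	NR_900009.1	13	2	622	153	none
SYNLNC10	NR_900010.1	16	10	650	195	cancer
SYNLNC11	NR_900011.1	2	4	695	87	neurodev
SYNLNC12	NR_900012.1	7	4	751	123	none
SYNLNC13	NR_900013.1	16	7	776	168	cancer
SYNLNC14	NR_900014.1	13	10	797	72	none
SYNLNC15	NR_900015.1	1	4	961	252	none
SYNLNC16	NR_900016.1	17	4	1002	294	cancer
SYNLNC17	NR_900017.1	17	4	1014	279	none
SYNLNC18	NR_900018.1	10	9	1018	345	cancer
SYNLNC19	NR_900019.1	9	9	1082	372	none
SYNLNC20	NR_900020.1	16	7	1108	216	imprinting
SYNLNC21	NR_900021.1	19	1	1192	405	imprinting
SYNLNC22	NR_900022.1	6	11	1245	168	neurodev
SYNLNC23	NR_900023.1	19	7	1400	360	neurodev
SYNLNC24	NR_900024.1	1	6	1446	402	cancer
SYNLNC25	NR_900025.1	5	2	1484	471	imprinting
SYNLNC26	NR_900026.1	18	2	1605	270	cancer
SYNLNC27	NR_900027.1	17	7	1684	468	cancer
SYNLNC28	NR_900028.1	16	2	1714	228	cancer
SYNLNC29	NR_900029.1	2	6	1730	240	imprinting
SYNLNC30	NR_900030.1	9	3	1873	381	cancer
SYNLNC31	NR_900031.1	12	1	2092	309	cancer
SYNLNC32	NR_900032.1	20	10	2167	195	neurodev
SYNLNC33	NR_900033.1	1	1	2244	123	cancer
SYNLNC34	NR_900034.1	8	1	2542	777	neurodev
SYNLNC35	NR_900035.1	7	8	2569	714	imprinting
SYNLNC36	NR_900036.1	18	5	2682	789	none
SYNLNC37	NR_900037.1	15	7	2802	333	imprinting
SYNLNC38	NR_900038.1	7	7	2906	165	none
SYNLNC39	NR_900039.1	21	11	3170	333	imprinting
SYNLNC40	NR_900040.1	1	3	3355	873	imprinting
SYNLNC41	NR_900041.1	20	6	3383	696	imprinting
SYNLNC42	NR_900042.1	21	6	3827	1191	cancer
SYNLNC43	NR_900043.1	22	6	4001	678	neurodev
SYNLNC44	NR_900044.1	3	3	4213	1473	imprinting
SYNLNC45	NR_900045.1	9	10	4341	1140	cancer
SYNLNC46	NR_900046.1	6	10	4403	528	cancer
SYNLNC47	NR_900047.1	7	2	4409	1128	neurodev
SYNLNC48	NR_900048.1	8	9	4428	810	imprinting
SYNLNC49	NR_900049.1	6	7	6404	795	neurodev
SYNLNC50	NR_900050.1	6	5	11586	705	imprinting
SYNLNC51	NR_900051.1	3	7	12397	3363	imprinting
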