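# Candidate-gene panel summary: per-gene variant totals as published.
# published_tavs = the number of variants dagger-marked as verified in the
# original report.
trait	gene	gene_id	chrom	length_bp	total_variants	ns_variants	published_tavs
Hd	DTH2	LOC4330574	2	1224	4	0	0
Hd	Hd16	LOC4334396	3	2124	0	0	0
Hd	Hd1	LOC4340746	6	1188	9	0	0
Hd	Hd3a	LOC4340185	6	540	7	3	1
Hd	Hd3b	LOC4340184	6	537	5	4	0
Hd	Hd5	LOC4344784	8	894	3	1	0
Hd	Ehd3	LOC4344443	8	1692	5	1	0
Hd	Ehd1	LOC107276289	10	1026	7	2	0
Hd	Ehd2	LOC4348644	10	1428	1	1	1
T	D10	LOC4326177	1	1710	2	1	1
T	RCN1	LOC4332449	3	2364	2	0	0
T	HTD2	LOC4331983	3	957	0	0	0
T	OsTB1	LOC4333856	3	1167	1	1	0
T	HTD1	LOC4336591	4	1830	5	2	0
T	DWARF3	LOC4339885	6	1521	1	1	0
T	D3	LOC9272469	6	2163	5	4	0
T	MOC1	LOC107278653	6	1326	2	0	0
T	OsSPL14	LOC4345998	8	1257	4	1	0
T	D53	LOC4349543	11	3396	5	2	1
TGW	Gn1a	LOC4327333	1	1698	5	2	2
TGW	GW2	LOC4328856	2	1278	1	0	0
TGW	GS3	LOC9269602	3	699	2	1	0
TGW	GIF1	LOC4335790	4	1797	3	1	1
TGW	GW5	LOC4338011	5	1413	3	1	0
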