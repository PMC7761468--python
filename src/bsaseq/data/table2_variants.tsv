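# Non-synonymous candidate-gene variants with per-bulk frequencies (%).
# cov_source: "published" where the original report prints the coverage at that
# variant; "synthetic" where it does not and a typical 40x stand-in is used
# (the verification outcome is frequency-driven; see docs/methods.md).
# published_mark: 1 where the original report marked the variant as a verified TAV.
# note: printed inconsistencies carried verbatim, never silently corrected.
trait	gene	gene_id	low_freq	high_freq	low_cov	high_cov	cov_source	kind	nuc_change	aa_change	bulk	published_mark	note
Hd	Hd3a	LOC4340185	17	65	40	40	synthetic	SNV	GCA > GGA	Ala100Gly	HdH	0
Hd	Hd3a	LOC4340185	15	46	40	40	synthetic	SNV	GTC > ATC	Val177Ile	HdH	0
Hd	Hd3a	LOC4340185	12	80	40	28	published	MNV	CCC > AAC	Pro179Asn	HdH	1	position 2942292^2942293, exon 4
Hd	Hd3b	LOC4340184	23	50	40	40	synthetic	SNV	GGC > CGC	Gly3Arg	HdH	0
Hd	Hd3b	LOC4340184	21	50	40	40	synthetic	SNV	AGC > ATC	Ser4Ile	HdH	0
Hd	Hd3b	LOC4340184	2	62	40	40	synthetic	SNV	GTC > GCC	Val31Ala	HdH	0
Hd	Hd3b	LOC4340184	0	55	40	40	synthetic	SNV	AAG > ACG	Lys45Thr	HdH	0
Hd	Hd5	LOC4344784	8	56	40	40	synthetic	SNV	GTA > GGA	Tyr189Ser	HdH	0
Hd	Ehd3	LOC4344443	62	40	40	40	synthetic	INS	Ins CCG	19insPro	HdL	0
Hd	Ehd1	LOC107276289	79	43	40	40	synthetic	SNV	TTC > TTT	Glu311Lys	HdL	0	printed TTC>TTT is Phe=Phe; aa change as printed
Hd	Ehd1	LOC107276289	78	44	40	40	synthetic	SNV	GTC > GTT	Asp195Asn	HdL	0	printed GTC>GTT is Val=Val; aa change as printed
Hd	Ehd2	LOC4348644	100	21	39	39	published	INS	Ins TGT	77insAsn	HdL	1	text says 277insAsn and TGT=Cys; table value kept
T	D10	LOC4326177	11	86	35	49	published	SNV	TTT > GTT	Lys565Asn	TH	1	minus-strand gene; plus-strand triplet printed
T	OsTB1	LOC4333856	0	23	40	40	synthetic	INS	Ins (GCG)*5	112-1116insAla*5	TH	0
T	HTD1	LOC4336591	0	51	40	40	synthetic	DEL	Del (GCC)*4	Ala*4 41-44del	TH	0
T	HTD1	LOC4336591	12	53	40	40	synthetic	SNV	CTC > GTC	Leu334Val	TH	0
T	DWARF3	LOC4339885	23	54	40	40	synthetic	SNV	ACC > TCC	Thr500Ser	TH	0
T	D3	LOC9272469	26	71	40	40	synthetic	INS	Ins (GAG)*3	7-10insGlu*3	TH	0
T	D3	LOC9272469	0	55	40	40	synthetic	INS	Ins GCG	111insGly	TH	0	GCG=Ala, printed as Gly; kept as printed
T	D3	LOC9272469	42	61	40	40	synthetic	SNV	GGT > TGT	Gly498Cys	TH	0
T	D3	LOC9272469	33	68	40	40	synthetic	SNV	GAT > GAG	Asp514Glu	TH	0
T	OsSPL14	LOC4345998	51	38	40	40	synthetic	SNV	CGG > TGG	Ala317Thr	TL	0	CGG>TGG is Arg>Trp; aa change as printed
T	D53	LOC4349543	8	60	40	40	synthetic	DEL	Del GAG	Glu 1070del	TH	0
T	D53	LOC4349543	12	75	40	57	published	SNV	GCA > ACA	Ala1113Thr	TH	1	dagger-marked at 75% despite the stated >80% rule
TGW	Gn1a	LOC4327333	14	77	40	30	published	SNV	CGC > AGC	Ale105Ser	TGWH	1	"Ale" presumed typo for Arg (CGC=Arg); dagger at 77% despite the >80% rule
TGW	Gn1a	LOC4327333	13	88	40	40	published	INS	Ins (CGG)*2	81-82insAla*2	TGWH	1	position 5275281^5275282
TGW	GS3	LOC9269602	69	5	40	40	synthetic	DEL	Del AGG	Ser123del	TGWL	0
TGW	GIF1	LOC4335790	84	18	32	38	published	SNV	ACC > GCC	Thr40Ala	TGWL	1
TGW	GW5	LOC4338011	18	47	40	40	synthetic	DEL	Del GCG	Gly 365del	TGWH	0
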