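# Six genome-wide trait-associated SNPs: printed (coverage, frequency, zygosity)
# pairs per bulk, amino-acid change, trait and gene/enzyme assignment.
chrom	pos	ref	alt	low_cov	low_freq	low_zygo	high_cov	high_freq	high_zygo	aa_change	trait	gene_id	enzyme
Chr06	3151977	G	A	54	19	Het	51	82	Het	Leu151Phe	Hd	LOC107275952	1.13.11.51-dioxygenase
Chr04	1971432	G	A	28	29	Het	28	97	Hom	Arg94Gln	TGW	LOC107275432	1.13.11.51-dioxygenase
Chr04	20422339	A	G	32	84	Het	38	18	Het	Thr40Ala	TGW	LOC4335790	3.2.1.26-invertase
Chr07	4834141	T	C	51	80	Het	38	18	Het	Ser73Pro	TGW	LOC107275425	2.5.1.75-transferase
Chr03	33906284	A	G	36	14	Het	50	96	Hom	Ser113Gly	T	LOC4334529	2.5.1.75-transferase
Chr01	31225473	T	G	35	11	Het	49	86	Het	Lys565Asn	T	LOC4326177	1.13.11.69-synthase
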