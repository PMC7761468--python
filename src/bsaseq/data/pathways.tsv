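# Gene -> enzyme -> pathway cross-reference for the six genome-wide TAV
# genes (synthetic lookup table standing in for a live annotation service).
gene_id	enzyme	pathway
LOC107275952	1.13.11.51-dioxygenase	carotenoid biosynthesis
LOC107275432	1.13.11.51-dioxygenase	carotenoid biosynthesis
LOC4335790	3.2.1.26-invertase	starch and sucrose metabolism
LOC107275425	2.5.1.75-transferase	zeatin biosynthesis
LOC4334529	2.5.1.75-transferase	zeatin biosynthesis
LOC4326177	1.13.11.69-synthase	carotenoid biosynthesis
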