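# Methods

## The design being emulated

The package models a two-bulk BSA-seq study on an interspecific rice
backcross population: a recurrent parent crossed to a donor parent, the
F1 backcrossed twice to the recurrent parent (BC2), then selfed by
single-seed descent to BC2F9.  Under this scheme the expected donor-allele
frequency at any site is (1/2)^(b+1) = 1/8 for b = 2 backcrosses, and the
expected per-site heterozygosity is (1/2)^b · (1/2)^(s−1) ≈ 9.8 × 10⁻⁴ at
s = 9 — the lines are effectively inbred, so a line contributes either
two recurrent or two donor alleles to a pool at almost every site.  Both
closed forms are asserted against simulation in the test suite and
recomputed by `scripts/acceptance.py`.

## Synthetic material

`generate_parents` builds A/C/G/T chromosomes, places non-overlapping
protein-coding genes (1–3 CDS exons, 60–100 codons, both strands, valid
ORFs: ATG start, no internal stop, length divisible by 3), and plants
polymorphic sites, a configurable fraction inside CDS.  The default site
mix is SNV-only, which keeps the two parental assemblies position-wise
comparable (the donor differs from the recurrent assembly at exactly
`n_sites` positions); MNV/insertion/deletion sites are available through
`site_type_weights` and are exercised directly in the annotation and
candidate-gene tests.  Coding donor alleles are chosen so they never
create a stop codon and never touch the start codon, keeping the donor
CDS translatable.

Meiosis is the simplest model consistent with a mosaic BIL genome:
crossover count per chromosome ~ Poisson(`recomb_rate`), uniform
breakpoints, no interference, random start phase.  `recomb_rate` defaults
to 1.0 expected crossover per chromosome per meiosis — the order of
magnitude of a real rice chromosome (~1–2 Morgans) — applied to the
desk-scale 50 kb chromosomes; linkage in the simulation is therefore
genetic, not physical.  Selfing is single-seed descent, one offspring per
line per generation, and every line is an independent lineage.

Phenotypes are Gaussian-additive: value = baseline + Σ effect × donor
dosage + a per-line environmental effect shared by the two "generations"
+ independent per-generation measurement noise.  The split matters: the
stability filter acts on the between-generation difference, which under
this model is N(0, 2·measurement_sd²) and independent of genotype, so a
k = 2 filter removes ≈ 4.6% of lines without biasing the bulks.  Default
architectures give each trait one major causal coding locus (Hd: baseline
95 d, effect +5 d, environmental SD 3, measurement SD 2; T: 12 tillers,
+2, 1.5, 1; TGW: 28 g, +1.5 g, 1, 0.8).  One major locus is the regime
the category scheme is designed for: with several equal loci the
phenotype tail splits among them and per-locus pooled frequencies sit
near 50%, which the het-het bounds deliberately exclude.  Polygenic
architectures remain available via `n_causal_per_trait`.

What the generator does **not** emulate: read-level errors correlated by
position or strand, mapping artefacts near indels, PCR duplicates,
segregation distortion, genotype × environment interaction, and linkage
disequilibrium structure beyond the Poisson-crossover model.  Passing
tests therefore demonstrate the correctness and calibration of the
filtration chain under its own assumptions, not robustness to real
sequencing pathologies.

## Pooled sequencing model

True pooled frequency p = Σ dosage / (2 × bulk size); depth ~ Poisson(μ)
with μ = 45 by default (the study's post-mapping coverage range is
41–54×); alternate count ~ Binomial(D, p(1−ε) + (1−p)ε/3) with a flat
base-call error ε = 0.003, a typical Illumina substitution rate.  The
ε/3 term is why a donor-absent site still shows ≈ 0.1% alternate reads.
Frequencies are carried as exact ratios internally and rounded to whole
percent only in reports.

## Thresholds

All defaults are the study's values: calling at coverage ≥ 10, count ≥ 2,
frequency ≥ 10%; mutation test at coverage ≥ 10 with no frequency floor
in the opposite bulk; Hom at ≥ 95%; category bounds < 30 and > 70;
chi-square α = 0.01 with no continuity correction and no
multiple-testing adjustment (a Bonferroni option exists, off by default);
final TAV split at ≥ 80 / ≤ 20 (inclusive — a published locus prints
exactly 80% and is retained); candidate-gene consensus masking below 5×.
Threshold inclusivity was fixed from the published worked examples:
96–97% are labelled Hom and 29% passes the "< 30" side, so Hom is
inclusive at 95 and the low bound strict at 30.  The calling and
consensus coverage thresholds (10 and 5) are deliberately independent,
stage-local parameters.

The het-het bound notation in the source is ambiguous; this package reads
it as "one bulk > 70%, the other < 30%", the only reading consistent with
every published disposition.  The published candidate table also marks
two variants (75% and 77%) as verified despite the stated > 80% rule;
the implementation applies the stated rule and reports the divergence
(`run_fixture_tables` / `bsaseq fixtures`) rather than replicating the
looser marking.

## Effect annotation

Coordinates are 0-based half-open internally, 1-based inclusive in
reports, with caret notation (`pos^pos+1`) for insertions.  Substituted
bases are mapped into CDS coordinates honouring strand and exon
junctions; all changed bases within one codon are evaluated as a single
MNV codon change, adjacent SNVs in one codon are merged before
annotation, and substitutions in different codons are annotated
independently.  Both the coding-strand codons and the plus-strand
genomic triplets are reported, because published tables print plus-strand
triplets for minus-strand genes while naming amino acids from the coding
strand.  In-frame indels at codon boundaries report the inserted/deleted
residues (`19insPro`, `Ala*4 41-44del`); off-phase in-frame indels report
the local before/after peptide; other indels are frameshifts.  Variants
partially overlapping CDS (spanning an exon boundary) are flagged
unsupported rather than guessed.  Translation uses the standard genetic
code with stops reported as `Ter`.

## Candidate genes

Consensus extraction is majority-allele per position with ties resolved
to the reference — conservative, avoiding fabricated segregating sites at
50/50 sampling noise — and N below the coverage threshold.  Three-way
comparison uses exact positional comparison when lengths match and
affine-gap global alignment (match 2, mismatch −3, open −5, extend −2)
when indels change length; the original interactive alignment step had no
published parameters, so these are ordinary DNA alignment scores.
Variants shared by both bulks but differing from the reference are
non-causal parental polymorphisms and never reach any TAV output;
segregating non-synonymous variants are verified with exactly the
association rule (`verify_frequency_rule` is the single authority used by
both the simulated path and the fixture re-analysis).

## Numerical choices

The 2×2 Pearson statistic is computed directly from expected counts and
its p-value from `scipy.stats.chi2.sf`; tests cross-check it against
`scipy.stats.chi2_contingency` to 10⁻⁹ and against Fisher's exact test
for rank ordering at fixed margins.  Counts are reconstructed from
printed whole-percent frequencies as round(freq/100 × coverage), half
away from zero.  Tables with a zero margin raise an explicit
undefined-test error.  Bulk-size rounding is ceiling (285 × 0.05 → 15).
Ties in phenotype ranking break by individual id, making bulk selection
deterministic.  All randomness flows from one integer seed through
deterministic, stage-labelled substreams (CRC32 of the stage name mixed
into a `SeedSequence`), so identical config + seed reproduces
byte-identical artifacts.

## Problem sizes

Desk-scale defaults — 3 chromosomes × 50 kb, 200 sites, 20 genes, 285
lines — keep a full pipeline run under a second while preserving every
statistical property of interest.  The test suite uses 2 × 30 kb with 80
sites; inheritance checks use 2,000–4,000 lines (the sampling unit for
standard errors is the individual, since linked sites within a line are
correlated); the type-I simulation uses 10,000 null loci and the recovery
simulation 100 replicates of the single-locus selection chain at 40×
depth and 15-member bulks.

## Known limitations

Only the two-allele (ref/alt) case is modelled; third alleles arising
from error are ignored, and loci whose alleles disagree between bulks are
excluded as multi-allelic with a logged warning.  The genome-wide path
considers SNV/MNV records only for the chi-square route (indels are
carried to the candidate-gene analysis), mirroring the original chain.
No read-level simulation, mapping, or indel realignment is performed —
the pipeline's unit is per-site allele counts.  No G′ / SNP-index
smoothing or sliding-window QTL-seq statistics: the method is
per-variant by design.
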