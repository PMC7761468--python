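"""Synthetic study material: parental genomes, gene models, a backcross
inbred line (BIL) population, and noisy two-generation phenotypes.

The generator emulates the material of an interspecific rice backcross
design: a recurrent parent (the reference-like genome) and a donor parent
differing at a known set of polymorphic sites, crossed once, backcrossed
``b`` times to the recurrent parent, then selfed by single-seed descent to
near-homozygosity.  Three quantitative traits (heading date Hd, tiller
number T, 1000 grain weight TGW) are driven by planted causal loci with
additive effects plus Gaussian noise, and each trait is "measured" in two
consecutive generations.

Expected allele dynamics used throughout the tests:

* donor-allele frequency after ``b`` backcrosses: ``(1/2)**(b+1)``
* per-site heterozygosity in BC``b``F``s``:
  ``(1/2)**b * (1/2)**(s-1)`` (each selfing round halves heterozygosity)

All randomness flows from a single integer seed; stage-local substreams are
spawned deterministically with :class:`numpy.random.SeedSequence`.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "GenomeAssembly",
    "GeneModel",
    "PolymorphicSite",
    "BILIndividual",
    "TraitArchitecture",
    "Parents",
    "SizingError",
    "ConfigurationError",
    "generate_parents",
    "simulate_population",
    "assign_phenotypes",
    "dosage_matrix",
    "default_architectures",
    "TRAITS",
]

TRAITS = ("Hd", "T", "TGW")

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS and a + b + c != "ATG"
]


class SizingError(ValueError):
    """Requested dimensions cannot be packed into the genome."""


class ConfigurationError(ValueError):
    """Inconsistent run configuration."""


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GenomeAssembly:
    """Ordered map of chromosome name -> A/C/G/T sequence."""

    chromosomes: Mapping[str, str]

    def __post_init__(self) -> None:
        names = list(self.chromosomes)
        if len(names) != len(set(names)):
            raise ValueError("chromosome names must be unique")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name} is empty")
            if set(seq) - set(_BASES):
                raise ValueError(f"chromosome {name} has non-ACGT characters")

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]


@dataclass(frozen=True)
class GeneModel:
    """A protein-coding gene: ordered CDS intervals on one strand.

    ``cds_intervals`` are 0-based half-open genome coordinates in ascending
    genome order; transcription order is ascending for ``+`` genes and
    descending for ``-`` genes.  The concatenated CDS must be a valid ORF
    (length divisible by 3, starts with ATG, no internal stop).
    """

    gene_id: str
    chrom: str
    strand: str
    cds_intervals: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")
        ivs = self.cds_intervals
        if not ivs:
            raise ValueError("gene needs at least one CDS interval")
        for (s, e) in ivs:
            if e <= s:
                raise ValueError("empty CDS interval")
        for (_, e1), (s2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError("CDS intervals overlap or are unsorted")
        if self.cds_length % 3:
            raise ValueError("CDS length must be divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds_intervals)

    @property
    def span(self) -> tuple[int, int]:
        return self.cds_intervals[0][0], self.cds_intervals[-1][1]

    def genomic_positions(self) -> list[int]:
        """Genome coordinates of CDS bases in transcription order."""
        pos: list[int] = []
        if self.strand == "+":
            for s, e in self.cds_intervals:
                pos.extend(range(s, e))
        else:
            for s, e in reversed(self.cds_intervals):
                pos.extend(range(e - 1, s - 1, -1))
        return pos

    def coding_sequence(self, assembly: GenomeAssembly) -> str:
        chrom = assembly[self.chrom]
        if self.strand == "+":
            return "".join(chrom[s:e] for s, e in self.cds_intervals)
        return "".join(
            _revcomp(chrom[s:e]) for s, e in reversed(self.cds_intervals)
        )

    def contains(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.cds_intervals)


@dataclass(frozen=True)
class PolymorphicSite:
    """A locus where the recurrent and donor assemblies differ.

    Alleles use VCF-style anchored strings: an SNV has two single bases,
    an insertion ``ref=X alt=X...``, a deletion ``ref=X... alt=X``, an MNV
    two equal-length multi-base strings.
    """

    chrom: str
    pos: int  # 0-based anchor position in the recurrent assembly
    recurrent_allele: str
    donor_allele: str
    site_type: str  # SNV | MNV | INS | DEL
    in_gene: str | None = None

    def __post_init__(self) -> None:
        if self.recurrent_allele == self.donor_allele:
            raise ValueError("alleles must differ")
        if self.site_type == "MNV" and (
            len(self.recurrent_allele) != len(self.donor_allele)
            or len(self.recurrent_allele) < 2
        ):
            raise ValueError("MNV alleles must be same length > 1")


@dataclass
class BILIndividual:
    """One backcross inbred line: two haplotypes over the site list plus
    per-trait (generation-1, generation-2) phenotype values."""

    individual_id: str
    hap1: np.ndarray  # uint8, 1 = donor allele
    hap2: np.ndarray
    phenotypes: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def dosage(self) -> np.ndarray:
        """Diploid donor-allele dosage in {0,1,2} at every site."""
        return (self.hap1 + self.hap2).astype(np.int64)


@dataclass(frozen=True)
class TraitArchitecture:
    """Generative model for one quantitative trait.

    ``causal_sites`` maps site index (into the parents' site list) to an
    additive per-allele effect.  ``environmental_sd`` is a per-line effect
    shared by the two generations (micro-environment / background);
    ``measurement_sd`` is drawn independently per generation and is what
    the stability filter acts on.
    """

    trait: str
    causal_sites: tuple[tuple[int, float], ...]
    baseline: float
    environmental_sd: float
    measurement_sd: float

    def __post_init__(self) -> None:
        if self.environmental_sd < 0 or self.measurement_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class Parents:
    """Output bundle of :func:`generate_parents`."""

    recurrent: GenomeAssembly
    donor: GenomeAssembly
    genes: tuple[GeneModel, ...]
    sites: tuple[PolymorphicSite, ...]

    def sites_on(self, chrom: str) -> list[int]:
        return [i for i, s in enumerate(self.sites) if s.chrom == chrom]


# ---------------------------------------------------------------------------
# parental genome generation
# ---------------------------------------------------------------------------


def _random_orf(rng: np.random.Generator, n_codons: int) -> str:
    codons = rng.choice(_SENSE_CODONS, size=n_codons - 1)
    return "ATG" + "".join(codons)


def _place_gene(
    rng: np.random.Generator,
    gene_id: str,
    chrom: str,
    slot_start: int,
    slot_end: int,
) -> GeneModel:
    n_exons = int(rng.integers(1, 4))
    n_codons = int(rng.integers(60, 101))
    total = 3 * n_codons
    # split CDS into exons of >= 21 bp each
    cuts = sorted(rng.choice(range(21, total - 20), size=n_exons - 1, replace=False)) if n_exons > 1 else []
    lengths = np.diff([0, *cuts, total]).tolist()
    introns = [int(rng.integers(30, 80)) for _ in range(n_exons - 1)]
    span = total + sum(introns)
    if span + 2 > slot_end - slot_start:
        raise SizingError(
            f"gene {gene_id}: span {span} does not fit slot of "
            f"{slot_end - slot_start} bp"
        )
    start = slot_start + int(rng.integers(0, slot_end - slot_start - span))
    intervals = []
    cursor = start
    for i, ln in enumerate(lengths):
        intervals.append((cursor, cursor + ln))
        cursor += ln + (introns[i] if i < len(introns) else 0)
    strand = "+" if rng.random() < 0.5 else "-"
    return GeneModel(gene_id, chrom, strand, tuple(intervals))


def _write_orf(chrom_seq: list[str], gene: GeneModel, orf: str) -> None:
    positions = gene.genomic_positions()
    for i, pos in enumerate(positions):
        base = orf[i]
        chrom_seq[pos] = base if gene.strand == "+" else base.translate(_COMPLEMENT)


def _coding_snv(
    rng: np.random.Generator, gene: GeneModel, assembly_seq: dict[str, list[str]]
) -> tuple[int, str, str] | None:
    """Pick a CDS position (not in the start codon) and a donor base that
    does not create a stop codon; return (genome_pos, ref, alt)."""
    positions = gene.genomic_positions()
    coding = [
        assembly_seq[gene.chrom][p] if gene.strand == "+"
        else assembly_seq[gene.chrom][p].translate(_COMPLEMENT)
        for p in positions
    ]
    for _ in range(40):
        ci = int(rng.integers(3, len(positions)))
        codon_start = 3 * (ci // 3)
        codon = coding[codon_start : codon_start + 3]
        within = ci - codon_start
        ref_coding = codon[within]
        alts = [b for b in _BASES if b != ref_coding]
        rng.shuffle(alts)
        for alt_coding in alts:
            new_codon = codon.copy()
            new_codon[within] = alt_coding
            if "".join(new_codon) in _STOPS:
                continue
            pos = positions[ci]
            ref = assembly_seq[gene.chrom][pos]
            alt = alt_coding if gene.strand == "+" else alt_coding.translate(_COMPLEMENT)
            return pos, ref, alt
    return None


def generate_parents(
    n_chrom: int = 3,
    chrom_length: int = 50_000,
    n_sites: int = 200,
    n_genes: int = 20,
    seed: int = 0,
    coding_fraction: float = 0.3,
    site_type_weights: Mapping[str, float] | None = None,
) -> Parents:
    """Generate a recurrent and a donor parental assembly differing at
    ``n_sites`` polymorphic sites, plus ``n_genes`` valid gene models.

    ``coding_fraction`` of the sites are placed inside CDS (on genes of
    both strands); the rest are intergenic.  ``site_type_weights`` maps
    site types to sampling weights and defaults to SNVs only, keeping the
    two assemblies position-comparable.  MNV/INS/DEL sites are restricted
    to intergenic space (coding indel/MNV constructs are exercised through
    the annotation API directly).
    """
    if n_sites < 1:
        raise SizingError("a BSA run needs at least one segregating site")
    if n_chrom < 1 or chrom_length < 1000:
        raise SizingError("need >= 1 chromosome of >= 1 kb")
    weights = dict(site_type_weights or {"SNV": 1.0})
    if any(t not in ("SNV", "MNV", "INS", "DEL") for t in weights):
        raise ConfigurationError(f"unknown site type in {weights}")

    ss = np.random.SeedSequence(seed)
    rng_seq, rng_gene, rng_site = (
        np.random.default_rng(s) for s in ss.spawn(3)
    )

    names = [f"Chr{i + 1:02d}" for i in range(n_chrom)]
    seqs: dict[str, list[str]] = {
        name: list(rng_seq.choice(list(_BASES), size=chrom_length))
        for name in names
    }

    # genes: round-robin over chromosomes, one non-overlapping slot each
    genes: list[GeneModel] = []
    per_chrom = [n_genes // n_chrom + (1 if i < n_genes % n_chrom else 0) for i in range(n_chrom)]
    for ci, (name, g_count) in enumerate(zip(names, per_chrom)):
        if g_count == 0:
            continue
        slot = chrom_length // g_count
        if slot < 700:
            raise SizingError(
                f"{g_count} genes do not fit on a {chrom_length} bp chromosome"
            )
        for gi in range(g_count):
            gene = _place_gene(
                rng_gene,
                f"GENE{len(genes) + 1:04d}",
                name,
                gi * slot + 50,
                (gi + 1) * slot - 50,
            )
            _write_orf(seqs[name], gene, _random_orf(rng_gene, gene.cds_length // 3))
            genes.append(gene)

    # polymorphic sites
    n_coding = int(round(coding_fraction * n_sites)) if genes else 0
    sites: list[PolymorphicSite] = []
    taken: set[tuple[str, int]] = set()

    coding_genes = list(genes)
    attempts = 0
    while len(sites) < n_coding:
        attempts += 1
        if attempts > 50 * n_sites:
            raise SizingError("cannot place the requested coding sites")
        gene = coding_genes[int(rng_site.integers(len(coding_genes)))]
        picked = _coding_snv(rng_site, gene, seqs)
        if picked is None:
            continue
        pos, ref, alt = picked
        if any((gene.chrom, pos + d) in taken for d in range(-6, 7)):
            continue
        sites.append(PolymorphicSite(gene.chrom, pos, ref, alt, "SNV", gene.gene_id))
        taken.add((gene.chrom, pos))

    type_names = list(weights)
    type_p = np.array([weights[t] for t in type_names], dtype=float)
    type_p /= type_p.sum()
    gene_spans = {
        name: [(g.span[0] - 10, g.span[1] + 10) for g in genes if g.chrom == name]
        for name in names
    }
    attempts = 0
    while len(sites) < n_sites:
        attempts += 1
        if attempts > 200 * n_sites:
            raise SizingError("cannot place the requested intergenic sites")
        name = names[int(rng_site.integers(n_chrom))]
        pos = int(rng_site.integers(10, chrom_length - 10))
        if any(s <= pos < e for s, e in gene_spans[name]):
            continue
        if any((name, pos + d) in taken for d in range(-6, 7)):
            continue
        stype = type_names[int(rng_site.choice(len(type_names), p=type_p))]
        ref_base = seqs[name][pos]
        if stype == "SNV":
            alt = str(rng_site.choice([b for b in _BASES if b != ref_base]))
            ref = ref_base
        elif stype == "MNV":
            ln = int(rng_site.integers(2, 4))
            ref = "".join(seqs[name][pos : pos + ln])
            alt = "".join(
                str(rng_site.choice([b for b in _BASES if b != r])) for r in ref
            )
        elif stype == "INS":
            ln = int(rng_site.integers(1, 5))
            ref = ref_base
            alt = ref_base + "".join(rng_site.choice(list(_BASES), size=ln))
        else:  # DEL
            ln = int(rng_site.integers(1, 5))
            ref = "".join(seqs[name][pos : pos + 1 + ln])
            alt = ref_base
        sites.append(PolymorphicSite(name, pos, ref, alt, stype, None))
        taken.add((name, pos))

    sites.sort(key=lambda s: (s.chrom, s.pos))

    recurrent = GenomeAssembly({name: "".join(seqs[name]) for name in names})
    donor = GenomeAssembly(
        {name: _apply_edits(seqs[name], [s for s in sites if s.chrom == name]) for name in names}
    )

    # sanity: every gene is a valid ORF in the recurrent assembly
    for gene in genes:
        cds = gene.coding_sequence(recurrent)
        if not cds.startswith("ATG"):
            raise AssertionError(f"{gene.gene_id}: CDS lacks start codon")
        internal = [cds[i : i + 3] for i in range(0, len(cds) - 3, 3)]
        if any(c in _STOPS for c in internal):
            raise AssertionError(f"{gene.gene_id}: internal stop codon")

    return Parents(recurrent, donor, tuple(genes), tuple(sites))


def _apply_edits(seq: list[str], sites: Sequence[PolymorphicSite]) -> str:
    out = seq.copy()
    for s in sorted(sites, key=lambda s: -s.pos):
        out[s.pos : s.pos + len(s.recurrent_allele)] = list(s.donor_allele)
    return "".join(out)


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------


def _gamete(
    hap1: np.ndarray,
    hap2: np.ndarray,
    chrom_index: np.ndarray,
    site_pos: np.ndarray,
    chrom_lengths: np.ndarray,
    recomb_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One meiotic product: Poisson crossover count per chromosome,
    uniform breakpoints, no interference."""
    phase = np.empty(hap1.shape, dtype=np.int64)
    for c in range(len(chrom_lengths)):
        mask = chrom_index == c
        if not mask.any():
            continue
        k = rng.poisson(recomb_rate)
        start = int(rng.integers(2))
        if k == 0:
            phase[mask] = start
        else:
            breaks = np.sort(rng.uniform(0, chrom_lengths[c], size=k))
            phase[mask] = (start + np.searchsorted(breaks, site_pos[mask])) % 2
    return np.where(phase == 0, hap1, hap2)


def simulate_population(
    parents: Parents,
    n_individuals: int = 285,
    n_backcrosses: int = 2,
    n_selfing_generations: int = 9,
    recomb_rate: float = 1.0,
    seed: int = 0,
) -> list[BILIndividual]:
    """Simulate BC``b``F``s`` backcross inbred lines by single-seed descent.

    Each line is an independent lineage: F1 (donor x recurrent) is
    backcrossed ``n_backcrosses`` times to the recurrent parent, then
    selfed for ``n_selfing_generations - 1`` rounds (the BC offspring is
    F1 of the inbreeding phase).  ``recomb_rate`` is the expected number
    of crossovers per chromosome per meiosis.
    """
    if n_individuals < 1:
        raise SizingError("population needs at least one individual")
    if n_backcrosses < 1 or n_selfing_generations < 1:
        raise ConfigurationError("need >= 1 backcross and >= 1 selfing generation")

    names = list(parents.recurrent.chromosomes)
    chrom_of = {n: i for i, n in enumerate(names)}
    chrom_index = np.array([chrom_of[s.chrom] for s in parents.sites])
    site_pos = np.array([s.pos for s in parents.sites], dtype=float)
    chrom_lengths = np.array(
        [len(parents.recurrent[n]) for n in names], dtype=float
    )
    n_sites = len(parents.sites)

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    zeros = np.zeros(n_sites, dtype=np.uint8)
    ones = np.ones(n_sites, dtype=np.uint8)

    population: list[BILIndividual] = []
    for i in range(n_individuals):
        hap_a, hap_b = ones.copy(), zeros.copy()  # F1
        for _ in range(n_backcrosses):
            g = _gamete(hap_a, hap_b, chrom_index, site_pos, chrom_lengths, recomb_rate, rng)
            hap_a, hap_b = g, zeros.copy()  # recurrent gamete is all-recurrent
        for _ in range(n_selfing_generations - 1):
            g1 = _gamete(hap_a, hap_b, chrom_index, site_pos, chrom_lengths, recomb_rate, rng)
            g2 = _gamete(hap_a, hap_b, chrom_index, site_pos, chrom_lengths, recomb_rate, rng)
            hap_a, hap_b = g1, g2
        population.append(
            BILIndividual(f"BIL{i + 1:04d}", hap_a.astype(np.uint8), hap_b.astype(np.uint8))
        )
    return population


def dosage_matrix(population: Sequence[BILIndividual]) -> np.ndarray:
    """(n_individuals, n_sites) donor-allele dosage matrix."""
    return np.stack([ind.dosage for ind in population])


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------


def assign_phenotypes(
    population: Sequence[BILIndividual],
    architectures: Sequence[TraitArchitecture],
    seed: int = 0,
) -> list[BILIndividual]:
    """Fill two-generation phenotype values in place (and return the list).

    generation value = baseline + sum(effect x dosage) + line environmental
    effect (shared between generations) + per-generation measurement noise.
    """
    n_sites = len(population[0].hap1)
    for arch in architectures:
        if not arch.causal_sites:
            raise ConfigurationError(f"{arch.trait}: no causal sites")
        for idx, _ in arch.causal_sites:
            if not (0 <= idx < n_sites):
                raise ConfigurationError(
                    f"{arch.trait}: causal site index {idx} not in site list"
                )
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    dosages = dosage_matrix(population)
    for arch in architectures:
        genetic = arch.baseline + sum(
            eff * dosages[:, idx] for idx, eff in arch.causal_sites
        )
        env = rng.normal(0.0, arch.environmental_sd, size=len(population)) if arch.environmental_sd else 0.0
        g1 = genetic + env + (rng.normal(0.0, arch.measurement_sd, size=len(population)) if arch.measurement_sd else 0.0)
        g2 = genetic + env + (rng.normal(0.0, arch.measurement_sd, size=len(population)) if arch.measurement_sd else 0.0)
        g1 = np.broadcast_to(np.asarray(g1, dtype=float), (len(population),))
        g2 = np.broadcast_to(np.asarray(g2, dtype=float), (len(population),))
        for ind, v1, v2 in zip(population, g1, g2):
            ind.phenotypes[arch.trait] = (float(v1), float(v2))
    return list(population)


def default_architectures(
    parents: Parents, seed: int = 0, n_causal: int = 1
) -> list[TraitArchitecture]:
    """Study-condition trait models: heading date in days, tiller count,
    1000 grain weight in grams, each driven by ``n_causal`` coding sites
    with effects large enough to separate the phenotype tails."""
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(3)[2])
    coding = [i for i, s in enumerate(parents.sites) if s.in_gene]
    if len(coding) < 3 * n_causal:
        raise ConfigurationError("not enough coding sites for three traits")
    picks = rng.choice(coding, size=3 * n_causal, replace=False)
    params = {
        "Hd": (95.0, 5.0, 3.0, 2.0),  # baseline days, effect, env sd, meas sd
        "T": (12.0, 2.0, 1.5, 1.0),
        "TGW": (28.0, 1.5, 1.0, 0.8),
    }
    archs = []
    for t, trait in enumerate(TRAITS):
        base, eff, env, meas = params[trait]
        causal = tuple(
            (int(picks[t * n_causal + j]), eff) for j in range(n_causal)
        )
        archs.append(TraitArchitecture(trait, causal, base, env, meas))
    return archs
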