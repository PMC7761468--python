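"""File formats: FASTA / GFF3 / VCF 4.2 / TSV emission and ingestion.

FASTA goes through Biopython; GFF3 and VCF are emitted as plain text
records for the synthetic truth tracks and per-bulk call sets (GFF3
1-based inclusive CDS features; VCF with INFO keys DP, AC, AF, ZYG).
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .calling import SiteCounts, VariantCall
from .synthetic import (
    BILIndividual,
    GeneModel,
    GenomeAssembly,
    PolymorphicSite,
)

__all__ = [
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
    "write_truth_vcf",
    "write_calls_vcf",
    "write_genotypes_tsv",
    "write_phenotypes_tsv",
    "read_phenotypes_tsv",
]


def write_fasta(assembly: GenomeAssembly, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="")
        for name, seq in assembly.chromosomes.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> GenomeAssembly:
    return GenomeAssembly(
        {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
    )


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """CDS features, 1-based inclusive coordinates, grouped per gene."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gene in genes:
            start, end = gene.span
            fh.write(
                f"{gene.chrom}\tbsaseq\tgene\t{start + 1}\t{end}\t.\t"
                f"{gene.strand}\t.\tID={gene.gene_id}\n"
            )
            for i, (s, e) in enumerate(gene.cds_intervals, 1):
                fh.write(
                    f"{gene.chrom}\tbsaseq\tCDS\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t0\tID={gene.gene_id}.cds{i};Parent={gene.gene_id}\n"
                )


def read_gff3(path: str | Path) -> list[GeneModel]:
    per_gene: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            if ftype != "CDS":
                continue
            fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            gid = fields.get("Parent") or fields["ID"].rsplit(".cds", 1)[0]
            g = per_gene.setdefault(gid, {"chrom": chrom, "strand": strand, "ivs": []})
            g["ivs"].append((int(start) - 1, int(end)))
    return [
        GeneModel(gid, g["chrom"], g["strand"], tuple(sorted(g["ivs"])))
        for gid, g in per_gene.items()
    ]


_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Pooled read depth">
##INFO=<ID=AC,Number=1,Type=Integer,Description="Alternate read count">
##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele frequency">
##INFO=<ID=ZYG,Number=1,Type=String,Description="Pooled zygosity call (Hom/Het)">
##INFO=<ID=TYPE,Number=1,Type=String,Description="Variant type (SNV/MNV/INS/DEL)">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def _contig_lines(assembly: GenomeAssembly | None) -> str:
    if assembly is None:
        return ""
    return "".join(
        f"##contig=<ID={name},length={len(seq)}>\n"
        for name, seq in assembly.chromosomes.items()
    )


def write_truth_vcf(
    sites: Sequence[PolymorphicSite],
    path: str | Path,
    assembly: GenomeAssembly | None = None,
) -> None:
    """Planted polymorphic sites with the donor allele as ALT."""
    with open(path, "w") as fh:
        header = _VCF_HEADER.split("\n")
        fh.write(header[0] + "\n" + _contig_lines(assembly))
        fh.write("\n".join(header[1:]))
        for s in sorted(sites, key=lambda s: (s.chrom, s.pos)):
            info = f"TYPE={s.site_type}"
            fh.write(
                f"{s.chrom}\t{s.pos + 1}\t.\t{s.recurrent_allele}\t"
                f"{s.donor_allele}\t.\tPASS\t{info}\n"
            )


def write_calls_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    assembly: GenomeAssembly | None = None,
) -> None:
    with open(path, "w") as fh:
        header = _VCF_HEADER.split("\n")
        fh.write(header[0] + "\n" + _contig_lines(assembly))
        fh.write("\n".join(header[1:]))
        for c in sorted(calls, key=lambda c: (c.chrom, c.pos)):
            info = (
                f"DP={c.depth};AC={c.alt_count};AF={c.frequency / 100:.4f};"
                f"ZYG={c.zygosity};TYPE={c.variant_type}"
            )
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref_allele}\t{c.alt_allele}\t"
                f".\tPASS\t{info}\n"
            )


_TAV_VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=CAT,Number=1,Type=String,Description="Zygosity category (hom-hom/hom-het/het-hom/het-het/unclassified)">
##INFO=<ID=CHI2P,Number=1,Type=Float,Description="Chi-square p-value (het-het loci only)">
##INFO=<ID=TAV,Number=0,Type=Flag,Description="Passes the trait-associated variant selection rule">
##INFO=<ID=LAF,Number=1,Type=Float,Description="Low-bulk alternate frequency">
##INFO=<ID=HAF,Number=1,Type=Float,Description="High-bulk alternate frequency">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_tav_vcf(records, path: str | Path, assembly: GenomeAssembly | None = None) -> None:
    """Association results as VCF: category, chi-square p and TAV flag."""
    with open(path, "w") as fh:
        header = _TAV_VCF_HEADER.split("\n")
        fh.write(header[0] + "\n" + _contig_lines(assembly))
        fh.write("\n".join(header[1:]))
        for r in sorted(records, key=lambda r: (r.comparison.chrom, r.comparison.pos)):
            c = r.comparison
            info = [
                f"CAT={r.category.value}",
                f"LAF={c.low.frequency / 100:.4f}",
                f"HAF={c.high.frequency / 100:.4f}",
            ]
            if r.p_value is not None:
                info.append(f"CHI2P={r.p_value:.4g}")
            if r.is_tav:
                info.append("TAV")
            fh.write(
                f"{c.chrom}\t{c.pos + 1}\t.\t{c.ref_allele}\t{c.alt_allele}\t"
                f".\tPASS\t{';'.join(info)}\n"
            )


def write_genotypes_tsv(
    population: Sequence[BILIndividual],
    sites: Sequence[PolymorphicSite],
    path: str | Path,
) -> None:
    """Dosage matrix: one row per individual, one column per site."""
    cols = [f"{s.chrom}:{s.pos + 1}" for s in sites]
    df = pd.DataFrame(
        [ind.dosage for ind in population],
        index=[ind.individual_id for ind in population],
        columns=cols,
    )
    df.index.name = "individual_id"
    df.to_csv(path, sep="\t")


def write_phenotypes_tsv(
    population: Sequence[BILIndividual], path: str | Path
) -> None:
    rows = []
    for ind in population:
        for trait, (g1, g2) in ind.phenotypes.items():
            rows.append((ind.individual_id, trait, g1, g2))
    pd.DataFrame(
        rows, columns=["individual_id", "trait", "gen1", "gen2"]
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
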