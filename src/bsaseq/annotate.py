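"""Amino-acid effect annotation of variants against gene models.

Maps genome positions into CDS coordinates honoring strand and exon
junctions, evaluates substitutions codon-by-codon (adjacent substituted
bases inside one codon are a single MNV codon change), classifies indels
as in-frame or frameshift, and reports changes in the field's notation
(``Pro179Asn``, ``19insPro``, ``Glu 1070del``).

Coordinates are 0-based half-open internally and 1-based inclusive in all
reports; insertions are reported with caret notation between the flanking
positions (``2942292^2942293``).  Both the coding-strand codons and the
plus-strand genomic triplets are carried, because published tables print
plus-strand triplets for minus-strand genes while naming amino acids from
the coding strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from Bio.Seq import Seq
from Bio.SeqUtils import seq3

from .synthetic import GeneModel, GenomeAssembly, PolymorphicSite

__all__ = [
    "EffectAnnotation",
    "AnnotationError",
    "NONSYNONYMOUS_EFFECTS",
    "translate",
    "annotate_effect",
    "filter_nonsynonymous",
    "merge_adjacent_substitutions",
    "position_label",
]

_BASES = set("ACGT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

NONSYNONYMOUS_EFFECTS = frozenset(
    {"missense", "stop_gained", "inframe_insertion", "inframe_deletion", "frameshift"}
)


class AnnotationError(ValueError):
    pass


def translate(codon: str) -> str:
    """Standard-genetic-code translation of one codon to a 3-letter amino
    acid code; stop codons translate to ``Ter``."""
    if len(codon) != 3 or set(codon) - _BASES:
        raise AnnotationError(f"not an A/C/G/T codon: {codon!r}")
    return seq3(str(Seq(codon).translate(table=1)))


def _translate_seq(cds: str) -> str:
    """3-letter-per-residue translation of a CDS prefix divisible by 3."""
    usable = len(cds) - len(cds) % 3
    return "".join(translate(cds[i : i + 3]) for i in range(0, usable, 3))


@dataclass(frozen=True)
class EffectAnnotation:
    gene_id: str | None
    effect: str  # synonymous|missense|stop_gained|inframe_insertion|
    #             inframe_deletion|frameshift|non_coding|unsupported
    chrom: str
    pos: int  # 0-based genomic anchor
    ref_allele: str
    alt_allele: str
    exon_index: int | None = None  # 1-based, transcription order
    coding_codon_before: str | None = None
    coding_codon_after: str | None = None
    genomic_triplet_before: str | None = None
    genomic_triplet_after: str | None = None
    aa_before: str | None = None
    aa_after: str | None = None
    aa_position: int | None = None
    notation: str | None = None

    @property
    def is_nonsynonymous(self) -> bool:
        return self.effect in NONSYNONYMOUS_EFFECTS

    @property
    def nuc_change(self) -> str:
        if len(self.ref_allele) == len(self.alt_allele):
            return f"{self.ref_allele} > {self.alt_allele}"
        if len(self.alt_allele) > len(self.ref_allele):
            return f"Ins {self.alt_allele[len(self.ref_allele):]}"
        return f"Del {self.ref_allele[len(self.alt_allele):]}"


def position_label(pos: int, ref: str, alt: str) -> str:
    """1-based report coordinate; insertions use caret notation between
    the flanking bases."""
    if len(alt) > len(ref):
        return f"{pos + 1}^{pos + 2}"
    return str(pos + 1)


def _alleles(variant) -> tuple[str, int, str, str]:
    if isinstance(variant, PolymorphicSite):
        return variant.chrom, variant.pos, variant.recurrent_allele, variant.donor_allele
    return variant.chrom, variant.pos, variant.ref_allele, variant.alt_allele


def _exon_index(gene: GeneModel, pos: int) -> int | None:
    ivs = list(gene.cds_intervals)
    if gene.strand == "-":
        ivs = ivs[::-1]
    for i, (s, e) in enumerate(ivs, start=1):
        if s <= pos < e:
            return i
    return None


def _residue_run(residues: list[str]) -> str:
    """'Pro' for one residue, 'Glu*3' for a homorun, concatenation else."""
    if len(residues) == 1:
        return residues[0]
    if len(set(residues)) == 1:
        return f"{residues[0]}*{len(residues)}"
    return "".join(residues)


def annotate_effect(
    variant, gene: GeneModel | None, reference: GenomeAssembly
) -> EffectAnnotation:
    """Annotate one variant against one gene model (or None -> intergenic).

    Substitutions are evaluated on the coding strand, with all changed
    bases of one codon treated as a single codon change; in-frame indels
    report the inserted/deleted residues; indels whose length is not a
    multiple of 3 are frameshifts.  Variants partially overlapping CDS
    (spanning an exon boundary) are flagged ``unsupported``.
    """
    chrom, pos, ref, alt = _alleles(variant)
    chrom_seq = reference[chrom]
    if not (0 <= pos < len(chrom_seq)):
        raise AnnotationError(f"position {pos} outside {chrom}")
    if chrom_seq[pos : pos + len(ref)] != ref:
        raise AnnotationError(
            f"reference mismatch at {chrom}:{pos + 1}: expected {ref}, "
            f"found {chrom_seq[pos:pos + len(ref)]}"
        )

    def plain(effect: str) -> EffectAnnotation:
        return EffectAnnotation(
            gene.gene_id if gene else None, effect, chrom, pos, ref, alt
        )

    if gene is None or gene.chrom != chrom:
        return plain("non_coding")

    posmap = {p: i for i, p in enumerate(gene.genomic_positions())}
    cds = list(gene.coding_sequence(reference))
    minus = gene.strand == "-"

    if len(ref) == len(alt):  # SNV / MNV substitution
        changed = [i for i in range(len(ref)) if ref[i] != alt[i]]
        if not changed:  # reference-identical: synonymous, identical codons
            ci = posmap.get(pos)
            if ci is None:
                return plain("non_coding")
            codon = "".join(cds[3 * (ci // 3) : 3 * (ci // 3) + 3])
            aa = translate(codon)
            return EffectAnnotation(
                gene.gene_id, "synonymous", chrom, pos, ref, alt,
                exon_index=_exon_index(gene, pos),
                coding_codon_before=codon, coding_codon_after=codon,
                aa_before=aa, aa_after=aa, aa_position=ci // 3 + 1,
                notation=f"{aa}{ci // 3 + 1}=",
            )
        idxs = [posmap.get(pos + i) for i in changed]
        if all(i is None for i in idxs):
            return plain("non_coding")
        if any(i is None for i in idxs):
            return plain("unsupported")
        mutant = cds.copy()
        for i, ci in zip(changed, idxs):
            b = alt[i]
            mutant[ci] = b.translate(_COMPLEMENT) if minus else b
        codons = sorted({ci // 3 for ci in idxs})
        pieces = []
        effects = []
        for c in codons:
            before = "".join(cds[3 * c : 3 * c + 3])
            after = "".join(mutant[3 * c : 3 * c + 3])
            aa_b, aa_a = translate(before), translate(after)
            if aa_b == aa_a:
                effects.append("synonymous")
                pieces.append((c, before, after, aa_b, aa_a, f"{aa_b}{c + 1}="))
            else:
                effects.append("stop_gained" if aa_a == "Ter" else "missense")
                pieces.append((c, before, after, aa_b, aa_a, f"{aa_b}{c + 1}{aa_a}"))
        if "stop_gained" in effects:
            effect = "stop_gained"
        elif "missense" in effects:
            effect = "missense"
        else:
            effect = "synonymous"
        c0, before, after, aa_b, aa_a, notation = pieces[0]
        if len(pieces) > 1:
            notation = "/".join(p[5] for p in pieces)
        codon_positions = sorted(
            p for p, i in posmap.items() if i // 3 == c0
        )
        trip_b = "".join(chrom_seq[p] for p in codon_positions)
        mutated_chrom = dict(zip(range(pos, pos + len(alt)), alt))
        trip_a = "".join(mutated_chrom.get(p, chrom_seq[p]) for p in codon_positions)
        return EffectAnnotation(
            gene.gene_id, effect, chrom, pos, ref, alt,
            exon_index=_exon_index(gene, pos + changed[0]),
            coding_codon_before=before, coding_codon_after=after,
            genomic_triplet_before=trip_b, genomic_triplet_after=trip_a,
            aa_before=aa_b, aa_after=aa_a, aa_position=c0 + 1,
            notation=notation,
        )

    if len(alt) > len(ref):  # insertion after `pos`
        ins = alt[len(ref):]
        left, right = posmap.get(pos), posmap.get(pos + 1)
        if left is None and right is None:
            return plain("non_coding")
        if left is None or right is None:
            return plain("unsupported")
        if abs(left - right) != 1:
            return plain("unsupported")
        # transcription-order index before which the coding-strand insert lands
        ins_at = right if not minus else left
        coding_ins = ins if not minus else ins.translate(_COMPLEMENT)[::-1]
        exon = _exon_index(gene, pos)
        if len(ins) % 3:
            return EffectAnnotation(
                gene.gene_id, "frameshift", chrom, pos, ref, alt,
                exon_index=exon, aa_position=ins_at // 3 + 1,
                notation=f"{translate(''.join(cds[3 * (ins_at // 3):3 * (ins_at // 3) + 3]))}"
                f"{ins_at // 3 + 1}fs",
            )
        if ins_at % 3 == 0:  # codon-boundary insertion
            residues = [translate(coding_ins[i : i + 3]) for i in range(0, len(coding_ins), 3)]
            effect = "stop_gained" if "Ter" in residues else "inframe_insertion"
            run = _residue_run(residues)
            return EffectAnnotation(
                gene.gene_id, effect, chrom, pos, ref, alt,
                exon_index=exon, aa_before="", aa_after=run,
                aa_position=ins_at // 3,
                notation=f"{ins_at // 3}ins{run}",
            )
        # off-phase in-frame insertion: report the local before/after peptide
        c = ins_at // 3
        local_before = "".join(cds[3 * c : 3 * c + 3])
        mutant = cds[:ins_at] + list(coding_ins) + cds[ins_at:]
        local_after = "".join(mutant[3 * c : 3 * c + 3 + len(coding_ins)])
        aa_b = translate(local_before)
        aa_a = _translate_seq(local_after)
        effect = "stop_gained" if "Ter" in aa_a else "inframe_insertion"
        return EffectAnnotation(
            gene.gene_id, effect, chrom, pos, ref, alt,
            exon_index=exon, coding_codon_before=local_before,
            aa_before=aa_b, aa_after=aa_a, aa_position=c + 1,
            notation=f"{aa_b}{c + 1}delins{aa_a}",
        )

    # deletion of ref[1:] after the anchor base
    deleted = range(pos + 1, pos + len(ref))
    idxs = [posmap.get(p) for p in deleted]
    if all(i is None for i in idxs):
        return plain("non_coding")
    if any(i is None for i in idxs):
        return plain("unsupported")
    idxs = sorted(idxs)
    exon = _exon_index(gene, pos + 1)
    if len(deleted) % 3:
        return EffectAnnotation(
            gene.gene_id, "frameshift", chrom, pos, ref, alt,
            exon_index=exon, aa_position=idxs[0] // 3 + 1,
            notation=f"{translate(''.join(cds[3 * (idxs[0] // 3):3 * (idxs[0] // 3) + 3]))}"
            f"{idxs[0] // 3 + 1}fs",
        )
    if idxs[0] % 3 == 0:  # whole-codon deletion
        residues = [
            translate("".join(cds[i : i + 3])) for i in range(idxs[0], idxs[-1] + 1, 3)
        ]
        first, last = idxs[0] // 3 + 1, idxs[-1] // 3 + 1
        run = _residue_run(residues)
        notation = (
            f"{run} {first}del" if first == last else f"{run} {first}-{last}del"
        )
        return EffectAnnotation(
            gene.gene_id, "inframe_deletion", chrom, pos, ref, alt,
            exon_index=exon, aa_before=run, aa_after="",
            aa_position=first, notation=notation,
        )
    # off-phase in-frame deletion
    c_first, c_last = idxs[0] // 3, idxs[-1] // 3
    local_before = "".join(cds[3 * c_first : 3 * c_last + 3])
    keep = [b for i, b in enumerate(cds) if not (idxs[0] <= i <= idxs[-1])]
    local_after = "".join(keep[3 * c_first : 3 * c_first + 3])
    aa_b = _translate_seq(local_before)
    aa_a = _translate_seq(local_after)
    return EffectAnnotation(
        gene.gene_id, "inframe_deletion", chrom, pos, ref, alt,
        exon_index=exon, aa_before=aa_b, aa_after=aa_a,
        aa_position=c_first + 1,
        notation=f"{aa_b}{c_first + 1}delins{aa_a}",
    )


def filter_nonsynonymous(
    annotations: Iterable[EffectAnnotation],
) -> list[EffectAnnotation]:
    """Keep missense, stop-gained, in-frame indels and frameshifts; drop
    synonymous, non-coding and unsupported records."""
    return [a for a in annotations if a.is_nonsynonymous]


def merge_adjacent_substitutions(
    sites: Sequence[PolymorphicSite],
    genes: Sequence[GeneModel],
) -> list[PolymorphicSite]:
    """Merge genomically adjacent SNVs that fall in the same codon of the
    same gene into one MNV; all other sites pass through unchanged."""
    by_gene = {g.gene_id: g for g in genes}
    out: list[PolymorphicSite] = []
    ordered = sorted(sites, key=lambda s: (s.chrom, s.pos))
    i = 0
    while i < len(ordered):
        s = ordered[i]
        if s.site_type != "SNV" or s.in_gene not in by_gene:
            out.append(s)
            i += 1
            continue
        gene = by_gene[s.in_gene]
        posmap = {p: k for k, p in enumerate(gene.genomic_positions())}
        run = [s]
        while (
            i + len(run) < len(ordered)
            and (nxt := ordered[i + len(run)]).site_type == "SNV"
            and nxt.in_gene == s.in_gene
            and nxt.chrom == s.chrom
            and nxt.pos == run[-1].pos + 1
            and posmap.get(nxt.pos) is not None
            and posmap.get(run[-1].pos) is not None
            and posmap[nxt.pos] // 3 == posmap[run[0].pos] // 3
        ):
            run.append(nxt)
        if len(run) == 1:
            out.append(s)
        else:
            out.append(
                PolymorphicSite(
                    s.chrom, s.pos,
                    "".join(r.recurrent_allele for r in run),
                    "".join(r.donor_allele for r in run),
                    "MNV", s.in_gene,
                )
            )
        i += len(run)
    return out
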