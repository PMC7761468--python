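"""Targeted candidate-gene analysis.

For each gene of a candidate panel, a per-bulk consensus coding sequence
is reconstructed from pooled counts (majority allele per position, ties to
the reference, positions under a low coverage threshold masked with N),
the two bulk consensuses are compared three-way with the reference CDS,
and every difference is classified:

* ``shared_nonref`` - both bulks carry the same non-reference allele:
  a parental polymorphism uninformative for the trait contrast (non-causal);
* ``segregating`` - the bulks disagree: a possible causal variant.

Non-synonymous segregating variants are then verified with the same
category + chi-square + 80/20 frequency rule as the genome-wide
association path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from Bio import Align

from .annotate import _translate_seq, translate
from .association import (
    CategoryLabel,
    UndefinedTestError,
    chi_square_2x2,
    classify_category,
    reconstruct_alt_count,
)
from .calling import SiteCounts
from .synthetic import GeneModel, GenomeAssembly

__all__ = [
    "GeneConsensus",
    "CandidateVariant",
    "extract_consensus",
    "compare_gene",
    "cds_effect",
    "verify_frequency_rule",
    "verify_candidate_tavs",
    "run_candidate_panel",
]

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class GeneConsensus:
    gene_id: str
    bulk_label: str
    sequence: str  # coding-strand CDS consensus, N at masked positions
    masked_fraction: float


@dataclass
class CandidateVariant:
    """One three-way difference within a candidate gene's CDS."""

    gene_id: str
    cds_pos: int  # 0-based position in the reference CDS
    ref_allele: str
    low_allele: str
    high_allele: str
    kind: str  # SNV | MNV | INS | DEL
    classification: str  # shared_nonref | segregating
    effect: str = "unknown"  # synonymous | missense | ... (coding-strand)
    notation: str = ""
    low_freq: float | None = None
    high_freq: float | None = None
    low_cov: int | None = None
    high_cov: int | None = None
    verified_tav: bool = False


# ---------------------------------------------------------------------------
# consensus extraction
# ---------------------------------------------------------------------------


def extract_consensus(
    gene: GeneModel,
    reference: GenomeAssembly,
    counts: Sequence[SiteCounts],
    bulk_label: str,
    min_coverage: int = 5,
    depth_at: Mapping[int, int] | int = 45,
) -> GeneConsensus:
    """Majority-allele consensus of a gene's CDS for one bulk.

    ``counts`` carries the pooled observations at the polymorphic sites
    inside the gene; every other CDS position is covered at ``depth_at``
    (a constant or a genomic-position map) and agrees with the reference.
    Positions under ``min_coverage`` become N; the alternate allele enters
    the consensus only where it holds a strict read majority (ties resolve
    to the reference).
    """
    minus = gene.strand == "-"
    positions = gene.genomic_positions()
    posmap = {p: i for i, p in enumerate(positions)}
    cds = list(gene.coding_sequence(reference))

    def depth_of(p: int) -> int:
        if isinstance(depth_at, int):
            return depth_at
        return depth_at.get(p, 0)

    depths = [depth_of(p) for p in positions]
    site_here = [c for c in counts if c.chrom == gene.chrom and c.pos in posmap]
    for c in site_here:
        span = range(c.pos, c.pos + len(c.ref_allele))
        for p in span:
            if p in posmap:
                depths[posmap[p]] = c.depth

    masked = [d < min_coverage for d in depths]
    if all(masked):
        logger.warning("gene %s entirely uncovered in %s", gene.gene_id, bulk_label)
        return GeneConsensus(gene.gene_id, bulk_label, "N" * len(cds), 1.0)

    # base layer: reference with N masks
    out = ["N" if m else b for b, m in zip(cds, masked)]

    # site layer: majority alternate alleles, as cds-coordinate edits
    edits: list[tuple[int, int, str]] = []  # (cds_start, n_removed, inserted)
    for c in site_here:
        if c.depth < min_coverage:
            continue
        if c.alt_count * 2 <= c.depth:  # no strict majority -> reference
            continue
        lr, la = len(c.ref_allele), len(c.alt_allele)
        if lr == la:  # SNV / MNV
            for i in range(lr):
                p = c.pos + i
                if p not in posmap:
                    continue
                b = c.alt_allele[i]
                out[posmap[p]] = b.translate(_COMPLEMENT) if minus else b
        elif la > lr:  # insertion after anchor
            left, right = posmap.get(c.pos), posmap.get(c.pos + 1)
            if left is None or right is None or abs(left - right) != 1:
                continue
            ins = c.alt_allele[lr:]
            coding_ins = ins if not minus else ins.translate(_COMPLEMENT)[::-1]
            edits.append((right if not minus else left, 0, coding_ins))
        else:  # deletion after anchor
            idxs = sorted(
                posmap[p] for p in range(c.pos + 1, c.pos + lr) if p in posmap
            )
            if idxs:
                edits.append((idxs[0], len(idxs), ""))
    for start, n_removed, inserted in sorted(edits, reverse=True):
        out[start : start + n_removed] = list(inserted)

    seq = "".join(out)
    return GeneConsensus(
        gene.gene_id, bulk_label, seq, sum(masked) / len(masked)
    )


# ---------------------------------------------------------------------------
# three-way comparison
# ---------------------------------------------------------------------------


def _aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 2
    a.mismatch_score = -3
    a.open_gap_score = -5
    a.extend_gap_score = -2
    return a


def _diff_to_reference(ref: str, seq: str) -> tuple[dict[int, str], dict[int, str], set[int]]:
    """(substitutions, insertions-after, deleted positions) of ``seq``
    relative to ``ref``; exact positional fast path when lengths match."""
    subs: dict[int, str] = {}
    ins: dict[int, str] = {}
    dels: set[int] = set()
    if len(seq) == len(ref):
        for i, (r, s) in enumerate(zip(ref, seq)):
            if s != r and s != "N":
                subs[i] = s
        return subs, ins, dels
    if set(seq) <= {"N"}:
        return subs, ins, dels
    alignment = _aligner().align(ref, seq)[0]
    ref_blocks, seq_blocks = alignment.aligned
    prev_r = prev_s = 0
    for (rs, re), (ss, se) in zip(ref_blocks, seq_blocks):
        if rs > prev_r:  # deletion in seq
            dels.update(range(prev_r, rs))
        if ss > prev_s:  # insertion in seq, anchored after ref position prev_r-1
            ins[prev_r - 1] = seq[prev_s:ss]
        for i in range(re - rs):
            r, s = ref[rs + i], seq[ss + i]
            if s != r and s != "N":
                subs[rs + i] = s
        prev_r, prev_s = re, se
    if prev_r < len(ref):
        dels.update(range(prev_r, len(ref)))
    if prev_s < len(seq):
        ins[prev_r - 1] = seq[prev_s:]
    return subs, ins, dels


def _merge_runs(positions: Sequence[int]) -> list[list[int]]:
    runs: list[list[int]] = []
    for p in sorted(positions):
        if runs and p == runs[-1][-1] + 1:
            runs[-1].append(p)
        else:
            runs.append([p])
    return runs


def cds_effect(ref_cds: str, pos: int, ref_allele: str, alt_allele: str) -> tuple[str, str]:
    """(effect class, notation) of a coding-strand CDS edit."""
    lr, la = len(ref_allele), len(alt_allele)
    if lr == la:  # substitution
        mutant = list(ref_cds)
        mutant[pos : pos + lr] = list(alt_allele)
        codons = sorted({c // 3 for c in range(pos, pos + lr)})
        labels, effects = [], []
        for c in codons:
            b = ref_cds[3 * c : 3 * c + 3]
            a = "".join(mutant[3 * c : 3 * c + 3])
            if len(b) < 3:
                continue
            aa_b, aa_a = translate(b), translate(a)
            if aa_b == aa_a:
                effects.append("synonymous")
                labels.append(f"{aa_b}{c + 1}=")
            else:
                effects.append("stop_gained" if aa_a == "Ter" else "missense")
                labels.append(f"{aa_b}{c + 1}{aa_a}")
        if "stop_gained" in effects:
            return "stop_gained", "/".join(labels)
        if "missense" in effects:
            return "missense", "/".join(labels)
        return "synonymous", "/".join(labels)
    if la > lr:  # insertion (alt carries extra bases after shared prefix)
        ins = alt_allele[lr:]
        if len(ins) % 3:
            return "frameshift", f"{pos // 3 + 1}fs"
        at = pos + lr
        if at % 3 == 0:
            residues = [translate(ins[i : i + 3]) for i in range(0, len(ins), 3)]
            run = residues[0] if len(residues) == 1 else (
                f"{residues[0]}*{len(residues)}" if len(set(residues)) == 1 else "".join(residues)
            )
            eff = "stop_gained" if "Ter" in residues else "inframe_insertion"
            return eff, f"{at // 3}ins{run}"
        return "inframe_insertion", f"{at // 3 + 1}delins"
    # deletion
    removed = ref_allele[la:]
    if len(removed) % 3:
        return "frameshift", f"{pos // 3 + 1}fs"
    at = pos + la
    if at % 3 == 0:
        residues = [
            translate(ref_cds[i : i + 3]) for i in range(at, at + len(removed), 3)
        ]
        run = residues[0] if len(residues) == 1 else (
            f"{residues[0]}*{len(residues)}" if len(set(residues)) == 1 else "".join(residues)
        )
        first, last = at // 3 + 1, (at + len(removed)) // 3
        label = f"{run} {first}del" if first == last else f"{run} {first}-{last}del"
        return "inframe_deletion", label
    return "inframe_deletion", f"{at // 3 + 1}delins"


def compare_gene(
    gene_id: str,
    reference_cds: str,
    consensus_low: GeneConsensus,
    consensus_high: GeneConsensus,
) -> list[CandidateVariant]:
    """Three-way comparison of the reference CDS and the two bulk
    consensuses; every difference becomes a classified variant.  Masked
    (N) positions are skipped."""
    if set(consensus_low.sequence) <= {"N"} and set(consensus_high.sequence) <= {"N"}:
        logger.warning("gene %s: both consensuses fully masked", gene_id)
        return []
    subs_l, ins_l, dels_l = _diff_to_reference(reference_cds, consensus_low.sequence)
    subs_h, ins_h, dels_h = _diff_to_reference(reference_cds, consensus_high.sequence)
    variants: list[CandidateVariant] = []

    for run in _merge_runs(set(subs_l) | set(subs_h)):
        start, end = run[0], run[-1] + 1
        ref = reference_cds[start:end]
        low = "".join(subs_l.get(p, reference_cds[p]) for p in run)
        high = "".join(subs_h.get(p, reference_cds[p]) for p in run)
        alt = low if low != ref else high
        effect, notation = cds_effect(reference_cds, start, ref, alt)
        variants.append(
            CandidateVariant(
                gene_id, start, ref, low, high,
                "SNV" if end - start == 1 else "MNV",
                "shared_nonref" if low == high else "segregating",
                effect, notation,
            )
        )
    for anchor in sorted(set(ins_l) | set(ins_h)):
        il, ih = ins_l.get(anchor, ""), ins_h.get(anchor, "")
        ref = reference_cds[anchor] if anchor >= 0 else ""
        alt_ins = il or ih
        effect, notation = cds_effect(reference_cds, max(anchor, 0), ref, ref + alt_ins)
        variants.append(
            CandidateVariant(
                gene_id, max(anchor, 0), ref, ref + il, ref + ih, "INS",
                "shared_nonref" if il == ih else "segregating",
                effect, notation,
            )
        )
    for run in _merge_runs(dels_l | dels_h):
        start, end = run[0], run[-1] + 1
        anchor = max(start - 1, 0)
        ref = reference_cds[anchor:end]
        low = ref if not set(run) <= dels_l else reference_cds[anchor:start]
        high = ref if not set(run) <= dels_h else reference_cds[anchor:start]
        effect, notation = cds_effect(reference_cds, anchor, ref, reference_cds[anchor:start])
        variants.append(
            CandidateVariant(
                gene_id, anchor, ref, low, high, "DEL",
                "shared_nonref" if low == high else "segregating",
                effect, notation,
            )
        )
    variants.sort(key=lambda v: v.cds_pos)
    return variants


# ---------------------------------------------------------------------------
# verification
# ---------------------------------------------------------------------------


def verify_frequency_rule(
    low_freq: float,
    high_freq: float,
    low_cov: int | None,
    high_cov: int | None,
    is_nonsynonymous: bool,
    alpha: float = 0.01,
    final_high: float = 80.0,
    final_low: float = 20.0,
) -> bool:
    """The association rule applied to one candidate variant: category
    from the paired frequencies; het-het needs the chi-square (on counts
    reconstructed from frequency x coverage) and the inclusive 80/20
    split; hom-het / het-hom qualify by category.  Synonymous variants
    are never eligible."""
    if not is_nonsynonymous:
        return False
    category = classify_category(low_freq, high_freq)
    if category in (CategoryLabel.HOM_HET, CategoryLabel.HET_HOM):
        return True
    if category is not CategoryLabel.HET_HET:
        return False
    split = (low_freq >= final_high and high_freq <= final_low) or (
        high_freq >= final_high and low_freq <= final_low
    )
    if not split:
        return False
    if low_cov is None or high_cov is None:
        return False  # cannot run the test -> reported unverified
    alt_l = reconstruct_alt_count(low_freq, low_cov)
    alt_h = reconstruct_alt_count(high_freq, high_cov)
    try:
        _, p = chi_square_2x2(alt_l, low_cov - alt_l, alt_h, high_cov - alt_h)
    except UndefinedTestError:
        return False
    return p < alpha


def verify_candidate_tavs(
    variants: Sequence[CandidateVariant],
    alpha: float = 0.01,
    final_high: float = 80.0,
    final_low: float = 20.0,
) -> list[CandidateVariant]:
    """Flag ``verified_tav`` on non-synonymous segregating variants whose
    bulk frequencies pass the association rule; variants lacking frequency
    data stay unverified."""
    out = []
    for v in variants:
        ok = False
        if (
            v.classification == "segregating"
            and v.low_freq is not None
            and v.high_freq is not None
        ):
            ok = verify_frequency_rule(
                v.low_freq, v.high_freq, v.low_cov, v.high_cov,
                v.effect in ("missense", "stop_gained", "inframe_insertion",
                             "inframe_deletion", "frameshift"),
                alpha, final_high, final_low,
            )
        out.append(replace_variant(v, verified_tav=ok))
    return out


def replace_variant(v: CandidateVariant, **kw) -> CandidateVariant:
    d = dict(v.__dict__)
    d.update(kw)
    return CandidateVariant(**d)


def run_candidate_panel(
    panel: Sequence[str],
    variants_by_gene: Mapping[str, Sequence[CandidateVariant]],
) -> tuple[list[dict], list[str]]:
    """Per-gene summary over a candidate panel.

    Returns (rows, missing): one row per known gene with total variant,
    between-bulk (segregating), non-synonymous-segregating and verified
    TAV counts; panel ids absent from ``variants_by_gene`` are listed as
    missing and the run continues.
    """
    rows, missing = [], []
    nonsyn = {"missense", "stop_gained", "inframe_insertion",
              "inframe_deletion", "frameshift"}
    for gene_id in panel:
        if gene_id not in variants_by_gene:
            missing.append(gene_id)
            logger.warning("panel gene %s not found", gene_id)
            continue
        vs = list(variants_by_gene[gene_id])
        seg = [v for v in vs if v.classification == "segregating"]
        ns = [v for v in seg if v.effect in nonsyn]
        rows.append(
            {
                "gene_id": gene_id,
                "total_variants": len(vs),
                "between_bulk_variants": len(seg),
                "nonsynonymous": len(ns),
                "verified_tavs": sum(v.verified_tav for v in vs),
            }
        )
    return rows, missing
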