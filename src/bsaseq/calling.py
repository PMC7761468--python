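"""Pooled variant calling and the between-bulk mutation test.

The pipeline's unit is per-site allele counts, not reads.  Simulation mode
models pooled sequencing of a DNA bulk: per-site depth is Poisson around
the mean, and the alternate-read count is binomial around the bulk's true
pooled allele frequency perturbed by a flat base-call error (an erroneous
base is one of the three others uniformly, so a true-negative site still
shows alternate reads at rate error/3).

Calling keeps sites passing minimum coverage, minimum alternate count and
minimum frequency (defaults 10 / 2 / 10%).  The mutation test then pairs
every call in one bulk with the raw counts at the same locus in the
opposite bulk (coverage >= 10 there, no frequency floor), which is what
makes hom-het contrasts observable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .bulks import BulkDefinition
from .synthetic import BILIndividual, ConfigurationError, PolymorphicSite

__all__ = [
    "SiteCounts",
    "VariantCall",
    "BulkComparison",
    "pool_and_sample",
    "call_variants",
    "mutation_test",
    "paired_comparisons",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SiteCounts:
    """Raw pooled counts for one locus in one bulk."""

    chrom: str
    pos: int  # 0-based
    ref_allele: str
    alt_allele: str
    depth: int
    alt_count: int
    bulk_label: str

    def __post_init__(self) -> None:
        if not (0 <= self.alt_count <= self.depth):
            raise ValueError("need 0 <= alt_count <= depth")

    @property
    def frequency(self) -> float:
        """Alternate-allele frequency as a percentage (0 if uncovered)."""
        return 100.0 * self.alt_count / self.depth if self.depth else 0.0

    @property
    def locus(self) -> tuple[str, int]:
        return (self.chrom, self.pos)


@dataclass(frozen=True)
class VariantCall(SiteCounts):
    """A SiteCounts that passed the calling filters."""

    zygosity: str = "Het"  # Hom | Het
    variant_type: str = "SNV"


@dataclass(frozen=True)
class BulkComparison:
    """Paired low-bulk / high-bulk observations at one locus."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    low: SiteCounts
    high: SiteCounts
    variant_type: str = "SNV"

    def __post_init__(self) -> None:
        for side in (self.low, self.high):
            if side.locus != (self.chrom, self.pos) or (
                side.ref_allele != self.ref_allele
                or side.alt_allele != self.alt_allele
            ):
                raise ValueError("comparison sides must share locus and alleles")


def _classify(site: PolymorphicSite) -> str:
    return site.site_type


def pool_and_sample(
    bulk: BulkDefinition,
    population: Sequence[BILIndividual],
    sites: Sequence[PolymorphicSite],
    mean_depth: float = 45.0,
    error_rate: float = 0.003,
    seed: int = 0,
) -> list[SiteCounts]:
    """Simulate pooled sequencing of one bulk over the site list.

    True pooled frequency p = sum(dosages) / (2 x bulk size); observed
    depth ~ Poisson(mean_depth) and alternate count ~ Binomial(depth,
    p(1-e) + (1-p)e/3).
    """
    if mean_depth <= 0:
        raise ConfigurationError("mean_depth must be positive")
    if not 0 <= error_rate < 0.5:
        raise ConfigurationError("error_rate must be in [0, 0.5)")
    members = [ind for ind in population if ind.individual_id in set(bulk.member_ids)]
    if not members:
        raise ConfigurationError(f"bulk {bulk.label} has no members in the population")
    rng = np.random.default_rng(seed)
    dos = np.stack([m.dosage for m in members])  # (n_members, n_sites)
    p_true = dos.sum(axis=0) / (2.0 * len(members))
    p_obs = p_true * (1.0 - error_rate) + (1.0 - p_true) * error_rate / 3.0
    depth = rng.poisson(mean_depth, size=len(sites))
    alt = rng.binomial(depth, p_obs)
    return [
        SiteCounts(s.chrom, s.pos, s.recurrent_allele, s.donor_allele,
                   int(d), int(a), bulk.label)
        for s, d, a in zip(sites, depth, alt)
    ]


def call_variants(
    counts: Iterable[SiteCounts],
    min_coverage: int = 10,
    min_count: int = 2,
    min_frequency: float = 10.0,
    hom_threshold: float = 95.0,
    variant_types: Mapping[tuple[str, int], str] | None = None,
) -> list[VariantCall]:
    """Apply the calling filters (coverage AND count AND frequency) and
    assign zygosity (Hom iff frequency >= hom_threshold)."""
    calls = []
    for c in counts:
        if c.depth < min_coverage or c.alt_count < min_count:
            continue
        if c.frequency < min_frequency:
            continue
        vtype = (variant_types or {}).get(c.locus, _infer_type(c))
        calls.append(
            VariantCall(
                c.chrom, c.pos, c.ref_allele, c.alt_allele, c.depth,
                c.alt_count, c.bulk_label,
                zygosity="Hom" if c.frequency >= hom_threshold else "Het",
                variant_type=vtype,
            )
        )
    return calls


def _infer_type(c: SiteCounts) -> str:
    lr, la = len(c.ref_allele), len(c.alt_allele)
    if lr == la == 1:
        return "SNV"
    if lr == la:
        return "MNV"
    return "INS" if la > lr else "DEL"


def mutation_test(
    variants_a: Sequence[VariantCall],
    counts_b: Iterable[SiteCounts],
    a_side: str = "high",
    min_coverage: int = 10,
) -> list[BulkComparison]:
    """Re-interrogate the opposite bulk at every called locus.

    For each variant called in bulk A, report the same locus in bulk B
    with B's raw coverage and frequency; the locus is dropped when B's
    coverage is below ``min_coverage``.  B's frequency may legitimately be
    below the calling floor (0-10% presence) - that is the point of the
    test.  Loci whose alleles disagree between the bulks are multi-allelic
    under the two-allele model and are excluded with a warning.
    """
    if a_side not in ("low", "high"):
        raise ConfigurationError("a_side must be 'low' or 'high'")
    index = {c.locus: c for c in counts_b}
    out = []
    for v in variants_a:
        other = index.get(v.locus)
        if other is None or other.depth < min_coverage:
            continue
        if (other.ref_allele, other.alt_allele) != (v.ref_allele, v.alt_allele):
            logger.warning(
                "multi-allelic locus excluded: %s:%d %s/%s vs %s/%s",
                v.chrom, v.pos + 1, v.ref_allele, v.alt_allele,
                other.ref_allele, other.alt_allele,
            )
            continue
        low, high = (other, v) if a_side == "high" else (v, other)
        out.append(
            BulkComparison(v.chrom, v.pos, v.ref_allele, v.alt_allele,
                           low, high, variant_type=v.variant_type)
        )
    return out


def paired_comparisons(
    low_calls: Sequence[VariantCall],
    low_counts: Sequence[SiteCounts],
    high_calls: Sequence[VariantCall],
    high_counts: Sequence[SiteCounts],
    min_coverage: int = 10,
) -> list[BulkComparison]:
    """Union of the two mutation-test directions, one comparison per locus
    called in at least one bulk and covered in both."""
    by_locus: dict[tuple[str, int], BulkComparison] = {}
    for cmp_ in mutation_test(high_calls, low_counts, a_side="high", min_coverage=min_coverage):
        by_locus[(cmp_.chrom, cmp_.pos)] = cmp_
    for cmp_ in mutation_test(low_calls, high_counts, a_side="low", min_coverage=min_coverage):
        by_locus.setdefault((cmp_.chrom, cmp_.pos), cmp_)
    return [by_locus[k] for k in sorted(by_locus)]
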