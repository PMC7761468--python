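"""Marker-trait association on paired bulk frequencies.

The filtration chain: each bulk's alternate-allele frequency is labelled
Hom (>= 95%) or Het; the pair of frequencies places the locus into one of
four zygosity categories (hom-hom, hom-het, het-hom, het-het); het-het
SNV/MNV loci get a Pearson chi-square test (1 df, no continuity
correction) on the 2x2 allele-count table; finally het-het loci are
trait-associated variants (TAVs) when p < 0.01 AND one bulk's frequency
is >= 80% while the other's is <= 20%.  Hom-het and het-hom loci qualify
by their category bounds alone; hom-hom loci (fixed in both bulks) and
unclassified mid-frequency loci never do.

Threshold inclusivity follows the worked examples the bounds were
calibrated on: Hom at >= 95, the "low" regime strictly < 30, the final
rule inclusive at 80/20 (a bulk printing exactly 80% is retained).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from scipy import stats

from .annotate import EffectAnnotation
from .calling import BulkComparison

__all__ = [
    "CategoryLabel",
    "TAVRecord",
    "UndefinedTestError",
    "assign_zygosity",
    "classify_category",
    "chi_square_2x2",
    "reconstruct_alt_count",
    "build_records",
    "select_tavs",
]


class UndefinedTestError(ValueError):
    """A 2x2 table with a zero margin has no chi-square test."""


class CategoryLabel(str, enum.Enum):
    HOM_HOM = "hom-hom"
    HOM_HET = "hom-het"
    HET_HOM = "het-hom"
    HET_HET = "het-het"
    UNCLASSIFIED = "unclassified"


def assign_zygosity(frequency: float, hom_threshold: float = 95.0) -> str:
    """Hom iff the pooled frequency reaches the threshold, else Het."""
    if not 0.0 <= frequency <= 100.0:
        raise ValueError("frequency must be a percentage in [0, 100]")
    return "Hom" if frequency >= hom_threshold else "Het"


def classify_category(
    low_freq: float,
    high_freq: float,
    hom_threshold: float = 95.0,
    low_bound: float = 30.0,
    high_bound: float = 70.0,
) -> CategoryLabel:
    """Place a paired observation into the four-category scheme.

    het-het means each bulk is extreme but unfixed, in opposite
    directions: one frequency > high_bound (but below Hom), the other
    < low_bound.
    """
    low_hom = low_freq >= hom_threshold
    high_hom = high_freq >= hom_threshold
    if low_hom and high_hom:
        return CategoryLabel.HOM_HOM
    if low_hom and high_freq < low_bound:
        return CategoryLabel.HOM_HET
    if high_hom and low_freq < low_bound:
        return CategoryLabel.HET_HOM
    if not low_hom and not high_hom:
        if (low_freq > high_bound and high_freq < low_bound) or (
            high_freq > high_bound and low_freq < low_bound
        ):
            return CategoryLabel.HET_HET
    return CategoryLabel.UNCLASSIFIED


def chi_square_2x2(
    alt_low: int, ref_low: int, alt_high: int, ref_high: int
) -> tuple[float, float]:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2
    allele-count table; returns (statistic, p-value)."""
    cells = (alt_low, ref_low, alt_high, ref_high)
    if any(c < 0 for c in cells):
        raise ValueError("counts must be non-negative")
    n_low = alt_low + ref_low
    n_high = alt_high + ref_high
    alt_tot = alt_low + alt_high
    ref_tot = ref_low + ref_high
    total = n_low + n_high
    if n_low == 0 or n_high == 0 or alt_tot == 0 or ref_tot == 0:
        raise UndefinedTestError("2x2 table has a zero margin")
    stat = 0.0
    for observed, row, col in (
        (alt_low, n_low, alt_tot),
        (ref_low, n_low, ref_tot),
        (alt_high, n_high, alt_tot),
        (ref_high, n_high, ref_tot),
    ):
        expected = row * col / total
        stat += (observed - expected) ** 2 / expected
    return stat, float(stats.chi2.sf(stat, df=1))


def reconstruct_alt_count(frequency: float, depth: int) -> int:
    """Alternate count from a printed whole-percent frequency:
    round(freq/100 x coverage), half away from zero."""
    return int(math.floor(frequency / 100.0 * depth + 0.5))


@dataclass(frozen=True)
class TAVRecord:
    """One locus through the full filtration chain."""

    comparison: BulkComparison
    effect: EffectAnnotation | None
    category: CategoryLabel
    chi_square_statistic: float | None = None
    p_value: float | None = None
    passes_final_frequency: bool = False
    is_tav: bool = False

    @property
    def low_freq(self) -> float:
        return self.comparison.low.frequency

    @property
    def high_freq(self) -> float:
        return self.comparison.high.frequency

    @property
    def variant_type(self) -> str:
        return self.comparison.variant_type


def build_records(
    comparisons: Iterable[BulkComparison],
    effects: dict[tuple[str, int], EffectAnnotation] | None = None,
    hom_threshold: float = 95.0,
    low_bound: float = 30.0,
    high_bound: float = 70.0,
) -> list[TAVRecord]:
    """Categorise comparisons and attach chi-square results to het-het
    loci (the only category the test applies to)."""
    records = []
    for cmp_ in comparisons:
        category = classify_category(
            cmp_.low.frequency, cmp_.high.frequency,
            hom_threshold, low_bound, high_bound,
        )
        stat = p = None
        if category is CategoryLabel.HET_HET:
            try:
                stat, p = chi_square_2x2(
                    cmp_.low.alt_count, cmp_.low.depth - cmp_.low.alt_count,
                    cmp_.high.alt_count, cmp_.high.depth - cmp_.high.alt_count,
                )
            except UndefinedTestError:
                stat = p = None
        effect = (effects or {}).get((cmp_.chrom, cmp_.pos))
        records.append(TAVRecord(cmp_, effect, category, stat, p))
    return records


def select_tavs(
    records: Sequence[TAVRecord],
    alpha: float = 0.01,
    high_bound: float = 80.0,
    low_bound: float = 20.0,
    snv_only: bool = True,
    bonferroni: bool = False,
) -> list[TAVRecord]:
    """Set the final-frequency and TAV flags.

    het-het loci need p < alpha and the inclusive 80/20 split; hom-het and
    het-hom loci qualify by category alone.  With ``snv_only`` (the
    genome-wide path) only SNV/MNV records are eligible for the het-het
    chi-square route; indels are carried to candidate-gene analysis.
    ``bonferroni`` divides alpha by the number of het-het tests performed
    (off by default: the original chain applies no multiplicity
    correction).
    """
    if bonferroni:
        n_tests = sum(
            r.category is CategoryLabel.HET_HET and r.p_value is not None
            for r in records
        )
        alpha = alpha / max(n_tests, 1)
    out = []
    for rec in records:
        lf, hf = rec.low_freq, rec.high_freq
        split = (lf >= high_bound and hf <= low_bound) or (
            hf >= high_bound and lf <= low_bound
        )
        if rec.category in (CategoryLabel.HOM_HET, CategoryLabel.HET_HOM):
            is_tav = True
        elif rec.category is CategoryLabel.HET_HET:
            eligible = rec.variant_type in ("SNV", "MNV") or not snv_only
            is_tav = bool(
                eligible and rec.p_value is not None
                and rec.p_value < alpha and split
            )
        else:
            is_tav = False
        out.append(replace(rec, passes_final_frequency=split, is_tav=is_tav))
    return out
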