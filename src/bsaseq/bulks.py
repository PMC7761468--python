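"""Phenotype-tail bulk design.

Two-generation phenotype values are averaged per line, lines whose two
measurements disagree wildly are excluded (stability filter), and the
lowest/highest tails of the averaged distribution form the two DNA bulks
per trait (HdL/HdH, TL/TH, TGWL/TGWH).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .synthetic import BILIndividual, ConfigurationError

__all__ = [
    "BulkDefinition",
    "BULK_LABELS",
    "stability_filter",
    "select_bulks",
    "phenotype_table",
    "phenotype_histogram",
]

BULK_LABELS = {"Hd": ("HdL", "HdH"), "T": ("TL", "TH"), "TGW": ("TGWL", "TGWH")}


@dataclass(frozen=True)
class BulkDefinition:
    trait: str
    label: str
    member_ids: tuple[str, ...]
    tail_fraction: float

    def __post_init__(self) -> None:
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError("duplicate members in bulk")


def phenotype_table(population: Sequence[BILIndividual], trait: str) -> pd.DataFrame:
    """Long table of (individual_id, gen1, gen2, mean) for one trait."""
    rows = []
    for ind in population:
        if trait not in ind.phenotypes:
            raise ConfigurationError(f"{ind.individual_id} lacks {trait} phenotype")
        g1, g2 = ind.phenotypes[trait]
        rows.append((ind.individual_id, g1, g2, (g1 + g2) / 2.0))
    return pd.DataFrame(rows, columns=["individual_id", "gen1", "gen2", "mean"])


def stability_filter(
    population: Sequence[BILIndividual], trait: str, k: float = 2.0
) -> list[str]:
    """Ids of lines whose between-generation difference is within
    ``k`` standard deviations of the difference distribution.

    With zero variance (all lines equally stable) nothing is excluded.
    """
    table = phenotype_table(population, trait)
    diffs = (table["gen1"] - table["gen2"]).to_numpy()
    sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
    if sd == 0.0:
        return table["individual_id"].tolist()
    keep = np.abs(diffs) <= k * sd
    return table.loc[keep, "individual_id"].tolist()


def select_bulks(
    population: Sequence[BILIndividual],
    trait: str,
    tail_fraction: float = 0.05,
    eligible_ids: Sequence[str] | None = None,
) -> tuple[BulkDefinition, BulkDefinition]:
    """Select the low and high phenotype-tail bulks for one trait.

    Bulk size is ``ceil(tail_fraction x full population size)`` (285 x 5%
    -> 15), computed on the full population even when the stability filter
    shrank the eligible set.  Ties are broken by individual id.
    """
    if not 0 < tail_fraction <= 0.5:
        raise ConfigurationError("tail_fraction must be in (0, 0.5]")
    size = math.ceil(tail_fraction * len(population))
    table = phenotype_table(population, trait)
    if eligible_ids is not None:
        table = table[table["individual_id"].isin(set(eligible_ids))]
    if len(table) < 2 * size:
        raise ConfigurationError(
            f"{trait}: {len(table)} eligible lines < 2 x bulk size {size}"
        )
    ordered = table.sort_values(["mean", "individual_id"], kind="mergesort")
    low = ordered.head(size)["individual_id"].tolist()
    high = ordered.tail(size)["individual_id"].tolist()
    low_label, high_label = BULK_LABELS.get(trait, (f"{trait}L", f"{trait}H"))
    return (
        BulkDefinition(trait, low_label, tuple(low), tail_fraction),
        BulkDefinition(trait, high_label, tuple(high), tail_fraction),
    )


def phenotype_histogram(
    population: Sequence[BILIndividual], trait: str, n_bins: int = 20
) -> pd.DataFrame:
    """Frequency-distribution bins of the averaged phenotype (the data
    behind the bulk-selection histogram); emitted as TSV by the pipeline."""
    means = phenotype_table(population, trait)["mean"].to_numpy()
    counts, edges = np.histogram(means, bins=n_bins)
    return pd.DataFrame(
        {
            "trait": trait,
            "bin_left": edges[:-1],
            "bin_right": edges[1:],
            "count": counts,
        }
    )
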