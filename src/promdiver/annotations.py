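"""Per-gene annotation flags from plain gene lists.

Disease-gene, cancer-driver, duplicate and singleton memberships arrive as
flat identifier lists (one symbol per line). Lists from multiple sources are
merged non-redundantly (set union), and every gene in the analysis universe
gets boolean flags. Duplicability is tri-state: a gene can be a duplicate, a
known singleton, or of unknown duplicability (absent from both lists) — the
last group is excluded from duplicability denominators.

No cross-database identifier mapping is attempted: all inputs must share one
gene-symbol namespace, and mismatches surface as unmatched ids.
"""

from __future__ import annotations

import warnings
from typing import AbstractSet, Iterable

import pandas as pd

__all__ = ["parse_gene_list", "merge_nonredundant", "build_flags", "FLAG_COLUMNS"]

FLAG_COLUMNS = ["is_disease", "is_cancer_driver", "is_duplicate", "is_singleton"]


def parse_gene_list(stream: Iterable[str]) -> set[str]:
    """One gene id per line; ``#`` comments and blank lines skipped,
    surrounding whitespace stripped, duplicates collapsed, case preserved."""
    genes: set[str] = set()
    for raw in stream:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        genes.add(line)
    if not genes:
        warnings.warn("gene list is empty", stacklevel=2)
    return genes


def merge_nonredundant(*lists: AbstractSet[str]) -> set[str]:
    """Non-redundant union of two or more gene sets."""
    if len(lists) < 2:
        raise ValueError("need at least two sets to merge")
    merged: set[str] = set()
    for s in lists:
        merged |= s
    return merged


def build_flags(
    universe: AbstractSet[str],
    disease: AbstractSet[str] = frozenset(),
    driver: AbstractSet[str] = frozenset(),
    duplicate: AbstractSet[str] = frozenset(),
    singleton: AbstractSet[str] = frozenset(),
) -> pd.DataFrame:
    """Boolean flag table over ``universe``, one row per gene.

    A gene present in both the duplicate and singleton lists is contradictory
    input and raises. A gene in neither has unknown duplicability (both flags
    False).
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    clash = sorted(duplicate & singleton)
    if clash:
        raise ValueError(
            f"{len(clash)} gene(s) listed as both duplicate and singleton: {clash[:10]}"
        )
    genes = sorted(universe)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "is_disease": [g in disease for g in genes],
            "is_cancer_driver": [g in driver for g in genes],
            "is_duplicate": [g in duplicate for g in genes],
            "is_singleton": [g in singleton for g in genes],
        }
    )
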