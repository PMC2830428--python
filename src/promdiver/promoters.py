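"""Promoter architecture from TSS evidence.

A gene's promoters are defined operationally: experimentally observed
transcription start sites (TSS) on the same strand are clustered with a
500-bp proximity rule, and each cluster is one promoter. Genes are then
binned into four classes by promoter count — single promoter (SP),
two promoters (AP=2), three or four (AP=3~4), and five or more (AP>=5).
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import pandas as pd

DEFAULT_GAP = 500

__all__ = [
    "DEFAULT_GAP",
    "PromoterClass",
    "TSSRecord",
    "PromoterProfile",
    "parse_tss_table",
    "cluster_tss",
    "promoter_profile",
    "assign_class",
    "TSSFormatError",
]


class TSSFormatError(ValueError):
    """Raised for malformed TSS BED input; message carries the line number."""


class PromoterClass(str, enum.Enum):
    """Four-way promoter-count binning."""

    SP = "SP"
    AP2 = "AP2"
    AP3_4 = "AP3_4"
    AP5PLUS = "AP5plus"


@dataclass(frozen=True, slots=True)
class TSSRecord:
    """One observed transcription start (0-based coordinate, BED convention)."""

    chrom: str
    pos: int
    strand: str
    gene_id: str
    support: int = 1

    def __post_init__(self) -> None:
        if self.pos < 0:
            raise ValueError(f"TSS position must be >= 0, got {self.pos}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.gene_id:
            raise ValueError("gene_id must be non-empty")
        if self.support < 0:
            raise ValueError("support must be non-negative")


@dataclass(frozen=True, slots=True)
class PromoterProfile:
    """Per-gene promoter count and the class it maps to."""

    gene_id: str
    n_promoters: int
    promoter_class: PromoterClass = field(compare=False)


def parse_tss_table(stream: Iterable[str]) -> list[TSSRecord]:
    """Read TSS evidence from BED6 text with 1-bp intervals.

    Columns: chrom, start, end, name (= gene id), score (= clone support),
    strand. Lines starting with ``#`` and blank lines are skipped. The
    interval must be exactly one base wide (a single TSS position); wider
    intervals are a format error.
    """
    records: list[TSSRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise TSSFormatError(
                f"line {lineno}: expected >=6 tab-separated BED fields, got {len(fields)}"
            )
        chrom, start_s, end_s, name, score_s, strand = fields[:6]
        try:
            start, end = int(start_s), int(end_s)
        except ValueError as exc:
            raise TSSFormatError(f"line {lineno}: non-integer coordinates") from exc
        if end - start != 1:
            raise TSSFormatError(
                f"line {lineno}: TSS interval must be 1 bp wide, got {end - start}"
            )
        support = 1 if score_s in (".", "") else int(float(score_s))
        try:
            records.append(
                TSSRecord(chrom=chrom, pos=start, strand=strand, gene_id=name, support=support)
            )
        except ValueError as exc:
            raise TSSFormatError(f"line {lineno}: {exc}") from exc
    return records


def cluster_tss(
    positions: Sequence[int], gap: int = DEFAULT_GAP, mode: str = "linkage"
) -> list[list[int]]:
    """Cluster genomic positions with a ``gap``-bp proximity rule.

    ``linkage`` (default): single-linkage chaining on sorted positions — two
    adjacent positions join the same cluster iff their distance is <= gap, so
    a run of 500-bp steps chains into one cluster. ``window``: a fixed window
    anchored at each cluster's first position; a position opens a new cluster
    when it lies more than ``gap`` from that anchor.

    Returns clusters in ascending coordinate order; every input position
    appears in exactly one cluster.
    """
    if len(positions) == 0:
        raise ValueError("cannot cluster an empty set of TSS positions")
    if gap <= 0:
        raise ValueError("gap must be positive")
    if mode not in ("linkage", "window"):
        raise ValueError(f"unknown cluster mode {mode!r}")
    pos = sorted(positions)
    clusters: list[list[int]] = [[pos[0]]]
    for p in pos[1:]:
        anchor = clusters[-1][-1] if mode == "linkage" else clusters[-1][0]
        if p - anchor <= gap:
            clusters[-1].append(p)
        else:
            clusters.append([p])
    return clusters


def assign_class(n_promoters: int) -> PromoterClass:
    """Map a promoter count to its class: 1 -> SP, 2 -> AP2, 3-4 -> AP3_4, >=5 -> AP5plus."""
    if n_promoters < 1:
        raise ValueError(f"n_promoters must be >= 1, got {n_promoters}")
    if n_promoters == 1:
        return PromoterClass.SP
    if n_promoters == 2:
        return PromoterClass.AP2
    if n_promoters <= 4:
        return PromoterClass.AP3_4
    return PromoterClass.AP5PLUS


def _iter_groups(
    records: Iterable[TSSRecord],
) -> Iterator[tuple[str, tuple[str, str], list[int]]]:
    by_gene: dict[str, dict[tuple[str, str], dict[int, int]]] = {}
    for r in records:
        key = (r.chrom, r.strand)
        posmap = by_gene.setdefault(r.gene_id, {}).setdefault(key, {})
        # duplicate positions collapse; clone support sums
        posmap[r.pos] = posmap.get(r.pos, 0) + r.support
    for gene_id in sorted(by_gene):
        for key in sorted(by_gene[gene_id]):
            yield gene_id, key, sorted(by_gene[gene_id][key])


def promoter_profile(
    records: Iterable[TSSRecord], gap: int = DEFAULT_GAP, mode: str = "linkage"
) -> pd.DataFrame:
    """Derive each gene's promoter count and class from its TSS evidence.

    TSSs are grouped by (gene, chromosome, strand) and clustered within each
    group; a gene with evidence on both strands or on two chromosomes keeps
    the groups separate (opposite-strand TSSs cannot share one promoter's
    directional architecture), sums the cluster counts and triggers a warning.
    The result is invariant to the ordering of the input records.

    Returns a DataFrame with columns ``gene_id``, ``n_promoters``,
    ``promoter_class`` sorted by gene id.
    """
    records = list(records)
    if not records:
        raise ValueError("no TSS records given")
    counts: dict[str, int] = {}
    groups_per_gene: dict[str, int] = {}
    for gene_id, _key, positions in _iter_groups(records):
        clusters = cluster_tss(positions, gap=gap, mode=mode)
        counts[gene_id] = counts.get(gene_id, 0) + len(clusters)
        groups_per_gene[gene_id] = groups_per_gene.get(gene_id, 0) + 1
    split = [g for g, k in groups_per_gene.items() if k > 1]
    if split:
        warnings.warn(
            f"{len(split)} gene(s) have TSS evidence on multiple strands/chromosomes; "
            f"cluster counts were summed per gene (e.g. {split[:5]})",
            stacklevel=2,
        )
    return pd.DataFrame(
        {
            "gene_id": list(counts),
            "n_promoters": list(counts.values()),
            "promoter_class": [assign_class(n).value for n in counts.values()],
        }
    )
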