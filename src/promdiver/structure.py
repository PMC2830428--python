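"""Gene-structure length metrics from BED12 gene models.

For each gene one representative transcript (by default the one with the
longest spliced length) is reduced to eight metrics: genomic span, CDS
length, 5' and 3' UTR lengths, total exon and total intron length, and the
exon/intron counts. UTR lengths are genomic coordinate differences between
the transcription boundary and the coding boundary on the appropriate side
of the strand; a spliced-UTR alternative is available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "TranscriptModel",
    "StructureMetrics",
    "BEDFormatError",
    "parse_gene_models",
    "select_representative",
    "structure_metrics",
    "gene_structure_table",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "genomic_len",
    "cds_len",
    "utr5_len",
    "utr3_len",
    "exon_total_len",
    "intron_total_len",
    "n_exon",
    "n_intron",
]


class BEDFormatError(ValueError):
    pass


@dataclass(frozen=True, slots=True)
class TranscriptModel:
    """One transcript: span, coding span and exon blocks (0-based half-open)."""

    tx_id: str
    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if not self.tx_start < self.tx_end:
            raise ValueError("transcript span must be non-empty")
        if not (self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end):
            raise ValueError("CDS interval must lie within the transcript span")
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError("empty exon")
            if prev_end is not None and s < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = e
        if self.exons[0][0] != self.tx_start or self.exons[-1][1] != self.tx_end:
            raise ValueError("exons must cover the transcript span ends")

    @property
    def is_coding(self) -> bool:
        return self.cds_start < self.cds_end

    @property
    def spliced_len(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def genomic_len(self) -> int:
        return self.tx_end - self.tx_start


def parse_gene_models(
    stream: Iterable[str],
    gene_map: Mapping[str, str] | None = None,
    name_sep: str = "|",
) -> dict[str, list[TranscriptModel]]:
    """Parse BED12 into transcripts grouped by gene.

    The BED name field supplies transcript identity. Gene identity comes from
    ``gene_map`` (transcript id -> gene id) when given; otherwise a name of
    the form ``gene|transcript`` is split on ``name_sep``; otherwise the name
    itself is the gene id.
    """
    genes: dict[str, list[TranscriptModel]] = {}
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise BEDFormatError(f"line {lineno}: expected 12 BED fields, got {len(fields)}")
        try:
            chrom = fields[0]
            start, end = int(fields[1]), int(fields[2])
            name = fields[3]
            strand = fields[5]
            thick_start, thick_end = int(fields[6]), int(fields[7])
            n_blocks = int(fields[9])
            sizes = [int(x) for x in fields[10].rstrip(",").split(",")]
            starts = [int(x) for x in fields[11].rstrip(",").split(",")]
        except ValueError as exc:
            raise BEDFormatError(f"line {lineno}: {exc}") from exc
        if len(sizes) != n_blocks or len(starts) != n_blocks:
            raise BEDFormatError(
                f"line {lineno}: blockCount {n_blocks} inconsistent with "
                f"{len(sizes)} sizes / {len(starts)} starts"
            )
        exons = tuple((start + off, start + off + size) for off, size in zip(starts, sizes))
        if exons[0][0] != start or exons[-1][1] != end:
            raise BEDFormatError(f"line {lineno}: blocks do not cover chromStart/chromEnd")
        if gene_map is not None:
            gene_id = gene_map.get(name, name)
            tx_id = name
        elif name_sep in name:
            gene_id, tx_id = name.split(name_sep, 1)
        else:
            gene_id = tx_id = name
        try:
            model = TranscriptModel(
                tx_id=tx_id,
                gene_id=gene_id,
                chrom=chrom,
                strand=strand,
                tx_start=start,
                tx_end=end,
                cds_start=thick_start,
                cds_end=thick_end,
                exons=exons,
            )
        except ValueError as exc:
            raise BEDFormatError(f"line {lineno}: {exc}") from exc
        genes.setdefault(gene_id, []).append(model)
    return genes


def select_representative(
    transcripts: Sequence[TranscriptModel], criterion: str = "spliced"
) -> TranscriptModel:
    """Pick one transcript per gene: the longest one.

    ``spliced`` (default) ranks by mature-transcript length (sum of exon
    lengths); ``span`` by genomic span. Ties fall back to the larger genomic
    span and then the lexicographically smallest transcript id, which makes
    the selection deterministic.
    """
    if not transcripts:
        raise ValueError("no transcripts")
    if criterion == "spliced":
        key = lambda t: (-t.spliced_len, -t.genomic_len, t.tx_id)
    elif criterion == "span":
        key = lambda t: (-t.genomic_len, -t.spliced_len, t.tx_id)
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    return min(transcripts, key=key)


@dataclass(frozen=True, slots=True)
class StructureMetrics:
    gene_id: str
    genomic_len: int
    exon_total_len: int
    intron_total_len: int
    n_exon: int
    n_intron: int
    cds_len: int | None
    utr5_len: int | None
    utr3_len: int | None


def _spliced_overlap(exons: Sequence[tuple[int, int]], lo: int, hi: int) -> int:
    return sum(max(0, min(e, hi) - max(s, lo)) for s, e in exons)


def structure_metrics(t: TranscriptModel, utr_mode: str = "genomic") -> StructureMetrics:
    """The eight length/count metrics of one transcript.

    CDS and UTR fields are None for non-coding transcripts. With
    ``utr_mode="genomic"`` the UTR lengths are coordinate differences between
    the transcription boundary and the coding boundary (5' upstream of the
    CDS, 3' downstream, with the sides swapped on the minus strand);
    ``"spliced"`` counts only exonic bases in those regions. CDS length is
    always the spliced length of exonic bases within the coding span.
    """
    if utr_mode not in ("genomic", "spliced"):
        raise ValueError(f"unknown utr_mode {utr_mode!r}")
    genomic = t.genomic_len
    exon_total = t.spliced_len
    n_exon = len(t.exons)
    cds_len = utr5 = utr3 = None
    if t.is_coding:
        cds_len = _spliced_overlap(t.exons, t.cds_start, t.cds_end)
        if utr_mode == "genomic":
            upstream = t.cds_start - t.tx_start
            downstream = t.tx_end - t.cds_end
        else:
            upstream = _spliced_overlap(t.exons, t.tx_start, t.cds_start)
            downstream = _spliced_overlap(t.exons, t.cds_end, t.tx_end)
        utr5, utr3 = (upstream, downstream) if t.strand == "+" else (downstream, upstream)
    return StructureMetrics(
        gene_id=t.gene_id,
        genomic_len=genomic,
        exon_total_len=exon_total,
        intron_total_len=genomic - exon_total,
        n_exon=n_exon,
        n_intron=n_exon - 1,
        cds_len=cds_len,
        utr5_len=utr5,
        utr3_len=utr3,
    )


def gene_structure_table(
    genes: Mapping[str, Sequence[TranscriptModel]],
    criterion: str = "spliced",
    utr_mode: str = "genomic",
) -> pd.DataFrame:
    """Representative-transcript metrics for every gene, one row per gene."""
    rows = []
    for gene_id in sorted(genes):
        m = structure_metrics(
            select_representative(genes[gene_id], criterion=criterion), utr_mode=utr_mode
        )
        rows.append(
            {
                "gene_id": gene_id,
                "genomic_len": m.genomic_len,
                "cds_len": m.cds_len,
                "utr5_len": m.utr5_len,
                "utr3_len": m.utr3_len,
                "exon_total_len": m.exon_total_len,
                "intron_total_len": m.intron_total_len,
                "n_exon": m.n_exon,
                "n_intron": m.n_intron,
            }
        )
    return pd.DataFrame(rows, columns=["gene_id", *METRIC_COLUMNS])
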