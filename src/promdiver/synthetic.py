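"""Seeded synthetic cohort with planted promoter-class effects.

Generates the five input kinds the pipeline consumes — TSS evidence (BED6),
a tri-state DE-call matrix (TSV), gene models (BED12), annotation gene lists
and a protein-interaction edge list — for a cohort whose per-class effect
sizes default to the published genome-wide values: class sizes
7,291 / 3,772 / 2,941 / 1,176 (SP / AP=2 / AP=3~4 / AP>=5), DER medians
0.50 / 0.52 / 0.54 / 0.56, cancer-driver fractions 2.9–9.7%, disease
fractions 16.4–26.6%, duplicate fractions 67–85%, and interaction-degree
means 6.5 / 8.0 / 9.0 / 10.5 (the two interior degree means interpolate
between the two published endpoints).

Construction guarantees: TSS clusters of one gene are separated by more than
the clustering gap and chained within it, so the promoter-profiling stage
recovers every gene's intended class exactly; the same seed yields a
byte-identical bundle; per-file random streams are independent, so adding a
file type never perturbs the others.
"""

from __future__ import annotations

import dataclasses
import functools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import brentq
from scipy.stats import beta as beta_dist

__all__ = [
    "SyntheticConfig",
    "CohortPaths",
    "default_config",
    "generate_cohort",
    "draw_der_values",
    "beta_params_for_median",
    "CLASS_NAMES",
]

CLASS_NAMES = ("SP", "AP2", "AP3_4", "AP5plus")

# fixed substream labels: adding a stream never shifts the others
_STREAMS = {"genes": 0, "tss": 1, "de": 2, "models": 3, "lists": 4, "network": 5}

# per-class structural medians (bases / counts) used for the lognormal laws:
# exon count, total exon length, 5' UTR, 3' UTR
_NEXON_MEDIANS = (6, 9, 12, 17)
_EXON_TOTAL_MEDIANS = (2158, 2808, 3492, 4178)
_UTR5_MEDIANS = (139, 172, 188, 207)
_UTR3_MEDIANS = (599, 881, 1178, 1325)


@dataclass
class SyntheticConfig:
    """All knobs of the generator; defaults are the published effect sizes."""

    seed: int = 17
    class_sizes: tuple[int, int, int, int] = (7291, 3772, 2941, 1176)
    n_datasets: int = 476
    der_medians: tuple[float, ...] = (0.50, 0.52, 0.54, 0.56)
    der_concentration: float = 20.0
    disease_fracs: tuple[float, ...] = (0.164, 0.199, 0.217, 0.266)
    driver_fracs: tuple[float, ...] = (0.029, 0.043, 0.062, 0.097)
    duplicate_fracs: tuple[float, ...] = (0.67, 0.74, 0.78, 0.85)
    known_duplicability_prob: float = 0.97
    degree_means: tuple[float, ...] = (6.5, 8.0, 9.0, 10.5)
    degree_dispersion: float = 1.0
    # lognormal scale (= median, bases) of per-class total intron length
    length_scale_factors: tuple[float, ...] = (14370.0, 25162.0, 43650.0, 87204.0)
    length_sigma: float = 1.0
    measured_prob: float = 0.6
    cluster_gap: int = 500
    second_transcript_prob: float = 0.1

    def __post_init__(self) -> None:
        if any(n < 1 for n in self.class_sizes):
            raise ValueError("class sizes must be >= 1")
        for name in ("der_medians", "disease_fracs", "driver_fracs", "duplicate_fracs"):
            if any(not 0 <= p <= 1 for p in getattr(self, name)):
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.measured_prob <= 1:
            raise ValueError("measured_prob must lie in [0, 1]")

    @property
    def n_genes(self) -> int:
        return sum(self.class_sizes)


def default_config(seed: int = 17) -> SyntheticConfig:
    return SyntheticConfig(seed=seed)


@dataclass(frozen=True)
class CohortPaths:
    tss: Path
    de_matrix: Path
    gene_models: Path
    disease: Path
    driver: Path
    duplicate: Path
    singleton: Path
    edges: Path
    manifest: Path


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=config.seed, spawn_key=(_STREAMS[stream],))
    )


@functools.lru_cache(maxsize=256)
def beta_params_for_median(m: float, concentration: float) -> tuple[float, float]:
    """Beta(a, b) with a + b = concentration and median m, by root-finding
    on the Beta quantile (the median has no closed form)."""
    if not 0 < m < 1:
        raise ValueError("median must be in (0, 1)")

    def f(a: float) -> float:
        return beta_dist.ppf(0.5, a, concentration - a) - m

    eps = 1e-6 * concentration
    a = brentq(f, eps, concentration - eps)
    return a, concentration - a


def _class_index(config: SyntheticConfig) -> np.ndarray:
    """Class label index per gene: contiguous blocks, SP first."""
    return np.repeat(np.arange(4), config.class_sizes)


def _gene_ids(config: SyntheticConfig) -> list[str]:
    return [f"G{i:05d}" for i in range(config.n_genes)]


def _promoter_counts(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    cls = _class_index(config)
    counts = np.ones(config.n_genes, dtype=int)
    counts[cls == 1] = 2
    counts[cls == 2] = rng.integers(3, 5, size=(cls == 2).sum())
    counts[cls == 3] = rng.integers(5, 9, size=(cls == 3).sum())
    return counts


def _write_tss(
    path: Path,
    config: SyntheticConfig,
    gene_ids: list[str],
    chroms: list[str],
    strands: list[str],
    promoter_counts: np.ndarray,
) -> None:
    rng = _rng(config, "tss")
    gap = config.cluster_gap
    cursors: dict[str, int] = {}
    lines = []
    for gid, chrom, strand, k in zip(gene_ids, chroms, strands, promoter_counts):
        pos = cursors.get(chrom, 10_000)
        for _ in range(int(k)):
            m = int(rng.integers(1, 4))  # 1-3 TSSs per promoter
            for _ in range(m):
                support = int(rng.integers(1, 100))
                lines.append(f"{chrom}\t{pos}\t{pos + 1}\t{gid}\t{support}\t{strand}\n")
                pos += int(rng.integers(1, gap // 3))  # chain step, well under gap
            pos += gap + 1 + int(rng.integers(0, 1500))  # break: next cluster > gap away
        cursors[chrom] = pos + 10_000
    with open(path, "w") as fh:
        fh.write("# synthetic TSS evidence (BED6, 1-bp intervals)\n")
        fh.writelines(lines)


def _write_de_matrix(path: Path, config: SyntheticConfig, gene_ids: list[str]) -> None:
    rng = _rng(config, "de")
    cls = _class_index(config)
    rates = np.empty(config.n_genes)
    for i in range(4):
        a, b = beta_params_for_median(config.der_medians[i], config.der_concentration)
        rates[cls == i] = rng.beta(a, b, size=(cls == i).sum())
    measured = rng.random((config.n_genes, config.n_datasets)) < config.measured_prob
    de = rng.random((config.n_genes, config.n_datasets)) < rates[:, None]
    cells = np.where(measured, np.where(de, "1", "0"), "NA")
    header = "gene_id\t" + "\t".join(f"D{j:03d}" for j in range(config.n_datasets))
    with open(path, "w") as fh:
        fh.write(header + "\n")
        for gid, row in zip(gene_ids, cells):
            fh.write(gid + "\t" + "\t".join(row) + "\n")


def _write_gene_models(
    path: Path,
    config: SyntheticConfig,
    gene_ids: list[str],
    chroms: list[str],
    strands: list[str],
) -> None:
    rng = _rng(config, "models")
    cls = _class_index(config)
    sig = config.length_sigma
    cursors: dict[str, int] = {}
    with open(path, "w") as fh:
        for gi, (gid, chrom, strand) in enumerate(zip(gene_ids, chroms, strands)):
            c = cls[gi]
            n_exon = max(1, int(round(rng.lognormal(np.log(_NEXON_MEDIANS[c]), 0.4))))
            exon_total = max(
                n_exon, int(round(rng.lognormal(np.log(_EXON_TOTAL_MEDIANS[c]), 0.6)))
            )
            if n_exon > 1:
                intron_total = max(
                    n_exon - 1,
                    int(round(rng.lognormal(np.log(config.length_scale_factors[c]), sig))),
                )
                intron_parts = _partition(rng, intron_total, n_exon - 1)
            else:
                intron_parts = []
            exon_parts = _partition(rng, exon_total, n_exon)
            start = cursors.get(chrom, 1_000_000)
            block_starts, off = [], 0
            for j, size in enumerate(exon_parts):
                block_starts.append(off)
                off += size
                if j < len(intron_parts):
                    off += intron_parts[j]
            end = start + off
            genomic_len = end - start
            u5 = int(round(rng.lognormal(np.log(_UTR5_MEDIANS[c]), 0.8)))
            u3 = int(round(rng.lognormal(np.log(_UTR3_MEDIANS[c]), 0.8)))
            if u5 + u3 >= genomic_len:
                u5 = genomic_len // 4
                u3 = genomic_len // 4
            if strand == "+":
                thick_start, thick_end = start + u5, end - u3
            else:
                thick_start, thick_end = start + u3, end - u5
            fh.write(
                _bed12_line(chrom, start, end, f"{gid}|{gid}.t1", strand,
                            thick_start, thick_end, exon_parts, block_starts)
            )
            # an occasional shorter second isoform exercises representative selection
            if n_exon > 1 and rng.random() < config.second_transcript_prob:
                short_exons = exon_parts[:-1]
                short_starts = block_starts[: len(short_exons)]
                short_end = start + short_starts[-1] + short_exons[-1]
                ts, te = min(thick_start, short_end), min(thick_end, short_end)
                fh.write(
                    _bed12_line(chrom, start, short_end, f"{gid}|{gid}.t2", strand,
                                ts, te, short_exons, short_starts)
                )
            cursors[chrom] = end + 50_000
    return None


def _partition(rng: np.random.Generator, total: int, parts: int) -> list[int]:
    """Split ``total`` into ``parts`` positive integers, Dirichlet-weighted."""
    if parts == 1:
        return [total]
    w = rng.dirichlet(np.ones(parts))
    sizes = np.maximum(1, np.floor(w * (total - parts)).astype(int) + 1)
    sizes[-1] += total - sizes.sum()
    if sizes[-1] < 1:  # pathological rounding; rebalance from the largest part
        deficit = 1 - sizes[-1]
        sizes[np.argmax(sizes[:-1])] -= deficit
        sizes[-1] = 1
    return sizes.tolist()


def _bed12_line(chrom, start, end, name, strand, thick_start, thick_end,
                sizes, offsets) -> str:
    return (
        f"{chrom}\t{start}\t{end}\t{name}\t0\t{strand}\t{thick_start}\t{thick_end}\t0\t"
        f"{len(sizes)}\t{','.join(map(str, sizes))},\t{','.join(map(str, offsets))},\n"
    )


def _write_lists(
    outdir: Path, config: SyntheticConfig, gene_ids: list[str]
) -> tuple[Path, Path, Path, Path]:
    rng = _rng(config, "lists")
    cls = _class_index(config)
    n = config.n_genes
    disease = rng.random(n) < np.asarray(config.disease_fracs)[cls]
    driver = rng.random(n) < np.asarray(config.driver_fracs)[cls]
    known = rng.random(n) < config.known_duplicability_prob
    dup = rng.random(n) < np.asarray(config.duplicate_fracs)[cls]
    paths = (
        outdir / "disease_genes.txt",
        outdir / "cancer_driver_genes.txt",
        outdir / "duplicate_genes.txt",
        outdir / "singleton_genes.txt",
    )
    masks = (disease, driver, known & dup, known & ~dup)
    ids = np.asarray(gene_ids)
    for path, mask in zip(paths, masks):
        with open(path, "w") as fh:
            fh.write("# synthetic gene list\n")
            fh.writelines(f"{g}\n" for g in ids[mask])
    return paths


def _write_edges(path: Path, config: SyntheticConfig, gene_ids: list[str]) -> bool:
    """Configuration-model edge list with class-specific negative-binomial
    degrees. Returns True if one stub was added to repair an odd degree sum."""
    rng = _rng(config, "network")
    cls = _class_index(config)
    r = config.degree_dispersion
    means = np.asarray(config.degree_means)[cls]
    p = r / (r + means)
    degrees = rng.negative_binomial(r, p)
    repaired = False
    if degrees.sum() % 2 == 1:
        degrees[int(np.argmax(degrees > 0))] += 1
        repaired = True
    stubs = np.repeat(np.arange(config.n_genes), degrees)
    stubs = rng.permutation(stubs)
    ids = np.asarray(gene_ids)
    with open(path, "w") as fh:
        fh.write("# synthetic protein-interaction edge list\n")
        for i in range(0, len(stubs) - 1, 2):
            fh.write(f"{ids[stubs[i]]}\t{ids[stubs[i + 1]]}\n")
    return repaired


def generate_cohort(config: SyntheticConfig, outdir: str | Path) -> CohortPaths:
    """Write the full input bundle plus a JSON manifest of the true
    parameters into ``outdir``. Deterministic: same config, same bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gene_ids = _gene_ids(config)
    rng = _rng(config, "genes")
    chrom_pool = [f"chr{i}" for i in range(1, 23)]
    chroms = [chrom_pool[i % 22] for i in range(config.n_genes)]
    strands = ["+" if s else "-" for s in rng.random(config.n_genes) < 0.5]
    promoter_counts = _promoter_counts(config, rng)

    paths = CohortPaths(
        tss=outdir / "tss.bed",
        de_matrix=outdir / "de_matrix.tsv",
        gene_models=outdir / "gene_models.bed",
        disease=outdir / "disease_genes.txt",
        driver=outdir / "cancer_driver_genes.txt",
        duplicate=outdir / "duplicate_genes.txt",
        singleton=outdir / "singleton_genes.txt",
        edges=outdir / "ppi_edges.tsv",
        manifest=outdir / "manifest.json",
    )
    _write_tss(paths.tss, config, gene_ids, chroms, strands, promoter_counts)
    _write_de_matrix(paths.de_matrix, config, gene_ids)
    _write_gene_models(paths.gene_models, config, gene_ids, chroms, strands)
    _write_lists(outdir, config, gene_ids)
    repaired = _write_edges(paths.edges, config, gene_ids)

    offsets = np.concatenate([[0], np.cumsum(config.class_sizes)])
    manifest = {
        "config": dataclasses.asdict(config),
        "class_names": list(CLASS_NAMES),
        "gene_id_blocks": {
            CLASS_NAMES[i]: [f"G{offsets[i]:05d}", f"G{offsets[i + 1] - 1:05d}"]
            for i in range(4)
        },
        "degree_sum_repaired": repaired,
        "files": {k: getattr(paths, k).name for k in
                  ("tss", "de_matrix", "gene_models", "disease", "driver",
                   "duplicate", "singleton", "edges")},
    }
    with open(paths.manifest, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")
    return paths


def draw_der_values(
    rng: np.random.Generator,
    class_sizes: tuple[int, ...],
    der_medians: tuple[float, ...],
    concentration: float = 20.0,
    n_datasets: int = 476,
    measured_prob: float = 0.6,
) -> list[np.ndarray]:
    """Per-class DER samples under the cohort's generative law, without
    materializing a call matrix (used for fast replicated calibration)."""
    out = []
    for size, m in zip(class_sizes, der_medians):
        a, b = beta_params_for_median(m, concentration)
        rates = rng.beta(a, b, size=size)
        n_measured = np.maximum(1, rng.binomial(n_datasets, measured_prob, size=size))
        n_de = rng.binomial(n_measured, rates)
        out.append(n_de / n_measured)
    return out
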