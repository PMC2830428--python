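"""End-to-end orchestration: inputs -> promoter classes -> stratified report.

The pipeline profiles promoters from TSS evidence, then runs each downstream
analysis whose input is present — differential-expression ratio, the eight
gene-structure metrics, disease / cancer-driver / duplicability enrichment,
and interaction-network degree — each as the fixed four-rung promoter-class
comparison ladder. Analyses lacking their input are skipped and marked. The
report is a plain JSON-serializable structure with a provenance block, and
every filtering step is logged with before/after counts so cohort
bookkeeping stays auditable.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .annotations import build_flags, parse_gene_list
from .expression import compute_der, filter_measured, parse_de_matrix
from .network import clean_network, degree_table, parse_edges
from .promoters import parse_tss_table, promoter_profile
from .stats import LadderResult, class_ladder
from .structure import METRIC_COLUMNS, gene_structure_table, parse_gene_models

__all__ = ["PipelineInputs", "PipelineOptions", "Report", "run", "render_report"]

CLASS_ORDER = ["SP", "AP2", "AP3_4", "AP5plus"]


@dataclass
class PipelineInputs:
    """Paths to the input files; only ``tss`` is mandatory."""

    tss: Path
    de_matrix: Path | None = None
    gene_models: Path | None = None
    disease: Path | None = None
    driver: Path | None = None
    duplicate: Path | None = None
    singleton: Path | None = None
    edges: Path | None = None


@dataclass
class PipelineOptions:
    gap: int = 500
    cluster_mode: str = "linkage"
    measured_min_frac: float = 0.05
    measured_min_count: int | None = None
    alternative: str = "two_sided"
    utr_mode: str = "genomic"
    longest: str = "spliced"
    absent_degree: str = "missing"  # or "zero"
    overlap_floor: float = 0.5


@dataclass
class Report:
    """JSON-serializable analysis report."""

    data: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.data, indent=1, sort_keys=True) + "\n"

    @classmethod
    def from_json(cls, text: str) -> "Report":
        return cls(data=json.loads(text))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _ladder_section(ladder: LadderResult) -> dict:
    return {
        "status": "ok",
        "comparisons": [c.as_row() for c in ladder.comparisons],
        "class_summaries": {
            str(row["class"]): {"n": int(row["n"]), "summary": _jsonable(row["summary"])}
            for _, row in ladder.class_summaries.iterrows()
        },
    }


def _jsonable(v):
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def _check_overlap(name: str, ids: set[str], universe: set[str], floor: float, log: list) -> None:
    if not ids:
        return
    denom = min(len(ids), len(universe))
    frac = len(ids & universe) / denom if denom else 0.0
    log.append(f"{name}: {len(ids)} ids, overlap with profiled genes {frac:.1%}")
    if frac < floor:
        raise ValueError(
            f"{name}: only {frac:.1%} of ids overlap the profiled genes "
            f"(floor {floor:.0%}) — check that all inputs share one gene-id namespace"
        )


def run(inputs: PipelineInputs, options: PipelineOptions | None = None) -> Report:
    """Run every analysis whose input file is present and assemble the report."""
    opts = options or PipelineOptions()
    log: list[str] = []
    data: dict = {}

    with open(inputs.tss) as fh:
        profiles = promoter_profile(
            parse_tss_table(fh), gap=opts.gap, mode=opts.cluster_mode
        )
    universe = set(profiles["gene_id"])
    counts = profiles["promoter_class"].value_counts()
    data["class_counts"] = {cls: int(counts.get(cls, 0)) for cls in CLASS_ORDER}
    data["n_profiled"] = len(profiles)
    log.append(f"promoter profiling: {len(profiles)} genes profiled")

    # --- differential expression ratio -----------------------------------
    if inputs.de_matrix is not None:
        with open(inputs.de_matrix) as fh:
            matrix = parse_de_matrix(fh)
        _check_overlap("de_matrix", set(matrix.gene_ids), universe, opts.overlap_floor, log)
        retained = filter_measured(
            matrix, min_fraction=opts.measured_min_frac, min_count=opts.measured_min_count
        )
        log.append(
            f"measured-fraction filter: {len(matrix.gene_ids)} genes in, "
            f"{len(retained)} retained (>= {opts.measured_min_frac:.0%} of "
            f"{matrix.n_datasets} datasets)"
        )
        der = compute_der(matrix)
        der = der[der["gene_id"].isin(retained & universe)]
        log.append(f"DER scored for {len(der)} profiled genes")
        ladder = class_ladder(
            dict(zip(der["gene_id"], der["der"])), profiles, "rank_sum",
            alternative=opts.alternative,
        )
        section = _ladder_section(ladder)
        section["n_scored"] = int(len(der))
        data["der"] = section
    else:
        data["der"] = {"status": "skipped"}

    # --- gene structure ---------------------------------------------------
    if inputs.gene_models is not None:
        with open(inputs.gene_models) as fh:
            genes = parse_gene_models(fh)
        _check_overlap("gene_models", set(genes), universe, opts.overlap_floor, log)
        table = gene_structure_table(genes, criterion=opts.longest, utr_mode=opts.utr_mode)
        table = table[table["gene_id"].isin(universe)]
        log.append(f"gene structure: {len(table)} profiled genes with models")
        section: dict = {"status": "ok", "metrics": {}}
        for metric in METRIC_COLUMNS:
            ladder = class_ladder(
                dict(zip(table["gene_id"], table[metric])), profiles, "rank_sum",
                alternative=opts.alternative,
            )
            section["metrics"][metric] = _ladder_section(ladder)
        data["structure"] = section
    else:
        data["structure"] = {"status": "skipped"}

    # --- annotation flags -------------------------------------------------
    lists = {}
    for name in ("disease", "driver", "duplicate", "singleton"):
        path = getattr(inputs, name)
        if path is not None:
            with open(path) as fh:
                lists[name] = parse_gene_list(fh)
    if lists:
        flags = build_flags(
            universe,
            disease=lists.get("disease", frozenset()),
            driver=lists.get("driver", frozenset()),
            duplicate=lists.get("duplicate", frozenset()),
            singleton=lists.get("singleton", frozenset()),
        )
    for key, col in (("disease", "is_disease"), ("cancer_driver", "is_cancer_driver")):
        src = "disease" if key == "disease" else "driver"
        if src in lists:
            ladder = class_ladder(
                dict(zip(flags["gene_id"], flags[col].astype(bool))),
                profiles, "fisher", alternative=opts.alternative,
            )
            data[key] = _ladder_section(ladder)
        else:
            data[key] = {"status": "skipped"}
    if "duplicate" in lists or "singleton" in lists:
        # tri-state: unknown duplicability (in neither list) is excluded
        tri = {
            g: (True if d else (False if s else None))
            for g, d, s in zip(
                flags["gene_id"], flags["is_duplicate"], flags["is_singleton"]
            )
        }
        n_known = sum(v is not None for v in tri.values())
        log.append(f"duplicability known for {n_known} of {len(tri)} profiled genes")
        ladder = class_ladder(tri, profiles, "fisher", alternative=opts.alternative)
        section = _ladder_section(ladder)
        section["n_known"] = n_known
        data["duplicability"] = section
    else:
        data["duplicability"] = {"status": "skipped"}

    # --- interaction degree ----------------------------------------------
    if inputs.edges is not None:
        with open(inputs.edges) as fh:
            graph = clean_network(parse_edges(fh))
        _check_overlap("edges", set(graph.nodes), universe, opts.overlap_floor, log)
        degrees = degree_table(graph)
        deg_map: dict[str, float] = dict(
            zip(degrees["id"], degrees["degree"].astype(float))
        )
        if opts.absent_degree == "zero":
            deg_map = {g: float(deg_map.get(g, 0.0)) for g in universe}
        elif opts.absent_degree != "missing":
            raise ValueError(f"unknown absent_degree policy {opts.absent_degree!r}")
        log.append(
            f"network: {graph.number_of_nodes()} proteins, "
            f"{graph.number_of_edges()} interactions after cleaning"
        )
        ladder = class_ladder(deg_map, profiles, "rank_sum", alternative=opts.alternative)
        section = _ladder_section(ladder)
        by_class = profiles.set_index("gene_id")["promoter_class"]
        means = {}
        for cls in CLASS_ORDER:
            vals = [deg_map[g] for g in by_class.index[by_class == cls] if g in deg_map]
            means[cls] = _jsonable(sum(vals) / len(vals)) if vals else None
        section["class_means"] = means
        data["degree"] = section
    else:
        data["degree"] = {"status": "skipped"}

    data["log"] = log
    data["provenance"] = {
        "version": __version__,
        "options": asdict(opts),
        "inputs": {
            name: {"path": str(p), "sha256": _sha256(Path(p))}
            for name, p in asdict(inputs).items()
            if p is not None
        },
    }
    return Report(data=data)


def _ladder_frame(section: dict) -> pd.DataFrame:
    return pd.DataFrame(section["comparisons"])


def render_report(report: Report, outdir: str | Path, format: str = "both") -> list[Path]:
    """Write the report: one TSV per analysis plus the single JSON file.

    P-values below the display floor appear as ``<2.2e-16`` in the TSVs
    (``p_display``) while the stored JSON keeps full precision.
    """
    if format not in ("tsv", "json", "both"):
        raise ValueError(f"unknown format {format!r}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    d = report.data
    if format in ("json", "both"):
        path = outdir / "report.json"
        path.write_text(report.to_json())
        written.append(path)
    if format in ("tsv", "both"):
        counts = pd.DataFrame(
            {"class": CLASS_ORDER, "n": [d["class_counts"][c] for c in CLASS_ORDER]}
        )
        written.append(_write_tsv(counts, outdir / "class_counts.tsv"))
        for key in ("der", "cancer_driver", "disease", "duplicability", "degree"):
            if d.get(key, {}).get("status") == "ok":
                written.append(
                    _write_tsv(_ladder_frame(d[key]), outdir / f"{key}_ladder.tsv")
                )
        if d.get("structure", {}).get("status") == "ok":
            metrics = d["structure"]["metrics"]
            med = pd.DataFrame(
                {
                    cls: [metrics[m]["class_summaries"][cls]["summary"] for m in METRIC_COLUMNS]
                    for cls in CLASS_ORDER
                },
                index=METRIC_COLUMNS,
            )
            med.index.name = "metric"
            written.append(_write_tsv(med.reset_index(), outdir / "table1_medians.tsv"))
            ladders = pd.concat(
                [_ladder_frame(metrics[m]).assign(metric=m) for m in METRIC_COLUMNS],
                ignore_index=True,
            )
            written.append(_write_tsv(ladders, outdir / "structure_ladders.tsv"))
    return written


def _write_tsv(df: pd.DataFrame, path: Path) -> Path:
    df.to_csv(path, sep="\t", index=False)
    return path
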