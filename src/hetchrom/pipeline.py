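"""End-to-end orchestration: regions -> windows -> tabulation -> model
selection -> enrichment, with machine-readable reports.

Every run is driven by a :class:`PipelineConfig` holding either real input
paths or a simulation seed (never both), and writes TSV/JSON artifacts plus
a run log carrying package version, seed and a configuration hash, so any
report is regenerable from the saved intermediates alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .enrichment import enrich, read_annotations, write_enrichment
from .features import (
    FEATURE_CLASSES,
    make_windows,
    read_unified_features,
    records_to_frame,
    summarize_by_class,
    tabulate,
)
from .model import ChromatinCountModel
from .regions import (
    ChromatinRegion,
    read_region_table,
    summarize_chromatin,
    transition_zones,
    write_bed,
    zone_stats_kb,
)
from .simulate import SimulationSpec, gen_chromatin_map, gen_feature_intervals, gen_go_annotations

__all__ = ["PipelineConfig", "run", "report_table2"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one of (``regions_path`` [+ ``features_path``]) or
    ``simulate=True`` must be chosen; a seed is required whenever any
    stochastic stage runs.
    """

    output_dir: str = "hetchrom_out"
    regions_path: str | None = None
    features_path: str | None = None
    annotations_path: str | None = None
    study_genes_path: str | None = None
    simulate: bool = False
    seed: int | None = None
    sim_scale: float = 1.0
    eu_window: int = 5_000_000
    het_window: int = 1_000_000
    genome_size: int = 260_000_000
    total_genes: int = 13_000
    model_space: str = "joint"
    strategy: str = "exhaustive"
    iterations: int = 1_000_000
    alpha: float = 0.05
    features: tuple[str, ...] = FEATURE_CLASSES

    def __post_init__(self) -> None:
        real = self.regions_path is not None
        if real == self.simulate:
            raise ValueError(
                "exactly one of a real region table or simulate=True is required"
            )
        if (self.simulate or self.strategy == "anneal") and self.seed is None:
            raise ValueError("a seed is required for stochastic stages")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        if "features" in payload:
            payload["features"] = tuple(payload["features"])
        return cls(**payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["features"] = list(d["features"])
        return d

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def report_table2(regions: list[ChromatinRegion]) -> pd.DataFrame:
    """Arm-grouped boundary table with a totals row.

    The totals row aggregates the heterochromatic classes (PH, IHc, IHd); on
    the packaged AgamP3 map it reproduces the ~16.6 Mb / 232 gene totals.
    """
    rows = [
        {
            "arm": r.arm,
            "chromatin_type": r.chromatin_class,
            "start": r.start,
            "end": r.end,
            "size_bp": r.size,
            "gene_number": r.gene_count,
            "start_marker": r.start_marker,
            "end_marker": r.end_marker,
        }
        for r in regions
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "arm", "chromatin_type", "start", "end", "size_bp",
            "gene_number", "start_marker", "end_marker",
        ],
    )
    if not df.empty:
        het = df[df["chromatin_type"].isin(["PH", "IHc", "IHd"])]
        genes = het["gene_number"]
        total = {
            "arm": "total",
            "chromatin_type": "heterochromatin",
            "start": None,
            "end": None,
            "size_bp": int(het["size_bp"].sum()),
            "gene_number": None if genes.isna().any() else int(genes.sum()),
            "start_marker": None,
            "end_marker": None,
        }
        df = pd.concat([df, pd.DataFrame([total])], ignore_index=True)
    return df


def run(config: PipelineConfig) -> dict:
    """Execute all stages and write the report bundle.

    Returns a manifest dict (also written to ``run_log.json``) listing the
    artifacts produced and per-stage record counts.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stages": {},
        "warnings": [],
    }

    def stage(name: str):
        logger.info("stage: %s", name)
        return manifest["stages"].setdefault(name, {})

    try:
        # -- regions -------------------------------------------------------
        info = stage("regions")
        if config.simulate:
            spec = SimulationSpec(seed=config.seed, scale=config.sim_scale)
            regions = gen_chromatin_map(spec)
        else:
            regions = read_region_table(config.regions_path)
        info["n_regions"] = len(regions)
        report_table2(regions).to_csv(out / "table2_report.tsv", sep="\t", index=False)
        zones = transition_zones(regions)
        info["n_transition_zones"] = len(zones)
        write_bed(regions, out / "regions.bed")
        write_bed(zones, out / "transition_zones.bed")
        summary = summarize_chromatin(regions, config.genome_size, config.total_genes)
        payload = summary.to_dict()
        payload["transition_zones_kb"] = zone_stats_kb(zones)
        (out / "chromatin_summary.json").write_text(json.dumps(payload, indent=2) + "\n")

        # -- windows & tabulation -----------------------------------------
        info = stage("windows")
        windows = make_windows(regions, config.eu_window, config.het_window)
        info["n_windows"] = len(windows)

        info = stage("tabulate")
        if config.simulate:
            intervals = gen_feature_intervals(regions, spec)
        else:
            intervals = (
                read_unified_features(config.features_path)
                if config.features_path
                else []
            )
        info["n_intervals"] = len(intervals)
        records = tabulate(windows, intervals, config.features)
        info["n_records"] = len(records)
        table = records_to_frame(records)
        table.to_csv(out / "window_features.tsv", sep="\t", index=False)
        summarize_by_class(records).to_csv(
            out / "class_medians.tsv", sep="\t", index=False
        )

        # -- per-feature model selection ----------------------------------
        info = stage("model_selection")
        selection_rows = []
        for feature in config.features:
            model = ChromatinCountModel.from_frame(table, feature=feature)
            sel = model.select_max_model(
                mode=config.model_space,
                strategy=config.strategy,
                seed=config.seed,
                iterations=config.iterations,
            )
            sel.to_json(out / f"model_selection_{feature}.json")
            df = sel.to_frame()
            df.insert(0, "feature", feature)
            selection_rows.append(df)
            info[feature] = sel.best.config.label()
        if selection_rows:
            pd.concat(selection_rows, ignore_index=True).to_csv(
                out / "model_selection.tsv", sep="\t", index=False
            )

        # -- enrichment ----------------------------------------------------
        info = stage("enrichment")
        if config.simulate:
            ann, study, planted = gen_go_annotations(spec)
            ns: dict[str, str] = {}
            info["planted_terms"] = planted
        elif config.annotations_path and config.study_genes_path:
            ann, ns = read_annotations(config.annotations_path)
            study = [
                line.strip()
                for line in Path(config.study_genes_path).read_text().splitlines()
                if line.strip()
            ]
        else:
            ann, study, ns = {}, [], {}
        if study:
            result = enrich(study, ann, alpha=config.alpha, namespaces=ns or None)
            write_enrichment(result, out / "enrichment.tsv")
            info["n_terms_tested"] = len(result)
            info["n_significant"] = int(result["significant"].sum())
        else:
            info["skipped"] = True
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage {list(manifest['stages'])[-1]!r} failed: {exc}"
        ) from exc

    (out / "run_log.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
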