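"""Orchestration of the four published comparative analyses.

Each run assembles a composition matrix (from the packaged tables, a
synthetic cohort, or a user CSV of animal records), applies the selected
transformation path, runs the correspondence analysis and writes a report
bundle: coordinates, axis inertias, contributions, percent profiles, the
ratio table when applicable, and a run-metadata JSON from which the whole
run can be regenerated.

Analyses
--------
``all_species``
    Principal-cell composition across every group with count data.
``rodents``
    The same restricted to rodent groups.
``rodents_with_neurogenesis``
    Rodent groups with Ki67/DCX counts age-normalized to the reference age
    appended as two extra columns.
``ratios``
    Correspondence analysis of the convergence/divergence ratio table
    (ratios need no further transformation).
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .age_normalization import DeclineModel
from .connectivity_ratios import RATIO_COLUMNS, classify_table
from .correspondence import CAResult, correspondence_analysis, offset_shift
from .datasets import POPULATIONS
from .synthetic_data import CohortSpec, animals_to_frame, generate_animals
from .transform import CompositionMatrix, percent_matrix, scale_matrix

log = logging.getLogger(__name__)

ANALYSES = ("all_species", "rodents", "rodents_with_neurogenesis", "ratios")
TRANSFORMATIONS = ("log_scale_shift", "raw_counts", "percent")
Y_SOURCES = ("literature", "study")


@dataclass
class AnalysisConfig:
    """Everything needed to reproduce one analysis run."""

    analysis: str
    source: str = "fixtures"  # fixtures | synthetic | <path to animal CSV>
    transformation: str = "log_scale_shift"
    y_source: str = "literature"
    reference_age_months: float = 3.0
    groups: Optional[tuple[str, ...]] = None
    exclude_groups: tuple[str, ...] = ()
    seed: int = 0
    shift_epsilon: float = 0.0
    out_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.analysis not in ANALYSES:
            raise ValueError(f"analysis must be one of {ANALYSES}")
        if self.transformation not in TRANSFORMATIONS:
            raise ValueError(f"transformation must be one of {TRANSFORMATIONS}")
        if self.y_source not in Y_SOURCES:
            raise ValueError(f"y_source must be one of {Y_SOURCES}")
        if self.groups is not None:
            self.groups = tuple(self.groups)
        self.exclude_groups = tuple(self.exclude_groups)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text())
        return cls(**raw)


@dataclass
class RunResult:
    """In-memory report bundle of one analysis run."""

    config: AnalysisConfig
    ca: CAResult
    matrix: CompositionMatrix
    ratios: Optional[pd.DataFrame] = None
    profiles: Optional[pd.DataFrame] = None
    row_mode: str = "group_means"
    paths: dict[str, Path] = field(default_factory=dict)


def _resolve_groups(config: AnalysisConfig) -> list[str]:
    base = {
        "all_species": datasets.all_groups(),
        "rodents": datasets.rodent_groups(),
        "rodents_with_neurogenesis": datasets.neurogenesis_groups(),
        "ratios": datasets.all_groups(),
    }[config.analysis]
    requested = list(config.groups) if config.groups is not None else list(base)
    unknown = [g for g in requested if g not in datasets.all_groups()]
    unknown += [g for g in config.exclude_groups if g not in datasets.all_groups()]
    if unknown:
        raise ValueError(f"unknown group ids: {sorted(set(unknown))}")
    groups = [g for g in requested if g in base and g not in config.exclude_groups]

    if config.analysis != "ratios" and config.source in ("fixtures", "synthetic"):
        available = set(datasets.printed_groups())
        missing = [g for g in groups if g not in available]
        if missing:
            if config.groups is not None:
                raise ValueError(
                    "per-population data unavailable (literature-sourced) for: "
                    + ", ".join(missing)
                )
            log.info("restricting to groups with printed counts; dropping %s", missing)
            groups = [g for g in groups if g in available]
    return groups


def _neurogenesis_columns_fixture(groups: Sequence[str], config: AnalysisConfig) -> pd.DataFrame:
    """Ki67/DCX group means extrapolated to the reference age."""
    t3 = datasets.load_fixture("table3")
    ages = datasets.group_mean_ages()
    cols = {}
    for marker in ("Ki67", "DCX"):
        model = (
            DeclineModel.literature(marker, config.reference_age_months)
            if config.y_source == "literature"
            else DeclineModel.study_refit(marker, config.reference_age_months)
        )
        sub = t3[t3["marker"] == marker].set_index("group_id")
        values = []
        for g in groups:
            raw = float(sub.loc[g, "mean_count"])
            age = ages[g]
            factor = float(np.exp((np.log(model.reference_age_months) - np.log(age)) * model.exponent))
            values.append(raw * factor)
        cols[marker] = values
    return pd.DataFrame(cols, index=list(groups))


def _assemble_counts(config: AnalysisConfig, groups: Sequence[str]) -> tuple[pd.DataFrame, str]:
    """Rows × columns count table plus the row mode used."""
    with_markers = config.analysis == "rodents_with_neurogenesis"
    if config.source == "fixtures":
        counts = datasets.count_matrix(groups)
        if with_markers:
            counts = counts.join(_neurogenesis_columns_fixture(groups, config))
        return counts, "group_means"

    if config.source == "synthetic":
        spec = CohortSpec.from_fixtures(groups, include_neurogenesis=with_markers)
        frame = animals_to_frame(generate_animals(spec, config.seed))
    else:  # user CSV of animal records
        frame = pd.read_csv(config.source, index_col=0)
        frame = frame[frame["group_id"].isin(groups)]
    cols = list(POPULATIONS) + (["Ki67", "DCX"] if with_markers else [])
    counts = frame[cols].copy()
    if with_markers:
        for marker in ("Ki67", "DCX"):
            model = (
                DeclineModel.literature(marker, config.reference_age_months)
                if config.y_source == "literature"
                else DeclineModel.study_refit(marker, config.reference_age_months)
            )
            factor = np.exp(
                (np.log(model.reference_age_months) - np.log(frame["age_months"].to_numpy()))
                * model.exponent
            )
            counts[marker] = counts[marker].to_numpy() * factor
    counts.attrs["group_ids"] = frame["group_id"]
    return counts, "per_animal"


def run_analysis(config: AnalysisConfig) -> RunResult:
    """Execute one configured analysis and (optionally) write its reports."""
    groups = _resolve_groups(config)
    if not groups:
        raise ValueError("no groups left to analyze after exclusions")
    ratios = None
    profiles = None

    if config.analysis == "ratios":
        t4 = datasets.load_fixture("table4").set_index("group_id")
        matrix = CompositionMatrix(
            t4.loc[list(groups), list(RATIO_COLUMNS)], semantics="raw",
            meta={"analysis": config.analysis},
        )
        ratios = classify_table(matrix.values)
        row_mode = "group_ratios"
        log.info("ratio analysis on %d groups; no transformation applied", len(groups))
    else:
        counts, row_mode = _assemble_counts(config, groups)
        raw = CompositionMatrix(counts, semantics="raw", meta={"analysis": config.analysis})
        profiles = percent_matrix(
            CompositionMatrix(counts[list(POPULATIONS)], semantics="raw")
        ).values
        if config.transformation == "log_scale_shift":
            matrix = offset_shift(scale_matrix(raw, apply_log=True), config.shift_epsilon)
            log.info("log + per-animal scaling, offset shift %.6g", matrix.meta["shift"])
        elif config.transformation == "percent":
            matrix = percent_matrix(raw)
        else:
            matrix = raw

    ca = correspondence_analysis(matrix)
    ca.meta.update(analysis=config.analysis, row_mode=row_mode,
                   shift=matrix.meta.get("shift", 0.0))
    result = RunResult(
        config=config, ca=ca, matrix=matrix, ratios=ratios, profiles=profiles,
        row_mode=row_mode,
    )
    if config.out_dir is not None:
        result.paths = write_reports(result)
    return result


def write_reports(result: RunResult) -> dict[str, Path]:
    """Write the standard report CSVs and the run-metadata JSON."""
    outdir = Path(result.config.out_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    ca = result.ca
    paths: dict[str, Path] = {}

    coords = pd.concat(
        [ca.row_coords.assign(side="row"), ca.col_coords.assign(side="col")]
    )
    coords.index.name = "label"
    inertia = pd.DataFrame(
        {
            "singular_value": ca.singular_values,
            "inertia_pct": ca.axis_inertia_pct,
        },
        index=ca.row_coords.columns,
    )
    inertia.index.name = "axis"
    contrib = pd.concat(
        [ca.row_contrib_pct.assign(side="row"), ca.col_contrib_pct.assign(side="col")]
    )
    contrib.index.name = "label"

    frames = {"coordinates": coords, "inertia": inertia, "contributions": contrib}
    if result.ratios is not None:
        frames["ratios"] = result.ratios
    if result.profiles is not None:
        profiles = result.profiles.copy()
        profiles.index.name = "label"
        frames["profiles"] = profiles
    for name, frame in frames.items():
        path = outdir / f"{name}.csv"
        frame.to_csv(path)
        paths[name] = path

    meta = {
        "config": asdict(result.config),
        "row_mode": result.row_mode,
        "shift": result.matrix.meta.get("shift", 0.0),
        "total_inertia": result.ca.total_inertia,
        "groups_analyzed": sorted(set(
            result.matrix.values.index
            if result.row_mode != "per_animal"
            else [str(i).split("/")[0] for i in result.matrix.values.index]
        )),
    }
    meta_path = outdir / "run_metadata.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True))
    paths["metadata"] = meta_path
    return paths


def run_from_metadata(path: str | Path, out_dir: Optional[str] = None) -> RunResult:
    """Regenerate a run from its metadata JSON (config echo) alone."""
    meta = json.loads(Path(path).read_text())
    cfg = dict(meta["config"])
    if cfg.get("groups") is not None:
        cfg["groups"] = tuple(cfg["groups"])
    cfg["exclude_groups"] = tuple(cfg.get("exclude_groups", ()))
    if out_dir is not None:
        cfg["out_dir"] = out_dir
    return run_analysis(AnalysisConfig(**cfg))
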