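"""End-to-end study orchestration: ingest -> QC -> normalize -> indices -> comparisons.

``run_study`` wires the modules together under a single seeded
configuration and returns a result bundle; ``write_results`` serializes
every artifact as delimited text plus a provenance record (config hash,
seed, package version, decision parameters) so a run is reproducible
byte-for-byte.  A failing loading-control QC is reported and recorded but
does not abort the downstream stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .densitometry import quantify_blot, read_image, read_roi_table, measurements_to_frame
from .indices import DEFAULT_INDEX_DEFINITIONS, compute_indices
from .mc import MCConfig, comparison_matrix, table1_layout
from .normalization import (
    BAND_COLUMNS,
    NormalizedTable,
    QCReport,
    loading_control_qc,
    normalize,
    summarize,
)

__all__ = ["StudyConfig", "StudyResult", "run_study", "read_band_table", "write_results"]


@dataclass(frozen=True)
class StudyConfig:
    """Full study description: design, maps, index definitions, MC settings."""

    groups: Mapping[str, int]
    reference_group: str = "normal"
    loading_control: str = "GAPDH"
    blot_set_map: Mapping[str, str] = field(default_factory=dict)
    control_lanes: Mapping[str, str] = field(default_factory=dict)
    index_definitions: Mapping[str, tuple[str, str]] | None = None
    mc: MCConfig = field(default_factory=MCConfig)
    references: Sequence[str] | None = None  # CI columns; default: all groups
    include_indices: bool = True
    input_mode: str = "table"  # "table" | "images"
    band_table: str | None = None
    images: Mapping[str, str] = field(default_factory=dict)  # blot_id -> image path
    roi_table: str | None = None
    lane_maps: Mapping[str, Mapping[str, tuple[str, str]]] = field(default_factory=dict)
    output_dir: str | None = None

    def __post_init__(self) -> None:
        if self.reference_group not in self.groups:
            raise ValueError(f"reference group {self.reference_group!r} not in groups")
        if self.input_mode not in ("table", "images"):
            raise ValueError(f"unknown input_mode {self.input_mode!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw, base_dir=Path(path).parent)

    @classmethod
    def from_dict(cls, raw: dict, base_dir: Path | None = None) -> "StudyConfig":
        raw = dict(raw)
        for key in ("groups", "blot_set_map", "control_lanes"):
            if key in raw and raw[key] is not None:
                raw[key] = dict(raw[key])
        if raw.get("index_definitions"):
            raw["index_definitions"] = {
                k: tuple(v) for k, v in raw["index_definitions"].items()
            }
        if "mc" in raw and not isinstance(raw["mc"], MCConfig):
            raw["mc"] = MCConfig(**raw["mc"])
        if base_dir is not None:
            for key in ("band_table", "roi_table"):
                if raw.get(key):
                    raw[key] = str(base_dir / raw[key])
            if raw.get("images"):
                raw["images"] = {b: str(base_dir / p) for b, p in raw["images"].items()}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config fields: {', '.join(sorted(unknown))}")
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["mc"] = dataclasses.asdict(self.mc)
        d["groups"] = dict(self.groups)
        if self.index_definitions is not None:
            d["index_definitions"] = {k: list(v) for k, v in self.index_definitions.items()}
        return d

    def sha256(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        ).hexdigest()


@dataclass(frozen=True)
class StudyResult:
    """Bundle of every pipeline artifact."""

    qc: QCReport
    normalized: NormalizedTable
    summaries: pd.DataFrame
    index_values: pd.DataFrame | None
    matrix: pd.DataFrame
    table1: pd.DataFrame
    provenance: dict


def read_band_table(path: str | Path) -> pd.DataFrame:
    """Read a delimited-text band table, validating the canonical schema."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in BAND_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"band table {path}: missing columns {', '.join(missing)}")
    if len(df):
        bad = df.loc[pd.to_numeric(df["raw_density"], errors="coerce").isna()]
        if len(bad):
            raise ValueError(f"band table {path}: non-numeric raw_density in rows {bad.index.tolist()[:10]}")
    for col in ("blot_id", "lane_id", "animal_id", "group", "protein"):
        df[col] = df[col].astype(str)
    return df


def _table_from_images(config: StudyConfig) -> pd.DataFrame:
    if not config.images or config.roi_table is None:
        raise ValueError("input_mode='images' requires 'images' and 'roi_table'")
    rois = read_roi_table(config.roi_table)
    frames = []
    for blot_id, path in sorted(config.images.items()):
        image = read_image(path)
        blot_rois = [r for r in rois if r.blot_id == blot_id]
        lane_map = {k: tuple(v) for k, v in config.lane_maps.get(blot_id, {}).items()}
        frames.append(measurements_to_frame(quantify_blot(image, blot_rois, lane_map)))
    return pd.concat(frames, ignore_index=True)


def run_study(config: StudyConfig, band_table: pd.DataFrame | None = None) -> StudyResult:
    """Execute the full analysis chain; deterministic given the config seed."""
    if band_table is None:
        if config.input_mode == "images":
            band_table = _table_from_images(config)
        elif config.band_table is not None:
            band_table = read_band_table(config.band_table)
        else:
            raise ValueError("no input: provide band_table (argument or config) or images")

    sample_groups = set(band_table["group"].unique()) - {"control_sample"}
    unknown = sorted(sample_groups - set(config.groups))
    if unknown:
        raise ValueError(f"data contain groups absent from the design: {', '.join(unknown)}")
    absent = sorted(set(config.groups) - sample_groups)
    if absent:
        raise ValueError(f"design groups absent from the data: {', '.join(absent)}")

    normalized = normalize(
        band_table,
        blot_set_map=config.blot_set_map,
        control_lanes=config.control_lanes,
        reference_group=config.reference_group,
    )
    qc = loading_control_qc(normalized, config.loading_control, config.mc)

    summaries = summarize(normalized)
    index_values = None
    if config.include_indices:
        defs = config.index_definitions or DEFAULT_INDEX_DEFINITIONS
        index_values = compute_indices(normalized, defs)
        summaries = pd.concat(
            [summaries, summarize(index_values)], ignore_index=True
        )

    matrix = comparison_matrix(summaries, config.mc, references=config.references)
    provenance = {
        "package": "blotkit",
        "version": __version__,
        "config_sha256": config.sha256(),
        "seed": config.mc.seed,
        "qc_passed": qc.passed,
        "n_comparisons": int(len(matrix)),
        "decisions": {
            "background_estimator": "surround median, margin 3 px",
            "normalization_order": "set-average then control-sample ratio",
            "ci_method": "empirical percentile (alpha/2, 1-alpha/2) of simulated means",
            "p_floor": 1.0 / config.mc.reps,
            "indices": "per-animal",
        },
    }
    return StudyResult(
        qc=qc,
        normalized=normalized,
        summaries=summaries,
        index_values=index_values,
        matrix=matrix,
        table1=table1_layout(matrix),
        provenance=provenance,
    )


def write_results(result: StudyResult, outdir: str | Path) -> dict[str, Path]:
    """Write every artifact as delimited text / JSON; returns the file map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files = {}

    def _csv(name: str, df: pd.DataFrame, **kw) -> None:
        path = outdir / name
        df.to_csv(path, **kw)
        files[name] = path

    _csv("normalized.csv", result.normalized.rows, index=False)
    _csv("group_summaries.csv", result.summaries, index=False)
    if result.index_values is not None:
        _csv("index_values.csv", result.index_values, index=False)
    _csv("comparisons.csv", result.matrix, index=False)
    _csv("statistical_table.csv", result.table1, index=True)

    qc_payload = {
        "passed": result.qc.passed,
        "control_protein": result.qc.control_protein,
        "alpha": result.qc.alpha,
        "significant_groups": sorted(
            result.qc.comparisons.loc[
                result.qc.comparisons.get("significant", pd.Series(dtype=bool)) == True,  # noqa: E712
                "comparator",
            ].unique()
        ) if len(result.qc.comparisons) else [],
    }
    for name, payload in (("qc.json", qc_payload), ("provenance.json", result.provenance)):
        path = outdir / name
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
        files[name] = path
    return files
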