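"""Configured end-to-end pipeline over a replica registry.

One YAML config drives every stage.  Each registry entry points (via its
``paths`` mapping) at per-replica feature tables: ``dihedrals`` (44
angle columns), optional ``signatures`` (encoded carbonyl-flip strings),
``ions``/``water`` (axial traces), ``gating`` (two interface distance
columns) and ``lipid`` (headgroup in-plane distances).  The pipeline
embeds and clusters the dihedrals, labels states, counts permeation
events and conductance per condition, classifies gating, and flags
lipids, writing one JSON report per replica plus an aggregate report.
Reports embed the config hash, seed and package version; given the same
inputs the run is deterministic.
"""

from __future__ import annotations

import hashlib
import json
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional

import numpy as np
import yaml
from pydantic import BaseModel, Field, ValidationError

from . import __version__
from .io import FeatureTable, ReplicaMeta, load_replica_registry, read_feature_table
from .embedding import SketchMap
from .states import DBSCANParams, dbscan, label_states, population_table
from .permeation import (
    FilterBounds,
    aggregate_conductance,
    detect_events,
    filter_events_after_water_exit,
    water_occupancy,
)
from .gating import classify_updown, joint_label, lipid_cavity_flag

__all__ = [
    "PipelineConfig",
    "validate_config",
    "run_pipeline",
    "encode_signature",
    "decode_signature",
    "ReportMeta",
    "ReplicaReport",
    "AggregateReport",
    "report_json_schema",
]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and replica."""


class EmbeddingConfig(BaseModel):
    sigma: float = Field(2.5, gt=0)
    A: float = Field(12.0, gt=0)
    B: float = Field(12.0, gt=0)
    a: float = Field(1.0, gt=0)
    b: float = Field(2.0, gt=0)
    n_landmarks: int = Field(1000, ge=3)
    metric: str = "periodic"


class ClusterConfig(BaseModel):
    eps: float = Field(0.8, gt=0)
    min_points: int = Field(3, ge=1)
    window: tuple[tuple[float, float], tuple[float, float]] = (
        (-60.0, 60.0),
        (-60.0, 60.0),
    )


class PermeationConfig(BaseModel):
    z_low: float = -6.0
    z_high: float = 6.0
    radial_cut: float = Field(4.0, gt=0)
    count_initial_inside: bool = True
    gate_on_water_exit: bool = False


class GatingConfig(BaseModel):
    threshold: float = Field(8.0, gt=0)
    min_dwell: int = Field(1, ge=1)


class LipidConfig(BaseModel):
    cutoff: float = Field(10.0, gt=0)
    fraction_rule: float = Field(0.5, ge=0, le=1)


class PipelineConfig(BaseModel):
    registry: str
    output_dir: str = "pipeline_out"
    seed: int = 0
    embedding: EmbeddingConfig = EmbeddingConfig()
    cluster: ClusterConfig = ClusterConfig()
    permeation: PermeationConfig = PermeationConfig()
    gating: GatingConfig = GatingConfig()
    lipids: LipidConfig = LipidConfig()

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


class ReportMeta(BaseModel):
    config_hash: str
    seed: int
    version: str


class ReplicaReport(BaseModel):
    """Schema of one per-replica report file."""

    replica: str
    sections: dict
    meta: ReportMeta
    timestamp: str


class AggregateReport(BaseModel):
    """Schema of the aggregate report file."""

    populations_percent: dict[str, dict[str, float]]
    conductance: dict[str, dict]
    replicas: list[str]
    meta: ReportMeta
    timestamp: str


def report_json_schema() -> dict:
    """JSON schema of the report bundle (also shipped as package data)."""
    return {
        "replica_report": ReplicaReport.model_json_schema(),
        "aggregate_report": AggregateReport.model_json_schema(),
    }


def validate_config(path: str | Path) -> tuple[Optional[PipelineConfig], list[str]]:
    """Load and validate a YAML pipeline config, collecting all errors."""
    errors: list[str] = []
    path = Path(path)
    if not path.exists():
        return None, [f"config file not found: {path}"]
    try:
        doc = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        return None, [f"invalid YAML: {exc}"]
    try:
        cfg = PipelineConfig(**doc)
    except ValidationError as exc:
        for err in exc.errors():
            loc = ".".join(str(x) for x in err["loc"])
            errors.append(f"{loc}: {err['msg']}")
        return None, errors
    reg_path = Path(cfg.registry)
    if not reg_path.is_absolute():
        reg_path = path.parent / reg_path
    if not reg_path.exists():
        errors.append(f"registry: file not found: {reg_path}")
        return None, errors
    cfg = cfg.model_copy(update={"registry": str(reg_path)})
    try:
        registry = load_replica_registry(reg_path)
    except Exception as exc:
        errors.append(f"registry: {exc}")
        return None, errors
    for meta in registry:
        for key, p in meta.paths.items():
            p = Path(p)
            if not p.is_absolute():
                p = reg_path.parent / p
            if not p.exists():
                errors.append(
                    f"registry: replica {meta.force_field}-{meta.init_config}-"
                    f"{meta.voltage_mV}mV #{meta.replica}: missing {key} file {p}"
                )
    return (cfg, errors) if not errors else (None, errors)


# --- flip-signature encoding used in signatures.csv sidecars ---------------

def encode_signature(sig: frozenset) -> str:
    """Encode a flip signature as 'A:S4-S3;B:S3-S2' ('' for none)."""
    return ";".join(f"{c}:{b}" for c, b in sorted(sig))


def decode_signature(text: str) -> frozenset:
    text = str(text).strip()
    if not text or text == "nan":
        return frozenset()
    pairs = []
    for item in text.split(";"):
        chain, boundary = item.split(":")
        pairs.append((chain, boundary))
    return frozenset(pairs)


def _replica_tag(meta: ReplicaMeta) -> str:
    return f"{meta.force_field}-{meta.init_config}-{int(meta.voltage_mV)}mV-r{meta.replica}"


def _condition_tag(meta: ReplicaMeta) -> str:
    return f"{meta.force_field}-{meta.init_config}-{int(meta.voltage_mV)}mV"


def _resolve(meta: ReplicaMeta, key: str, base: Path) -> Path | None:
    if key not in meta.paths:
        return None
    p = Path(meta.paths[key])
    return p if p.is_absolute() else base / p


def _load_table(meta, key, base) -> FeatureTable | None:
    p = _resolve(meta, key, base)
    return read_feature_table(p) if p is not None else None


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage for every replica; returns the aggregate report.

    Writes ``<output_dir>/<replica>.json`` per replica and
    ``<output_dir>/aggregate.json``; any stage failure aborts with a
    :class:`PipelineError` naming the stage.
    """
    registry = load_replica_registry(config.registry)
    base = Path(config.registry).parent
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    angle_cols_cache: dict[str, np.ndarray] = {}
    per_condition_labels: dict[str, list[np.ndarray]] = {}
    per_condition_counts: dict[str, list[tuple[int, float, float]]] = {}
    replica_reports = []

    for meta in registry:
        tag = _replica_tag(meta)
        report: dict = {"replica": tag, "sections": {}}

        # --- states: embed + cluster + label -----------------------------
        dihedrals = _load_table(meta, "dihedrals", base)
        if dihedrals is not None:
            try:
                X = np.column_stack([dihedrals[c] for c in dihedrals.column_names])
                sm = SketchMap(
                    sigma=config.embedding.sigma,
                    A=config.embedding.A, B=config.embedding.B,
                    a=config.embedding.a, b=config.embedding.b,
                    n_landmarks=config.embedding.n_landmarks,
                    metric=config.embedding.metric,
                    random_state=config.seed,
                )
                low_d = sm.fit_transform(X)
                params = DBSCANParams(
                    eps=config.cluster.eps,
                    min_points=config.cluster.min_points,
                    window=config.cluster.window,
                )
                cluster_ids = dbscan(low_d, params)
                sig_table = _load_table(meta, "signatures", base)
                if sig_table is not None:
                    import pandas as pd

                    sig_df = pd.read_csv(_resolve(meta, "signatures", base),
                                         keep_default_na=False)
                    signatures = [decode_signature(s) for s in sig_df["signature"]]
                    labels = label_states(cluster_ids, signatures)
                else:
                    labels = np.array(
                        ["other" if c == -1 else f"cluster_{c}" for c in cluster_ids]
                    )
                per_condition_labels.setdefault(_condition_tag(meta), []).append(labels)
                report["sections"]["states"] = {
                    "n_frames": int(len(labels)),
                    "n_clusters": int(len(set(cluster_ids) - {-1})),
                    "stress": float(sm.stress_),
                }
            except Exception as exc:
                raise PipelineError(f"{tag}: states stage failed: {exc}") from exc

        # --- permeation ---------------------------------------------------
        ions = _load_table(meta, "ions", base)
        if ions is not None:
            try:
                bounds = FilterBounds(
                    z_low=config.permeation.z_low,
                    z_high=config.permeation.z_high,
                    radial_cut=config.permeation.radial_cut,
                )
                series = {c: ions[c] for c in ions.column_names}
                events = detect_events(
                    series, bounds,
                    count_initial_inside=config.permeation.count_initial_inside,
                )
                if config.permeation.gate_on_water_exit:
                    water = _load_table(meta, "water", base)
                    if water is None:
                        raise PipelineError("water gating requested but no water table")
                    _, first_exit = water_occupancy(
                        {c: water[c] for c in water.column_names}, bounds
                    )
                    events = filter_events_after_water_exit(events, first_exit)
                outward = [e for e in events if e.direction == 1]
                per_condition_counts.setdefault(_condition_tag(meta), []).append(
                    (len(outward), meta.duration_us, meta.voltage_mV)
                )
                report["sections"]["permeation"] = {
                    "n_events_outward": len(outward),
                    "n_events_inward": len(events) - len(outward),
                }
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"{tag}: permeation stage failed: {exc}") from exc

        # --- gating -------------------------------------------------------
        gating_tbl = _load_table(meta, "gating", base)
        if gating_tbl is not None:
            try:
                summaries = {}
                for col in gating_tbl.column_names:
                    _, summary = classify_updown(
                        gating_tbl[col],
                        threshold=config.gating.threshold,
                        min_dwell=config.gating.min_dwell,
                    )
                    summaries[col] = summary
                cols = list(summaries)
                joint = (
                    joint_label(summaries[cols[0]], summaries[cols[1]])
                    if len(cols) >= 2 else summaries[cols[0]].prevalent
                )
                report["sections"]["gating"] = {
                    "joint_prevalent": joint,
                    "interfaces": {
                        c: {
                            "fraction_down": s.fraction_down,
                            "prevalent": s.prevalent,
                            "up_to_down": s.n_up_to_down,
                            "down_to_up": s.n_down_to_up,
                        }
                        for c, s in summaries.items()
                    },
                }
            except Exception as exc:
                raise PipelineError(f"{tag}: gating stage failed: {exc}") from exc

        # --- lipids -------------------------------------------------------
        lipid_tbl = _load_table(meta, "lipid", base)
        if lipid_tbl is not None:
            try:
                flags = {
                    c: lipid_cavity_flag(
                        lipid_tbl[c], lipid=c,
                        cutoff=config.lipids.cutoff,
                        fraction_rule=config.lipids.fraction_rule,
                    )
                    for c in lipid_tbl.column_names
                }
                report["sections"]["lipids"] = {
                    c: {"fraction_below": f.fraction_below, "in_cavity": f.in_cavity}
                    for c, f in flags.items()
                }
            except Exception as exc:
                raise PipelineError(f"{tag}: lipids stage failed: {exc}") from exc

        report["meta"] = {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": __version__,
        }
        report["timestamp"] = datetime.now(timezone.utc).isoformat()
        (out_dir / f"{tag}.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        replica_reports.append(report)

    # --- aggregate --------------------------------------------------------
    populations = {}
    if per_condition_labels:
        merged = {
            cond: np.concatenate(chunks)
            for cond, chunks in per_condition_labels.items()
        }
        populations = population_table(merged).round(4).to_dict(orient="index")
    conductance = {}
    for cond, rows in per_condition_counts.items():
        counts = [r[0] for r in rows]
        durations = [r[1] for r in rows]
        voltage = rows[0][2]
        if voltage == 0:
            conductance[cond] = {"events": counts, "mean_pS": None, "sd_pS": None}
        else:
            est = aggregate_conductance(counts, durations, voltage)
            conductance[cond] = {
                "events": counts,
                "mean_pS": est.mean,
                "sd_pS": est.sd,
            }
    aggregate = {
        "populations_percent": populations,
        "conductance": conductance,
        "replicas": [r["replica"] for r in replica_reports],
        "meta": {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": __version__,
        },
        "timestamp": datetime.now(timezone.utc).isoformat(),
    }
    (out_dir / "aggregate.json").write_text(json.dumps(aggregate, indent=2, sort_keys=True))
    return aggregate
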