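"""End-to-end orchestration: segments -> filters -> QRS -> cycle -> features -> stats.

``run_pipeline`` executes the full chain on either a synthetic cohort or
ECG/event files, producing the per-segment feature table, the group-
comparison report, and a run manifest that conserves segment counts across
every stage boundary.  Fully deterministic for a fixed configuration seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as nio
from .cycle import InsufficientCyclesError, build_cycle_matrix, extract_representative
from .features import DelineationError, TWaveConfig, compute_features, delineate_t
from .group_stats import assign_group, run_feature_tests
from .preprocess import (
    DegenerateSignalError, FilterConfig, extract_segments, filter_segment, normalize,
)
from .qrs import (
    DetectorConfig, GateConfig, InsufficientBeatsError, detect_r_peaks,
    locate_qrs_points, quality_gate,
)
from .synth import CohortConfig, generate_cohort

__all__ = ["PipelineConfig", "RunManifest", "run_pipeline", "process_segment"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All knobs of the analysis in one validated object.

    ``mode`` is 'synthetic' (generate a cohort from ``cohort``) or 'files'
    (read ``ecg_paths``/``events_paths`` pairs).  ``sides`` controls which
    event-adjacent segments enter the analysis; the default keeps one
    (following) segment per blood-gas event.
    """

    mode: str = "synthetic"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    ecg_paths: tuple[str, ...] = ()
    events_paths: tuple[str, ...] = ()
    format: str = "csv"
    channel: int = 0
    seg_len_s: float = 10.0
    sides: tuple[str, ...] = ("following",)
    filter: FilterConfig = field(default_factory=FilterConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    gate: GateConfig = field(default_factory=GateConfig)
    cycle_m: int = 256
    twave: TWaveConfig = field(default_factory=TWaveConfig)
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.seg_len_s <= 0:
            raise ValueError("segment length must be > 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.channel not in (0, 1):
            raise ValueError("channel must be 0 or 1")
        if self.cycle_m < 16:
            raise ValueError("cycle length M must be >= 16")
        bad = set(self.sides) - {"preceding", "following"}
        if bad or not self.sides:
            raise ValueError("sides must be a non-empty subset of {preceding, following}")
        if self.mode == "files" and len(self.ecg_paths) != len(self.events_paths):
            raise ValueError("ecg_paths and events_paths must pair up")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        nested = {
            "cohort": CohortConfig, "filter": FilterConfig, "detector": DetectorConfig,
            "gate": GateConfig, "twave": TWaveConfig,
        }
        kwargs = {}
        for key, value in raw.items():
            if key in nested and isinstance(value, dict):
                kwargs[key] = nested[key](**value)
            elif key in ("ecg_paths", "events_paths", "sides") and isinstance(value, list):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class RunManifest:
    """Per-run accounting: config snapshot, stage counts, dispositions."""

    version: str = __version__
    n_records: int = 0
    n_segments_extracted: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    dispositions: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def check(self) -> None:
        assert self.n_accepted + self.n_rejected == self.n_segments_extracted

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "n_records": self.n_records,
            "n_segments_extracted": self.n_segments_extracted,
            "n_accepted": self.n_accepted,
            "n_rejected": self.n_rejected,
            "dispositions": self.dispositions,
            "config": self.config,
        }


def process_segment(segment, config: PipelineConfig) -> tuple[dict | None, str]:
    """Run one raw segment through filter -> QRS -> cycle -> features.

    Returns (feature row, "") on success or (None, rejection reason).
    """
    try:
        filt = filter_segment(segment, config.filter)
        norm = normalize(filt)
    except (ValueError, DegenerateSignalError) as exc:
        return None, f"preprocess: {exc}"
    r = detect_r_peaks(norm, config.detector)
    if r.size < 2:
        return None, "beat-count"
    try:
        ann = locate_qrs_points(norm, r, config.detector)
    except InsufficientBeatsError:
        return None, "beat-count"
    ann = quality_gate(ann, norm, config.gate)
    if ann.verdict == "rejected":
        return None, ann.reason
    try:
        matrix = build_cycle_matrix(norm, ann, m=config.cycle_m)
        rep = extract_representative(matrix)
        rep = replace(rep, offset=norm.offset, scale=norm.scale)
        t_ann = delineate_t(rep, config.twave)
    except (InsufficientCyclesError, DelineationError) as exc:
        return None, f"cycle: {exc}"
    group = assign_group(segment.ph)
    row = compute_features(rep, ann, t_ann, ph=segment.ph, group=group,
                           segment_id=segment.meta.get("segment_id", segment.event_id))
    row["variance_fraction"] = rep.variance_fraction
    return row, ""


def _input_iter(config: PipelineConfig):
    """Yield (record_id, ECGRecord, events DataFrame) for the configured input."""
    if config.mode == "synthetic":
        cohort = replace(config.cohort, seed=config.seed)
        for i, (rec, truth, events) in enumerate(generate_cohort(cohort)):
            yield f"synth{i:03d}", rec, events
    else:
        for i, (ecg_path, ev_path) in enumerate(zip(config.ecg_paths, config.events_paths)):
            rec = nio.read_ecg(ecg_path, format=config.format)
            yield Path(ecg_path).stem, rec, nio.read_events(ev_path)


def run_pipeline(config: PipelineConfig) -> tuple[pd.DataFrame, dict, RunManifest]:
    """Execute the full analysis; optionally write outputs to ``config.out_dir``.

    Raises ``RuntimeError`` with a rejection summary when no segment survives
    the quality gate.
    """
    manifest = RunManifest(config=_config_snapshot(config))
    rows = []
    for rec_id, record, events in _input_iter(config):
        manifest.n_records += 1
        segments = extract_segments(
            record, events, seg_len=config.seg_len_s, channel=config.channel,
            sides=config.sides,
        )
        for seg in segments:
            manifest.n_segments_extracted += 1
            seg.meta["segment_id"] = f"{rec_id}:{seg.event_id}:{seg.side}"
            row, reason = process_segment(seg, config)
            if row is None:
                manifest.n_rejected += 1
                logger.info("segment %s rejected: %s", seg.meta["segment_id"], reason)
                manifest.dispositions.append(
                    {"segment_id": seg.meta["segment_id"], "status": "rejected",
                     "reason": reason})
            else:
                manifest.n_accepted += 1
                manifest.dispositions.append(
                    {"segment_id": seg.meta["segment_id"], "status": "accepted",
                     "reason": ""})
                rows.append(row)
    manifest.check()
    if not rows:
        reasons = pd.Series([d["reason"] for d in manifest.dispositions])
        raise RuntimeError(
            "no segments accepted; rejection reasons:\n" + reasons.value_counts().to_string()
        )
    table = pd.DataFrame(rows)
    report = run_feature_tests(table, alpha=config.alpha)
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        nio.write_features(table, out / "features.tsv")
        nio.write_report(report, out / "report.json")
        nio.write_report(manifest.to_dict(), out / "manifest.json")
    return table, report, manifest


def _config_snapshot(config: PipelineConfig) -> dict:
    def clean(obj):
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if obj is None or isinstance(obj, (bool, int, float, str)):
            return obj
        return str(obj)

    return clean(asdict(config))
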