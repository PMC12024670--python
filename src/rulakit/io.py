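"""File formats, run configuration and the end-to-end pipeline driver.

Serialised formats (all plain text, degrees everywhere):

* keypoints: JSON ``{"plane": ..., "keypoints": {name: [x, y, confidence]}}``
  or CSV with columns ``name,x,y,confidence`` and a ``# plane: ...`` header
  comment;
* manual annotations: JSON;
* angle streams: CSV with one column per posture field, one row per frame,
  and a ``# rate_hz: ...`` header comment;
* paired scores: long CSV ``participant,region,imu_score,pose_score``;
* agreement report: JSON (written with sorted keys so reruns with the same
  seed are byte-identical).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .agreement import StatsConfig, compare_methods
from .core import ANGLE_FIELDS, FLAG_FIELDS, MODIFIER_FIELDS, RulaInputs
from .errors import ConfigError, SchemaError
from .pose import KEYPOINT_NAMES, ManualAnnotations, PoseConfig, Skeleton2D, score_pose_capture
from .simulate import CohortConfig, PoseNoise, ImuNoise, AngleSpec, simulate_cohort
from .stream import AngleStream

__all__ = [
    "RunConfig",
    "read_keypoints",
    "write_keypoints",
    "read_annotations",
    "write_annotations",
    "read_angle_stream",
    "write_angle_stream",
    "read_paired_scores",
    "write_paired_scores",
    "load_run_config",
    "write_report",
    "bland_altman_plot",
    "run_pipeline",
]

_STREAM_COLUMNS = ANGLE_FIELDS + FLAG_FIELDS + MODIFIER_FIELDS


# --------------------------------------------------------------------------
# Keypoints.
# --------------------------------------------------------------------------


def write_keypoints(path, skeleton: Skeleton2D) -> None:
    path = Path(path)
    if path.suffix == ".csv":
        lines = [f"# plane: {skeleton.plane}", "name,x,y,confidence"]
        for name in KEYPOINT_NAMES:
            x, y = skeleton.keypoints[name]
            c = skeleton.confidence[name]
            lines.append(f"{name},{x!r},{y!r},{c!r}")
        path.write_text("\n".join(lines) + "\n")
    else:
        payload = {
            "plane": skeleton.plane,
            "keypoints": {
                name: [*skeleton.keypoints[name], skeleton.confidence[name]]
                for name in KEYPOINT_NAMES
            },
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _validate_keypoint_row(name: str, x, y, c) -> tuple[float, float, float]:
    if name not in KEYPOINT_NAMES:
        raise SchemaError(f"unknown keypoint name {name!r}")
    try:
        x, y, c = float(x), float(y), float(c)
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"malformed coordinate/confidence for {name!r}") from exc
    if not (np.isfinite(x) and np.isfinite(y)):
        raise SchemaError(f"non-finite coordinate for {name!r}")
    if not (0.0 <= c <= 1.0):
        raise SchemaError(f"confidence for {name!r} must be in [0, 1]")
    return x, y, c


def read_keypoints(path, plane: str | None = None) -> Skeleton2D:
    """Read a 17-keypoint skeleton from JSON or CSV."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"keypoint file not found: {path}")
    keypoints: dict[str, tuple[float, float]] = {}
    confidence: dict[str, float] = {}
    if path.suffix == ".csv":
        lines = path.read_text().splitlines()
        for line in lines:
            if line.startswith("# plane:"):
                plane = line.split(":", 1)[1].strip()
        rows = [l for l in lines if l and not l.startswith("#")]
        if not rows or rows[0] != "name,x,y,confidence":
            raise SchemaError("keypoint CSV must start with header name,x,y,confidence")
        for line in rows[1:]:
            parts = line.split(",")
            if len(parts) != 4:
                raise SchemaError(f"malformed keypoint CSV row: {line!r}")
            name = parts[0]
            x, y, c = _validate_keypoint_row(name, *parts[1:])
            keypoints[name] = (x, y)
            confidence[name] = c
    else:
        try:
            payload = json.loads(path.read_text())
        except json.JSONDecodeError as exc:
            raise SchemaError(f"invalid JSON in {path}") from exc
        plane = payload.get("plane", plane)
        kps = payload.get("keypoints")
        if not isinstance(kps, dict):
            raise SchemaError("keypoint JSON must contain a 'keypoints' mapping")
        for name, triple in kps.items():
            if not (isinstance(triple, (list, tuple)) and len(triple) == 3):
                raise SchemaError(f"keypoint {name!r} must map to [x, y, confidence]")
            x, y, c = _validate_keypoint_row(name, *triple)
            keypoints[name] = (x, y)
            confidence[name] = c
    if plane is None:
        raise SchemaError("plane not specified in file or argument")
    missing = set(KEYPOINT_NAMES) - set(keypoints)
    if missing:
        raise SchemaError(f"missing keypoints: {sorted(missing)}")
    return Skeleton2D(plane=plane, keypoints=keypoints, confidence=confidence)


# --------------------------------------------------------------------------
# Annotations.
# --------------------------------------------------------------------------


def write_annotations(path, ann: ManualAnnotations) -> None:
    payload = dataclasses.asdict(ann)
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_annotations(path) -> ManualAnnotations:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"annotation file not found: {path}")
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"invalid JSON in {path}") from exc
    known = {f.name for f in dataclasses.fields(ManualAnnotations)}
    unknown = set(payload) - known
    if unknown:
        raise SchemaError(f"unknown annotation fields: {sorted(unknown)}")
    if payload.get("hand_direction") is not None:
        payload["hand_direction"] = {
            plane: tuple(vec) for plane, vec in payload["hand_direction"].items()
        }
    try:
        return ManualAnnotations(**payload)
    except Exception as exc:
        raise SchemaError(f"invalid annotations: {exc}") from exc


# --------------------------------------------------------------------------
# Angle streams.
# --------------------------------------------------------------------------


def write_angle_stream(path, stream: AngleStream) -> None:
    cols = stream.to_arrays()
    lines = [f"# rate_hz: {stream.rate!r}", ",".join(_STREAM_COLUMNS)]
    n = len(stream.frames)
    for i in range(n):
        row = []
        for name in _STREAM_COLUMNS:
            v = cols[name][i]
            row.append(repr(float(v)) if name in ANGLE_FIELDS else str(int(v)))
        lines.append(",".join(row))
    Path(path).write_text("\n".join(lines) + "\n")


def read_angle_stream(path) -> AngleStream:
    """Read an angle-stream CSV (``# rate_hz`` comment plus one row per frame)."""
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"angle stream file not found: {path}")
    rate = None
    lines = path.read_text().splitlines()
    for line in lines:
        if line.startswith("# rate_hz:"):
            try:
                rate = float(line.split(":", 1)[1])
            except ValueError as exc:
                raise SchemaError("malformed rate_hz header") from exc
    rows = [l for l in lines if l and not l.startswith("#")]
    if rate is None:
        raise SchemaError("angle stream is missing the '# rate_hz:' header")
    if rate <= 0:
        raise SchemaError(f"sampling rate must be positive, got {rate}")
    if not rows:
        raise SchemaError("angle stream has no header row")
    header = rows[0].split(",")
    missing = set(_STREAM_COLUMNS) - set(header)
    if missing:
        raise SchemaError(f"angle stream missing columns: {sorted(missing)}")
    if len(rows) == 1:
        raise SchemaError("angle stream contains no frames")
    frames = []
    for r, line in enumerate(rows[1:]):
        parts = line.split(",")
        if len(parts) != len(header):
            raise SchemaError(f"row {r}: expected {len(header)} cells")
        cells = dict(zip(header, parts))
        kwargs: dict[str, Any] = {}
        for name in _STREAM_COLUMNS:
            raw = cells[name]
            try:
                if name in ANGLE_FIELDS:
                    kwargs[name] = float(raw)
                elif name in FLAG_FIELDS:
                    kwargs[name] = bool(int(raw))
                else:
                    kwargs[name] = int(raw)
            except ValueError as exc:
                raise SchemaError(f"row {r}, column {name}: non-numeric cell {raw!r}") from exc
        frames.append(RulaInputs(**kwargs))
    return AngleStream(rate=rate, frames=frames)


# --------------------------------------------------------------------------
# Paired scores and reports.
# --------------------------------------------------------------------------


def write_paired_scores(path, scores: pd.DataFrame) -> None:
    scores.to_csv(path, index=False)


def read_paired_scores(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"paired-score file not found: {path}")
    df = pd.read_csv(path)
    required = {"participant", "region", "imu_score", "pose_score"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"paired-score CSV missing columns: {sorted(missing)}")
    return df


def write_report(path, report: dict) -> None:
    Path(path).write_text(json.dumps(report, indent=1, sort_keys=True))


def bland_altman_plot(path, scores: pd.DataFrame, region: str = "overall") -> None:
    """Scatter of per-pair differences with mean and 1.96-SD limit lines."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .agreement import bland_altman

    sub = scores[scores["region"] == region]
    ba = bland_altman(sub["imu_score"].to_numpy(), sub["pose_score"].to_numpy())
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(ba.means, ba.diffs, s=18, alpha=0.7)
    ax.axhline(ba.mean_diff, color="k", lw=1)
    for y in (ba.loa_low, ba.loa_high):
        ax.axhline(y, color="k", lw=1, ls=":")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (IMU - pose)")
    ax.set_title(f"Bland-Altman: {region}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


# --------------------------------------------------------------------------
# Run configuration and pipeline.
# --------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Configuration for the end-to-end simulate/score/compare pipeline."""

    seed: int = 0
    out_dir: str = "rulakit_out"
    cohort: CohortConfig = field(default_factory=CohortConfig)
    pose: PoseConfig = field(default_factory=PoseConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    write_cohort_files: bool = False
    make_plot: bool = True


def _build(cls, payload: dict, path_hint: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"unknown {path_hint} keys: {sorted(unknown)}")
    return payload


def load_run_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration."""
    import yaml

    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    payload = yaml.safe_load(path.read_text()) or {}
    if not isinstance(payload, dict):
        raise ConfigError("config root must be a mapping")
    cohort_payload = payload.pop("cohort", {})
    angles = cohort_payload.pop("angles", None)
    if angles is not None:
        cohort_payload["angles"] = {
            name: AngleSpec(**spec) for name, spec in angles.items()
        }
    if "imu_noise" in cohort_payload:
        cohort_payload["imu_noise"] = ImuNoise(**cohort_payload["imu_noise"])
    if "pose_noise" in cohort_payload:
        cohort_payload["pose_noise"] = PoseNoise(**cohort_payload["pose_noise"])
    try:
        cohort = CohortConfig(**_build(CohortConfig, cohort_payload, "cohort"))
        pose = PoseConfig(**_build(PoseConfig, payload.pop("pose", {}), "pose"))
        stats = StatsConfig(**_build(StatsConfig, payload.pop("stats", {}), "stats"))
        return RunConfig(cohort=cohort, pose=pose, stats=stats, **_build(RunConfig, payload, "run"))
    except TypeError as exc:
        raise ConfigError(str(exc)) from exc


def score_pose_files(sagittal_path, frontal_path, annotation_path, cfg: PoseConfig | None = None):
    """Score one two-plane capture from files; returns the RulaResult."""
    sag = read_keypoints(sagittal_path, plane="sagittal")
    fro = read_keypoints(frontal_path, plane="frontal")
    ann = read_annotations(annotation_path)
    return score_pose_capture(sag, fro, ann, cfg)


def run_pipeline(cfg: RunConfig) -> dict:
    """Simulate a cohort, score both branches, compare, and write artifacts.

    Returns the report dict; writes ``paired_scores.csv``,
    ``agreement_report.json`` and (optionally) ``bland_altman.png`` under
    ``cfg.out_dir``.  All randomness flows from ``cfg.seed``.
    """
    import logging

    log = logging.getLogger("rulakit")
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    log.info("simulating cohort: n=%d", cfg.cohort.n_participants)
    cohort = simulate_cohort(cfg.cohort, rng, cfg.pose)
    if cfg.write_cohort_files:
        from .simulate import generate_cohort

        generate_cohort(cfg.cohort, out / "cohort", np.random.default_rng(cfg.seed), cfg.pose)
    scores = cohort.paired_scores()
    write_paired_scores(out / "paired_scores.csv", scores)
    log.info("scored %d participants on both branches", cfg.cohort.n_participants)

    reports = compare_methods(scores, cfg.stats)
    report = {
        "seed": cfg.seed,
        "n_participants": cfg.cohort.n_participants,
        "families": {region: r.to_dict() for region, r in reports.items()},
    }
    write_report(out / "agreement_report.json", report)
    if cfg.make_plot:
        bland_altman_plot(out / "bland_altman.png", scores)
    log.info("wrote agreement report for %d score families", len(reports))
    return report
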