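"""Shared data model and file I/O for the conversational-kinematics pipeline.

Internal units are SI: positions in meters, motion timestamps in seconds.
Annotation times are milliseconds from recording start. Conversion to the
reporting units (mm, cm/s) happens inside the feature extractors only.

Delimited tables are UTF-8 CSV with ``.`` as decimal separator. Annotations may
also come from ELAN EAF files (time-aligned tiers only).
"""

from __future__ import annotations

import logging
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("convkin")

# -- errors -------------------------------------------------------------------


class ConvkinError(Exception):
    """Base class for package errors."""


class ValidationError(ConvkinError):
    """A domain invariant is violated (bad data values, bad arguments)."""


class FormatError(ConvkinError):
    """A file does not conform to the expected schema/dialect."""


class StageError(ConvkinError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage '{stage}' failed: {message}")
        self.stage = stage


# -- categories ---------------------------------------------------------------


class SocialActionCategory(str, Enum):
    """Social action performed by a question utterance.

    The first six categories are analyzed; SIMCO and PlanAct occur in the
    corpus but are excluded from the statistical analysis (fewer than 100
    occurrences each in the reference corpus).
    """

    InfReq = "InfReq"      # information request
    UndCheck = "UndCheck"  # understanding check
    SelfDir = "SelfDir"    # self-directed question
    StanSem = "StanSem"    # stance or sentiment
    OIR = "OIR"            # other-initiated repair
    ActPart = "ActPart"    # active participation (e.g., backchannel question)
    SIMCO = "SIMCO"        # structuring/initiating/maintaining conversation
    PlanAct = "PlanAct"    # plans and actions


ANALYZED_CATEGORIES: tuple[SocialActionCategory, ...] = tuple(SocialActionCategory)[:6]
EXCLUDED_CATEGORIES: tuple[SocialActionCategory, ...] = (
    SocialActionCategory.SIMCO,
    SocialActionCategory.PlanAct,
)
CATEGORY_LABELS = tuple(c.value for c in SocialActionCategory)
ANALYZED_LABELS = tuple(c.value for c in ANALYZED_CATEGORIES)

#: Question counts per category in the reference corpus the generator emulates
#: (2078 coded questions in total, before the SIMCO/PlanAct exclusion).
REFERENCE_CATEGORY_COUNTS: dict[str, int] = {
    "InfReq": 693,
    "UndCheck": 365,
    "SelfDir": 360,
    "StanSem": 246,
    "OIR": 126,
    "ActPart": 161,
    "SIMCO": 74,
    "PlanAct": 53,
}

ARTICULATORS = ("torso", "head", "hand_left", "hand_right")
ANALYSIS_ARTICULATORS = ("torso", "head", "hands")
FEATURES = ("magnitude", "lateral_position", "ap_position", "peak_velocity")


def parse_category(label: str) -> SocialActionCategory:
    try:
        return SocialActionCategory(label)
    except ValueError:
        raise ValidationError(
            f"unknown social action category {label!r}; expected one of {CATEGORY_LABELS}"
        ) from None


# -- core types ---------------------------------------------------------------


@dataclass
class MotionTrack:
    """Timestamped 3D positions of one articulator for one participant.

    Coordinates are meters in the device frame: x lateral, y vertical,
    z depth. Missing samples are NaN rows in ``positions``; timestamps are
    strictly increasing seconds.
    """

    articulator: str
    timestamps: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.articulator not in ARTICULATORS:
            raise ValidationError(
                f"unknown articulator {self.articulator!r}; expected one of {ARTICULATORS}"
            )
        if self.positions.ndim != 2 or self.positions.shape[1] != 3:
            raise ValidationError(
                f"positions must be (n, 3), got shape {self.positions.shape}"
            )
        if len(self.timestamps) != len(self.positions):
            raise ValidationError(
                f"{self.articulator}: {len(self.timestamps)} timestamps but "
                f"{len(self.positions)} positions"
            )
        if not np.all(np.isfinite(self.timestamps)):
            row = int(np.flatnonzero(~np.isfinite(self.timestamps))[0])
            raise ValidationError(f"{self.articulator}: non-finite timestamp at row {row}")
        diffs = np.diff(self.timestamps)
        if np.any(diffs <= 0):
            row = int(np.flatnonzero(diffs <= 0)[0]) + 1
            raise ValidationError(
                f"{self.articulator}: timestamps not strictly increasing at row {row} "
                f"(t={self.timestamps[row]:.6f} after t={self.timestamps[row - 1]:.6f})"
            )

    @property
    def valid_mask(self) -> np.ndarray:
        return np.all(np.isfinite(self.positions), axis=1)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.timestamps[0]), float(self.timestamps[-1])

    def check_rate(self, nominal_hz: float, tol: float = 0.2) -> None:
        """Require the median sampling interval to be within `tol` of nominal."""
        if len(self.timestamps) < 2:
            raise ValidationError(f"{self.articulator}: fewer than 2 samples")
        med = float(np.median(np.diff(self.timestamps)))
        if abs(med - 1.0 / nominal_hz) > tol / nominal_hz:
            raise ValidationError(
                f"{self.articulator}: median sampling interval {med * 1000:.2f} ms is "
                f"more than {tol:.0%} off the nominal {1000 / nominal_hz:.2f} ms"
            )

    def shifted(self, dt_s: float) -> "MotionTrack":
        return MotionTrack(self.articulator, self.timestamps + dt_s, self.positions)


@dataclass
class SessionRecording:
    """All four articulator tracks for one participant in one dyad session."""

    dyad_id: str
    participant_id: str
    tracks: dict[str, MotionTrack]
    interlocutor_axis: np.ndarray = field(
        default_factory=lambda: np.array([0.0, 0.0, -1.0])
    )
    calibration_center_x: float | None = None

    def __post_init__(self) -> None:
        missing = [a for a in ARTICULATORS if a not in self.tracks]
        if missing:
            raise ValidationError(
                f"recording {self.participant_id}: missing articulator tracks {missing}"
            )
        self.interlocutor_axis = np.asarray(self.interlocutor_axis, dtype=float)
        norm = float(np.linalg.norm(self.interlocutor_axis))
        if abs(norm - 1.0) > 1e-9:
            raise ValidationError(
                f"recording {self.participant_id}: interlocutor_axis has norm "
                f"{norm:.12f}, expected 1"
            )

    def shifted(self, dt_s: float) -> "SessionRecording":
        return SessionRecording(
            dyad_id=self.dyad_id,
            participant_id=self.participant_id,
            tracks={a: t.shifted(dt_s) for a, t in self.tracks.items()},
            interlocutor_axis=self.interlocutor_axis.copy(),
            calibration_center_x=self.calibration_center_x,
        )


@dataclass
class UtteranceAnnotation:
    """Onset/offset (ms from recording start) and social action of one question."""

    utterance_id: str
    participant_id: str
    onset_ms: float
    offset_ms: float
    category: SocialActionCategory

    def __post_init__(self) -> None:
        if isinstance(self.category, str):
            self.category = parse_category(self.category)
        if not (self.offset_ms > self.onset_ms):
            raise ValidationError(
                f"utterance {self.utterance_id}: offset {self.offset_ms} ms must be "
                f"after onset {self.onset_ms} ms"
            )
        if not (1.0 <= self.duration_ms <= 60000.0):
            raise ValidationError(
                f"utterance {self.utterance_id}: duration {self.duration_ms:.1f} ms "
                "outside [1, 60000] ms"
            )

    @property
    def duration_ms(self) -> float:
        return self.offset_ms - self.onset_ms


# -- motion table I/O ---------------------------------------------------------

_MOTION_COLUMNS = ["time_s", "articulator", "x", "y", "z"]


def write_motion_table(recording: SessionRecording, path: str | Path) -> None:
    """Write a recording as a long-format CSV (time_s, articulator, x, y, z)."""
    frames = []
    for articulator in ARTICULATORS:
        track = recording.tracks[articulator]
        frames.append(
            pd.DataFrame(
                {
                    "time_s": track.timestamps,
                    "articulator": articulator,
                    "x": track.positions[:, 0],
                    "y": track.positions[:, 1],
                    "z": track.positions[:, 2],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False, float_format="%.9f")


def read_motion_table(
    path: str | Path,
    articulator_map: Mapping[str, str] | None = None,
    *,
    dyad_id: str | None = None,
    participant_id: str | None = None,
    interlocutor_axis: Sequence[float] = (0.0, 0.0, -1.0),
    calibration_center_x: float | None = None,
    nominal_rate_hz: float | None = None,
) -> SessionRecording:
    """Read one participant's motion tracks from a delimited table.

    Accepts long format (columns time_s, articulator, x, y, z) or wide format
    (time_s plus ``<articulator>_x/_y/_z`` column blocks). ``articulator_map``
    renames file labels to the canonical articulator names. Missing samples
    (empty / NaN coordinates) are kept as NaN rows, not dropped.
    """
    path = Path(path)
    try:
        table = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise FormatError(f"{path}: cannot parse as CSV ({exc})") from exc
    articulator_map = dict(articulator_map or {})
    if "time_s" not in table.columns:
        raise FormatError(f"{path}: missing required column 'time_s'")

    tracks: dict[str, MotionTrack] = {}
    if set(_MOTION_COLUMNS).issubset(table.columns):  # long format
        for raw_name, block in table.groupby("articulator", sort=False):
            name = articulator_map.get(str(raw_name), str(raw_name))
            if name not in ARTICULATORS:
                row = int(block.index[0]) + 2  # 1-based, after header
                raise FormatError(
                    f"{path}: unknown articulator {raw_name!r} first seen at line {row}"
                )
            tracks[name] = _build_track(path, name, block)
    else:  # wide format
        for raw_name in _wide_articulators(table.columns):
            name = articulator_map.get(raw_name, raw_name)
            if name not in ARTICULATORS:
                raise FormatError(f"{path}: unknown articulator column block {raw_name!r}")
            block = table[["time_s"] + [f"{raw_name}_{ax}" for ax in "xyz"]].copy()
            block.columns = ["time_s", "x", "y", "z"]
            tracks[name] = _build_track(path, name, block)
    if not tracks:
        raise FormatError(f"{path}: no articulator data found")

    recording = SessionRecording(
        dyad_id=dyad_id if dyad_id is not None else path.stem,
        participant_id=participant_id if participant_id is not None else path.stem,
        tracks=tracks,
        interlocutor_axis=np.asarray(interlocutor_axis, dtype=float),
        calibration_center_x=calibration_center_x,
    )
    if nominal_rate_hz is not None:
        for track in recording.tracks.values():
            track.check_rate(nominal_rate_hz)
    n_missing = sum(int((~t.valid_mask).sum()) for t in recording.tracks.values())
    if n_missing:
        logger.warning("%s: %d samples flagged missing", path.name, n_missing)
    return recording


def _build_track(path: Path, name: str, block: pd.DataFrame) -> MotionTrack:
    times = block["time_s"].to_numpy(dtype=float)
    positions = block[["x", "y", "z"]].to_numpy(dtype=float)
    diffs = np.diff(times)
    if np.any(~np.isfinite(times)) or np.any(diffs <= 0):
        bad = np.flatnonzero(~np.isfinite(times))
        if len(bad) == 0:
            bad = np.flatnonzero(diffs <= 0) + 1
        line = int(block.index[int(bad[0])]) + 2
        raise FormatError(
            f"{path}: non-monotone or invalid timestamp for articulator "
            f"{name!r} at line {line}"
        )
    return MotionTrack(name, times, positions)


def _wide_articulators(columns: Iterable[str]) -> list[str]:
    names = []
    for col in columns:
        if col.endswith("_x"):
            names.append(col[:-2])
    return names


# -- annotation I/O -----------------------------------------------------------

_ANNOTATION_COLUMNS = ["utterance_id", "participant_id", "onset_ms", "offset_ms", "category"]


def write_annotations(annotations: Sequence[UtteranceAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "utterance_id": a.utterance_id,
                "participant_id": a.participant_id,
                "onset_ms": a.onset_ms,
                "offset_ms": a.offset_ms,
                "category": a.category.value,
            }
            for a in annotations
        ],
        columns=_ANNOTATION_COLUMNS,
    ).to_csv(path, index=False)


def read_annotations(
    path: str | Path,
    *,
    tier: str = "questions",
    participant_id: str | None = None,
    on_unknown_category: str = "warn",
) -> list[UtteranceAnnotation]:
    """Read question annotations from a CSV table or an ELAN EAF file.

    For EAF, only the time-aligned tier named ``tier`` is read; the annotation
    value is the category label. Records whose label is not a known category
    are collected and reported (``on_unknown_category``: "warn" skips them
    with a logged warning, "raise" raises).
    """
    path = Path(path)
    if path.suffix.lower() == ".eaf":
        records = _read_eaf(path, tier=tier, participant_id=participant_id)
    else:
        table = pd.read_csv(path)
        missing = [c for c in _ANNOTATION_COLUMNS if c not in table.columns]
        if missing:
            raise FormatError(f"{path}: annotation table missing columns {missing}")
        records = [
            dict(
                utterance_id=str(r.utterance_id),
                participant_id=str(r.participant_id),
                onset_ms=float(r.onset_ms),
                offset_ms=float(r.offset_ms),
                category=str(r.category),
            )
            for r in table.itertuples()
        ]

    annotations: list[UtteranceAnnotation] = []
    unknown: list[str] = []
    for rec in records:
        label = rec["category"]
        if label not in CATEGORY_LABELS:
            unknown.append(label)
            continue
        annotations.append(UtteranceAnnotation(**rec))
    if unknown:
        message = (
            f"{path.name}: {len(unknown)} annotation(s) with unknown category "
            f"labels {sorted(set(unknown))}"
        )
        if on_unknown_category == "raise":
            raise ValidationError(message)
        logger.warning(message)
    return annotations


def _read_eaf(path: Path, *, tier: str, participant_id: str | None) -> list[dict]:
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as exc:
        raise FormatError(f"{path}: not parseable as EAF XML ({exc})") from exc

    slots: dict[str, float] = {}
    for slot in root.iter("TIME_SLOT"):
        value = slot.get("TIME_VALUE")
        if value is None:
            raise FormatError(
                f"{path}: time slot {slot.get('TIME_SLOT_ID')!r} has no TIME_VALUE "
                "(unfilled slots are not supported)"
            )
        slots[slot.get("TIME_SLOT_ID", "")] = float(value)

    tier_elem = None
    available = []
    for t in root.iter("TIER"):
        available.append(t.get("TIER_ID"))
        if t.get("TIER_ID") == tier:
            tier_elem = t
    if tier_elem is None:
        raise FormatError(f"{path}: no tier named {tier!r}; available tiers: {available}")

    pid = participant_id or tier_elem.get("PARTICIPANT") or path.stem
    records = []
    for i, ann in enumerate(tier_elem.iter("ALIGNABLE_ANNOTATION")):
        ref1, ref2 = ann.get("TIME_SLOT_REF1"), ann.get("TIME_SLOT_REF2")
        if ref1 not in slots or ref2 not in slots:
            raise FormatError(
                f"{path}: annotation {ann.get('ANNOTATION_ID')!r} references "
                "unknown time slots"
            )
        value_elem = ann.find("ANNOTATION_VALUE")
        label = (value_elem.text or "").strip() if value_elem is not None else ""
        records.append(
            dict(
                utterance_id=ann.get("ANNOTATION_ID") or f"{pid}_a{i:04d}",
                participant_id=pid,
                onset_ms=slots[ref1],
                offset_ms=slots[ref2],
                category=label,
            )
        )
    return records


# -- feature table I/O --------------------------------------------------------

FEATURE_TABLE_COLUMNS = [
    "utterance_id",
    "participant_id",
    "dyad_id",
    "articulator",
    "bin_index",
    "magnitude",
    "lateral_position",
    "ap_position",
    "peak_velocity",
    "utterance_duration_ms",
    "category",
    "n_valid_frames",
    "usable",
    "excluded",
]

_FEATURE_TABLE_HEADER = (
    "# conversational-kinematics feature table; one row per "
    "(utterance x articulator x time bin)\n"
    "# units: magnitude mm, lateral_position mm, ap_position SD-scaled proximity "
    "(larger = closer to interlocutor), peak_velocity cm/s, "
    "utterance_duration_ms ms\n"
    "# 'excluded' marks SIMCO/PlanAct rows kept out of the statistical analysis; "
    "'usable' is false when too few valid frames were available\n"
)


def write_feature_table(rows: pd.DataFrame, path: str | Path) -> None:
    """Write the tidy feature table with a unit-documenting header comment."""
    if len(rows) == 0:
        raise ValidationError("refusing to write an empty feature table")
    rows = rows[FEATURE_TABLE_COLUMNS]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_FEATURE_TABLE_HEADER)
        rows.to_csv(fh, index=False, float_format="%.9f")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    table = pd.read_csv(path, comment="#")
    missing = [c for c in FEATURE_TABLE_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: feature table missing columns {missing}")
    return table
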