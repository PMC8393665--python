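"""Windowed kinematic feature extraction.

Each question utterance anchors a 900 ms analysis window running from 300 ms
before to 600 ms after speech onset, cut into three contiguous half-open
300 ms bins. Within each bin, four features are computed per articulator:

- **magnitude** (mm): maximum 3D distance of the tracked point from its
  location at the start of the bin;
- **lateral position** (mm): maximum |x - center| excursion along the lateral
  axis;
- **anterior/posterior position**: the bin's most interlocutor-proximal value
  of the position projected onto the interlocutor axis (meters before
  rescaling; the table stores it rescaled to unit SD per articulator, with
  larger = closer to the interlocutor);
- **peak velocity** (cm/s): maximum frame-to-frame speed (derivative of
  absolute displacement, hence nonnegative).

The two hands are reduced to a single "hands" channel by taking the per-bin
maximum for magnitude, lateral position and peak velocity, and the more
interlocutor-proximal value for anterior/posterior position.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .datamodel import (
    ANALYSIS_ARTICULATORS,
    EXCLUDED_CATEGORIES,
    FEATURE_TABLE_COLUMNS,
    MotionTrack,
    SessionRecording,
    UtteranceAnnotation,
    ValidationError,
)

logger = logging.getLogger("convkin")


@dataclass(frozen=True)
class AnalysisWindow:
    """Onset-anchored analysis window split into contiguous half-open bins."""

    start_rel_ms: float = -300.0
    end_rel_ms: float = 600.0
    bin_width_ms: float = 300.0

    def __post_init__(self) -> None:
        span = self.end_rel_ms - self.start_rel_ms
        if span <= 0 or self.bin_width_ms <= 0:
            raise ValidationError("window span and bin width must be positive")
        n = span / self.bin_width_ms
        if abs(n - round(n)) > 1e-9:
            raise ValidationError(
                f"window span {span} ms is not a whole number of "
                f"{self.bin_width_ms} ms bins"
            )

    @property
    def n_bins(self) -> int:
        return int(round((self.end_rel_ms - self.start_rel_ms) / self.bin_width_ms))


DEFAULT_WINDOW = AnalysisWindow()


@dataclass
class WindowData:
    """An utterance window resampled to a uniform grid, cut into bins.

    ``positions`` is (n_frames, 3) with NaN rows where no valid sample could
    be interpolated; ``frame_times_s`` is the uniform grid in track time.
    """

    positions: np.ndarray
    valid: np.ndarray
    frame_times_s: np.ndarray
    frames_per_bin: int
    n_bins: int
    bin_complete: np.ndarray = field(default=None)  # all-frames-valid per bin

    def __post_init__(self) -> None:
        if self.bin_complete is None:
            self.bin_complete = np.array(
                [bool(np.all(v)) for _, v in self.bins()], dtype=bool
            )

    def bins(self) -> list[tuple[np.ndarray, np.ndarray]]:
        """Per-bin (positions, valid) views, in temporal order."""
        out = []
        for b in range(self.n_bins):
            sl = slice(b * self.frames_per_bin, (b + 1) * self.frames_per_bin)
            out.append((self.positions[sl], self.valid[sl]))
        return out


def extract_window(
    track: MotionTrack,
    onset_ms: float,
    window: AnalysisWindow = DEFAULT_WINDOW,
    rate_hz: float = 30.0,
    *,
    smooth: bool = False,
) -> WindowData:
    """Resample a track to a uniform grid over the utterance window.

    The grid starts at ``onset + start_rel`` and steps at ``1/rate_hz``; with
    the default window and 30 Hz this yields 27 frames, 9 per bin, and the
    half-open bins [onset-300, onset), [onset, onset+300), [onset+300,
    onset+600) ms. Linear interpolation is used between valid samples; grid
    points outside the track span, or bridging a gap longer than twice the
    nominal interval, are flagged invalid. Raises if the window lies entirely
    outside the track.
    """
    if rate_hz <= 0:
        raise ValidationError("rate_hz must be positive")
    frames_per_bin = window.bin_width_ms / 1000.0 * rate_hz
    if abs(frames_per_bin - round(frames_per_bin)) > 1e-9:
        raise ValidationError(
            f"bin width {window.bin_width_ms} ms is not a whole number of frames "
            f"at {rate_hz} Hz"
        )
    frames_per_bin = int(round(frames_per_bin))
    n_frames = frames_per_bin * window.n_bins

    start_s = (onset_ms + window.start_rel_ms) / 1000.0
    grid = start_s + np.arange(n_frames) / rate_hz

    t0, t1 = track.span
    if grid[-1] < t0 or grid[0] > t1:
        raise ValidationError(
            f"window [{grid[0]:.3f}, {grid[-1]:.3f}] s entirely outside track span "
            f"[{t0:.3f}, {t1:.3f}] s"
        )

    mask = track.valid_mask
    times, pos = track.timestamps[mask], track.positions[mask]
    valid = np.zeros(n_frames, dtype=bool)
    out = np.full((n_frames, 3), np.nan)
    if len(times) >= 2:
        inside = (grid >= times[0]) & (grid <= times[-1])
        # invalidate grid points interpolated across a data gap
        idx = np.searchsorted(times, grid, side="right")
        idx = np.clip(idx, 1, len(times) - 1)
        gap = times[idx] - times[idx - 1]
        max_gap = 2.0 / rate_hz
        valid = inside & (gap <= max_gap + 1e-12)
        for ax in range(3):
            out[valid, ax] = np.interp(grid[valid], times, pos[:, ax])
    if smooth and valid.any():
        out = _moving_average3(out)

    return WindowData(
        positions=out,
        valid=valid,
        frame_times_s=grid,
        frames_per_bin=frames_per_bin,
        n_bins=window.n_bins,
    )


def _moving_average3(positions: np.ndarray) -> np.ndarray:
    """Width-3 moving average, NaN-aware, endpoints kept."""
    out = positions.copy()
    stack = np.stack([positions[:-2], positions[1:-1], positions[2:]])
    with np.errstate(invalid="ignore"):
        inner = np.nanmean(stack, axis=0)
    keep = np.all(np.isfinite(positions[1:-1]), axis=1)
    out[1:-1][keep] = inner[keep]
    return out


# -- per-bin feature primitives ----------------------------------------------


def _masked(positions: np.ndarray, valid: np.ndarray | None) -> np.ndarray:
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 3:
        raise ValidationError(f"bin positions must be (n, 3), got {positions.shape}")
    if valid is None:
        valid = np.all(np.isfinite(positions), axis=1)
    return positions[np.asarray(valid, dtype=bool)]


def magnitude(positions: np.ndarray, valid: np.ndarray | None = None) -> float:
    """Max 3D distance (mm) from the bin's first valid frame; NaN if < 2 frames."""
    p = _masked(positions, valid)
    if len(p) < 2:
        return float("nan")
    return float(np.max(np.linalg.norm(p - p[0], axis=1)) * 1000.0)


def lateral_position(
    positions: np.ndarray, center_x: float, valid: np.ndarray | None = None
) -> float:
    """Max |x - center_x| (mm) over the bin's valid frames; NaN if none."""
    p = _masked(positions, valid)
    if len(p) == 0:
        return float("nan")
    return float(np.max(np.abs(p[:, 0] - center_x)) * 1000.0)


def ap_position(
    positions: np.ndarray,
    interlocutor_axis: Sequence[float],
    valid: np.ndarray | None = None,
) -> float:
    """The bin's most interlocutor-proximal projection (meters, pre-scaling).

    Proximity is the dot product of position with the unit interlocutor axis;
    larger values mean the articulator is closer to the interlocutor. Returns
    the bin maximum; NaN if no valid frame.
    """
    axis = np.asarray(interlocutor_axis, dtype=float)
    if abs(np.linalg.norm(axis) - 1.0) > 1e-9:
        raise ValidationError(
            f"interlocutor_axis must be a unit vector (norm {np.linalg.norm(axis):.6f})"
        )
    p = _masked(positions, valid)
    if len(p) == 0:
        return float("nan")
    return float(np.max(p @ axis))


def peak_velocity(
    positions: np.ndarray, rate_hz: float, valid: np.ndarray | None = None
) -> float:
    """Max speed (cm/s) over consecutive valid frame pairs on the uniform grid.

    NaN if fewer than one consecutive valid pair exists. Ties in the argmax
    resolve to the earliest pair (irrelevant for the value itself).
    """
    positions = np.asarray(positions, dtype=float)
    if valid is None:
        valid = np.all(np.isfinite(positions), axis=1)
    valid = np.asarray(valid, dtype=bool)
    if len(positions) < 2:
        return float("nan")
    pair_ok = valid[:-1] & valid[1:]
    if not pair_ok.any():
        return float("nan")
    step = np.linalg.norm(positions[1:] - positions[:-1], axis=1)
    return float(np.max(step[pair_ok]) * rate_hz * 100.0)


def aggregate_hands(left: dict | None, right: dict | None) -> dict | None:
    """Combine the two hands' per-bin features into the "hands" channel.

    Magnitude, lateral position and peak velocity take the max of the two
    hands; anterior/posterior position takes the more proximal value (the
    larger one, under the larger-is-closer convention). A hand whose value is
    NaN is treated as missing; if one hand is entirely missing the other
    carries through with ``hand_missing`` set. Returns None if both missing.
    """
    def _gone(h: dict | None) -> bool:
        return h is None or all(
            not np.isfinite(h[f])
            for f in ("magnitude", "lateral_position", "ap_position", "peak_velocity")
        )

    left_gone, right_gone = _gone(left), _gone(right)
    if left_gone and right_gone:
        return None
    if left_gone or right_gone:
        out = dict(right if left_gone else left)
        out["hand_missing"] = True
        return out
    out = {
        f: float(np.nanmax([left[f], right[f]]))
        for f in ("magnitude", "lateral_position", "ap_position", "peak_velocity")
    }
    out["n_valid_frames"] = max(left["n_valid_frames"], right["n_valid_frames"])
    out["hand_missing"] = False
    return out


def scale_proximity(
    rows: pd.DataFrame, ddof: int = 1, *, center: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Rescale ap_position to unit sample SD within each articulator.

    Mirrors the modeling-stage rescaling of proximity values by their standard
    deviation (raw projections are meters with tiny relative variance, which
    upsets mixed-model convergence). By default the articulator mean — the
    participant's overall distance from the device, which carries no
    utterance-level information and is absorbed by the model intercept — is
    removed first, so the scaled values are unit-SD proximity scores with
    larger = closer. Returns the rescaled table and the per-articulator scale
    factors. Raises if an articulator's proximity SD is zero.
    """
    rows = rows.copy()
    scales: dict[str, float] = {}
    for articulator, block in rows.groupby("articulator", sort=False):
        vals = block["ap_position"].to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if len(finite) < 2:
            raise ValidationError(
                f"articulator {articulator!r}: need >= 2 finite proximity values to rescale"
            )
        sd = float(np.std(finite, ddof=ddof))
        if sd <= 1e-12:
            raise ValidationError(
                f"articulator {articulator!r}: zero proximity SD, cannot rescale"
            )
        mean = float(np.mean(finite)) if center else 0.0
        rows.loc[block.index, "ap_position"] = (vals - mean) / sd
        scales[str(articulator)] = sd
    return rows, scales


# -- table construction -------------------------------------------------------


def _bulk_windows(
    track: MotionTrack,
    onsets_ms: np.ndarray,
    window: AnalysisWindow,
    rate_hz: float,
    smooth: bool,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Resample all utterance windows of one track in one pass.

    Returns (positions (U, n_frames, 3), valid (U, n_frames),
    outside (U,) marking windows entirely outside the track). Numerically
    identical to :func:`extract_window` applied per utterance.
    """
    frames_per_bin = int(round(window.bin_width_ms / 1000.0 * rate_hz))
    n_frames = frames_per_bin * window.n_bins
    rel = window.start_rel_ms / 1000.0 + np.arange(n_frames) / rate_hz
    grids = onsets_ms[:, None] / 1000.0 + rel[None, :]

    t0, t1 = track.span
    outside = (grids[:, -1] < t0) | (grids[:, 0] > t1)

    mask = track.valid_mask
    times, pos = track.timestamps[mask], track.positions[mask]
    out = np.full((len(onsets_ms), n_frames, 3), np.nan)
    valid = np.zeros((len(onsets_ms), n_frames), dtype=bool)
    if len(times) >= 2:
        flat = grids.ravel()
        inside = (flat >= times[0]) & (flat <= times[-1])
        idx = np.clip(np.searchsorted(times, flat, side="right"), 1, len(times) - 1)
        gap = times[idx] - times[idx - 1]
        ok = inside & (gap <= 2.0 / rate_hz + 1e-12)
        interp = np.full((len(flat), 3), np.nan)
        for ax in range(3):
            interp[ok, ax] = np.interp(flat[ok], times, pos[:, ax])
        out = interp.reshape(len(onsets_ms), n_frames, 3)
        valid = ok.reshape(len(onsets_ms), n_frames)
    if smooth:
        for u in range(len(onsets_ms)):
            if valid[u].any():
                out[u] = _moving_average3(out[u])
    return out, valid, outside


def _bulk_features(
    positions: np.ndarray,
    valid: np.ndarray,
    frames_per_bin: int,
    n_bins: int,
    center_x: float | None,
    axis: np.ndarray,
    rate_hz: float,
) -> dict[str, np.ndarray]:
    """Vectorized per-bin features over (U, n_frames, 3) windows.

    Bins containing invalid frames are recomputed through the scalar feature
    functions so the missing-frame policy (origin = first *valid* frame, etc.)
    matches :func:`extract_window` + the per-bin primitives exactly.
    """
    n_utt = positions.shape[0]
    p = positions.reshape(n_utt, n_bins, frames_per_bin, 3)
    v = valid.reshape(n_utt, n_bins, frames_per_bin)
    complete = v.all(axis=2)

    with np.errstate(invalid="ignore"):
        mag = np.max(np.linalg.norm(p - p[:, :, :1, :], axis=3), axis=2) * 1000.0
        if center_x is not None:
            cx = np.full(n_utt, float(center_x))
        else:
            # window-local reference: x at the window's first valid frame
            first = np.argmax(valid, axis=1)
            cx = positions[np.arange(n_utt), first, 0]
        lat = np.max(np.abs(p[..., 0] - cx[:, None, None]), axis=2) * 1000.0
        ap = np.max(p @ axis, axis=2)
        step = np.linalg.norm(np.diff(p, axis=2), axis=3)
        vel = (
            np.max(step, axis=2) * rate_hz * 100.0
            if frames_per_bin >= 2
            else np.full((n_utt, n_bins), np.nan)
        )
    out = dict(
        magnitude=mag,
        lateral_position=lat,
        ap_position=ap,
        peak_velocity=vel,
        n_valid_frames=v.sum(axis=2),
    )
    # scalar fallback for bins with missing frames
    for u, b in zip(*np.nonzero(~complete)):
        bp, bv = p[u, b], v[u, b]
        cxa = cx[u] if np.isfinite(cx[u]) else np.nan
        out["magnitude"][u, b] = magnitude(bp, bv)
        out["lateral_position"][u, b] = (
            lateral_position(bp, cxa, bv) if np.isfinite(cxa) else np.nan
        )
        out["ap_position"][u, b] = ap_position(bp, axis, bv)
        out["peak_velocity"][u, b] = peak_velocity(bp, rate_hz, bv)
    return out


def build_feature_table(
    recordings: Sequence[SessionRecording],
    annotations: Sequence[UtteranceAnnotation],
    window: AnalysisWindow = DEFAULT_WINDOW,
    rate_hz: float = 30.0,
    *,
    articulators: Sequence[str] = ANALYSIS_ARTICULATORS,
    min_valid_frac: float = 0.6,
    smooth: bool = False,
    rescale_proximity: bool = True,
) -> tuple[pd.DataFrame, list[dict]]:
    """Build the tidy feature table: one row per (utterance x articulator x bin).

    SIMCO/PlanAct utterances are extracted but flagged ``excluded``; bins with
    fewer than ``min_valid_frac`` of their expected frames valid are flagged
    not ``usable``. Both events, plus utterances whose window falls outside
    the recording, are itemized in the returned exclusion log. An annotation
    referencing an unknown participant raises.
    """
    by_participant = {r.participant_id: r for r in recordings}
    exclusion_log: list[dict] = []
    if len(annotations) == 0:
        logger.warning("build_feature_table: empty annotation list")
        return pd.DataFrame(columns=FEATURE_TABLE_COLUMNS), exclusion_log
    for ann in annotations:
        if ann.participant_id not in by_participant:
            raise ValidationError(
                f"utterance {ann.utterance_id}: unknown participant "
                f"{ann.participant_id!r}"
            )

    frames_per_bin = int(round(window.bin_width_ms / 1000.0 * rate_hz))
    n_bins = window.n_bins
    frames: list[pd.DataFrame] = []
    # group annotations by participant, keeping each participant's order
    order: dict[str, list[UtteranceAnnotation]] = {}
    for ann in annotations:
        order.setdefault(ann.participant_id, []).append(ann)

    for pid, anns in order.items():
        rec = by_participant[pid]
        onsets = np.array([a.onset_ms for a in anns])
        for articulator in articulators:
            sources = (
                ("hand_left", "hand_right") if articulator == "hands" else (articulator,)
            )
            feats_per_source, outside_any = [], np.zeros(len(anns), dtype=bool)
            for src in sources:
                positions, valid, outside = _bulk_windows(
                    rec.tracks[src], onsets, window, rate_hz, smooth
                )
                outside_any |= outside
                feats_per_source.append(
                    _bulk_features(
                        positions,
                        valid,
                        frames_per_bin,
                        n_bins,
                        rec.calibration_center_x,
                        rec.interlocutor_axis,
                        rate_hz,
                    )
                )
            feats = (
                _aggregate_hands_bulk(*feats_per_source)
                if articulator == "hands"
                else feats_per_source[0]
            )
            frames.append(
                _assemble_rows(
                    anns,
                    rec,
                    articulator,
                    feats,
                    outside_any,
                    n_bins,
                    frames_per_bin,
                    min_valid_frac,
                    exclusion_log,
                )
            )

    table = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()
    table = table.reindex(columns=FEATURE_TABLE_COLUMNS)
    for ann in annotations:  # category exclusions, one record per utterance
        if ann.category in EXCLUDED_CATEGORIES:
            exclusion_log.append(
                dict(
                    utterance_id=ann.utterance_id,
                    articulator="",
                    reason=f"excluded_category:{ann.category.value}",
                )
            )
    scales = {}
    if rescale_proximity and len(table):
        table, scales = scale_proximity(table)
    table.attrs["proximity_scales"] = scales
    return table, exclusion_log


def _aggregate_hands_bulk(left: dict, right: dict) -> dict:
    """Vectorized :func:`aggregate_hands` over (U, n_bins) feature arrays."""
    feature_names = ("magnitude", "lateral_position", "ap_position", "peak_velocity")
    left_gone = np.all([~np.isfinite(left[f]) for f in feature_names], axis=0)
    right_gone = np.all([~np.isfinite(right[f]) for f in feature_names], axis=0)
    out = {}
    for f in feature_names:
        with np.errstate(invalid="ignore"):
            both = np.fmax(left[f], right[f])  # NaN-ignoring max; proximal = larger
        vals = np.where(left_gone, right[f], np.where(right_gone, left[f], both))
        vals = np.where(left_gone & right_gone, np.nan, vals)
        out[f] = vals
    out["n_valid_frames"] = np.maximum(left["n_valid_frames"], right["n_valid_frames"])
    return out


def _assemble_rows(
    anns: Sequence[UtteranceAnnotation],
    rec: SessionRecording,
    articulator: str,
    feats: dict,
    outside: np.ndarray,
    n_bins: int,
    frames_per_bin: int,
    min_valid_frac: float,
    exclusion_log: list[dict],
) -> pd.DataFrame:
    keep = ~outside
    for ann in np.asarray(anns, dtype=object)[outside]:
        exclusion_log.append(
            dict(
                utterance_id=ann.utterance_id,
                articulator=articulator,
                reason="window_outside_recording",
            )
        )
    anns_kept = [a for a, k in zip(anns, keep) if k]
    n = len(anns_kept)
    usable = feats["n_valid_frames"][keep] >= min_valid_frac * frames_per_bin
    for u, b in zip(*np.nonzero(~usable)):
        exclusion_log.append(
            dict(
                utterance_id=anns_kept[u].utterance_id,
                articulator=articulator,
                reason=f"insufficient_valid_frames:bin{b}",
            )
        )
    return pd.DataFrame(
        {
            "utterance_id": np.repeat([a.utterance_id for a in anns_kept], n_bins),
            "participant_id": np.repeat([a.participant_id for a in anns_kept], n_bins),
            "dyad_id": rec.dyad_id,
            "articulator": articulator,
            "bin_index": np.tile(np.arange(n_bins), n),
            "magnitude": feats["magnitude"][keep].ravel(),
            "lateral_position": feats["lateral_position"][keep].ravel(),
            "ap_position": feats["ap_position"][keep].ravel(),
            "peak_velocity": feats["peak_velocity"][keep].ravel(),
            "utterance_duration_ms": np.repeat(
                [a.duration_ms for a in anns_kept], n_bins
            ),
            "category": np.repeat([a.category.value for a in anns_kept], n_bins),
            "n_valid_frames": feats["n_valid_frames"][keep].ravel(),
            "usable": usable.ravel(),
            "excluded": np.repeat(
                [a.category in EXCLUDED_CATEGORIES for a in anns_kept], n_bins
            ),
        }
    )
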