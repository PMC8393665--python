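"""Synthetic dyadic motion-capture corpus generator.

Emulates the statistical structure the downstream analysis assumes: dyads of
two participants recorded at ~30 Hz in a device frame, with baseline postural
jitter on every articulator, smooth bell-shaped movement bursts around each
question utterance, right-skewed (log-normal) utterance durations, and eight
social action categories at configurable frequencies. Category effects on the
burst parameters (amplitude, peak speed, lateral offset, interlocutor-directed
offset) can be injected per (category, articulator, feature), on top of
per-participant and per-dyad random offsets — so every downstream stage can be
tested against known ground truth without any real recordings.

What this generator does **not** emulate (see docs/methods.md): tracking
drop-outs and occlusions, clock drift, utterance-to-utterance variation in
movement amplitude beyond burst timing, gesture form, or interpersonal
synchrony dynamics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.stats import norm

from .datamodel import (
    ANALYSIS_ARTICULATORS,
    CATEGORY_LABELS,
    FEATURES,
    MotionTrack,
    REFERENCE_CATEGORY_COUNTS,
    SessionRecording,
    UtteranceAnnotation,
    ValidationError,
)

_Z75 = norm.ppf(0.75)

#: Resting articulator positions (m, device frame: x lateral, y vertical,
#: z depth from the sensor). Seated participant roughly 2.1 m from the device.
REST_POSITIONS: dict[str, np.ndarray] = {
    "torso": np.array([0.00, 0.60, 2.10]),
    "head": np.array([0.00, 0.95, 2.15]),
    "hand_left": np.array([-0.20, 0.35, 2.00]),
    "hand_right": np.array([0.20, 0.35, 2.00]),
}

#: Baseline burst parameters per analysis articulator (mm). Chosen for a
#: seated conversation: subtle postural shifts of torso and head, clearly
#: larger free-hand movements.
BURST_BASELINES: dict[str, dict[str, float]] = {
    "torso": dict(amplitude_mm=6.0, lateral_mm=2.0, proximal_mm=2.0),
    "head": dict(amplitude_mm=10.0, lateral_mm=3.0, proximal_mm=3.0),
    "hands": dict(amplitude_mm=35.0, lateral_mm=8.0, proximal_mm=8.0),
}

_INTERLOCUTOR_AXIS = np.array([0.0, 0.0, -1.0])  # toward the interlocutor


def default_category_weights() -> dict[str, float]:
    """Category probabilities proportional to the reference corpus counts."""
    total = sum(REFERENCE_CATEGORY_COUNTS.values())
    return {k: v / total for k, v in REFERENCE_CATEGORY_COUNTS.items()}


def _as_feature_sd(value) -> dict[str, float]:
    if isinstance(value, Mapping):
        unknown = set(value) - set(FEATURES)
        if unknown:
            raise ValidationError(f"unknown features in random-effect SDs: {sorted(unknown)}")
        return {f: float(value.get(f, 0.0)) for f in FEATURES}
    return {f: float(value) for f in FEATURES}


@dataclass
class GeneratorConfig:
    """Study conditions for one synthetic corpus.

    ``effect_table`` maps ``(category, articulator, feature)`` to an additive
    shift of the burst parameter driving that feature, in the feature's
    reporting units (mm for magnitude / lateral_position / ap_position burst
    offsets, cm/s for peak_velocity). ``participant_sd`` / ``dyad_sd`` give
    per-feature random-intercept SDs in the same units (a scalar broadcasts).
    """

    n_dyads: int = 20
    utterances_per_participant: int = 60
    category_weights: dict[str, float] = field(default_factory=default_category_weights)
    duration_median_ms: float = 1114.0
    duration_iqr_ms: float = 1138.0
    duration_min_ms: float = 99.0
    duration_max_ms: float = 13145.0
    sample_rate_hz: float = 30.0
    baseline_noise_sd_mm: float = 2.0
    effect_table: dict[tuple[str, str, str], float] = field(default_factory=dict)
    participant_sd: dict[str, float] | float = field(
        default_factory=lambda: dict(
            magnitude=1.5, lateral_position=1.0, ap_position=1.0, peak_velocity=1.0
        )
    )
    dyad_sd: dict[str, float] | float = field(
        default_factory=lambda: dict(
            magnitude=0.8, lateral_position=0.5, ap_position=0.5, peak_velocity=0.5
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.participant_sd = _as_feature_sd(self.participant_sd)
        self.dyad_sd = _as_feature_sd(self.dyad_sd)
        self.validate()

    def validate(self) -> None:
        if self.n_dyads < 1 or self.utterances_per_participant < 1:
            raise ValidationError("n_dyads and utterances_per_participant must be >= 1")
        if abs(sum(self.category_weights.values()) - 1.0) > 1e-9:
            raise ValidationError("category_weights must sum to 1 (within 1e-9)")
        unknown = set(self.category_weights) - set(CATEGORY_LABELS)
        if unknown:
            raise ValidationError(f"unknown categories in weights: {sorted(unknown)}")
        if any(w < 0 for w in self.category_weights.values()):
            raise ValidationError("category_weights must be nonnegative")
        if not (self.duration_min_ms < self.duration_median_ms < self.duration_max_ms):
            raise ValidationError(
                "need duration_min_ms < duration_median_ms < duration_max_ms"
            )
        if self.duration_iqr_ms < 0:
            raise ValidationError("duration_iqr_ms must be >= 0")
        if self.sample_rate_hz <= 0:
            raise ValidationError("sample_rate_hz must be positive")
        if self.baseline_noise_sd_mm < 0:
            raise ValidationError("baseline_noise_sd_mm must be >= 0")
        if any(v < 0 for v in self.participant_sd.values()) or any(
            v < 0 for v in self.dyad_sd.values()
        ):
            raise ValidationError("random-effect SDs must be >= 0")
        for cat, art, feat in self.effect_table:
            if cat not in CATEGORY_LABELS:
                raise ValidationError(f"effect_table: unknown category {cat!r}")
            if art not in ANALYSIS_ARTICULATORS:
                raise ValidationError(f"effect_table: unknown articulator {art!r}")
            if feat not in FEATURES:
                raise ValidationError(f"effect_table: unknown feature {feat!r}")

    @property
    def duration_sigma(self) -> float:
        """Log-normal shape solved so the quartile spread matches the IQR.

        With median m, the log-normal IQR is m*(e^(z75*s) - e^(-z75*s));
        setting r = IQR/m gives e^(z75*s) = (r + sqrt(r^2 + 4))/2 in closed
        form.
        """
        r = self.duration_iqr_ms / self.duration_median_ms
        if r == 0:
            return 0.0
        return math.log((r + math.sqrt(r * r + 4.0)) / 2.0) / _Z75


@dataclass
class SyntheticCorpus:
    """Generated recordings, annotations, and the ground truth behind them."""

    recordings: list[SessionRecording]
    annotations: list[UtteranceAnnotation]
    truth: dict
    config: GeneratorConfig


def sample_utterance_duration(
    config: GeneratorConfig, rng: np.random.Generator, size: int | None = None
):
    """Draw utterance durations (ms) from the configured log-normal.

    The distribution's median equals ``duration_median_ms`` and its IQR
    approximates ``duration_iqr_ms``; draws are clamped to
    [duration_min_ms, duration_max_ms]. With zero IQR every draw equals the
    median.
    """
    sigma = config.duration_sigma
    n = 1 if size is None else size
    draws = config.duration_median_ms * np.exp(sigma * rng.standard_normal(n))
    draws = np.clip(draws, config.duration_min_ms, config.duration_max_ms)
    return float(draws[0]) if size is None else draws


def _effect(config: GeneratorConfig, cat: str, art: str, feat: str) -> float:
    return config.effect_table.get((cat, art, feat), 0.0)


def generate_corpus(config: GeneratorConfig) -> SyntheticCorpus:
    """Generate a full synthetic corpus, deterministically given the seed.

    Each utterance produces one movement burst per analysis articulator (for
    the hands: on one randomly chosen hand). A burst is a Gaussian-profile
    displacement ``g(t) * D`` with nominal duration ~ U(300, 900) ms and
    center uniform in [onset - 200, onset + 400] ms, so the 900 ms analysis
    window captures it at varying phases. The displacement vector D combines
    a main component (amplitude), a lateral away-from-center component, and
    an interlocutor-directed component; its peak speed is steered by
    narrowing or widening the profile. All four burst parameters are the
    articulator baselines shifted by the category's injected effects plus the
    participant and dyad random offsets — per-utterance randomness enters
    only through burst timing, hand choice, and frame noise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    rate = config.sample_rate_hz
    labels = list(config.category_weights)
    weights = np.array([config.category_weights[c] for c in labels])

    recordings: list[SessionRecording] = []
    annotations: list[UtteranceAnnotation] = []
    participant_offsets: dict[str, dict] = {}
    dyad_offsets: dict[str, dict] = {}

    for d in range(config.n_dyads):
        dyad_id = f"d{d:03d}"
        d_off = {
            art: {f: rng.normal(0.0, config.dyad_sd[f]) for f in FEATURES}
            for art in ANALYSIS_ARTICULATORS
        }
        dyad_offsets[dyad_id] = d_off
        for side in ("A", "B"):
            pid = f"{dyad_id}_p{side}"
            p_off = {
                art: {f: rng.normal(0.0, config.participant_sd[f]) for f in FEATURES}
                for art in ANALYSIS_ARTICULATORS
            }
            participant_offsets[pid] = p_off

            n_utt = config.utterances_per_participant
            durations = sample_utterance_duration(config, rng, size=n_utt)
            categories = rng.choice(labels, size=n_utt, p=weights)
            onsets = np.empty(n_utt)
            t = 0.5 + rng.uniform(0.0, 0.5)
            for i in range(n_utt):
                onsets[i] = t
                t += max(durations[i] / 1000.0, 0.9) + rng.uniform(0.6, 1.4)

            # burst parameter tables, one burst per utterance per articulator
            bursts: dict[str, list[dict]] = {a: [] for a in ANALYSIS_ARTICULATORS}
            hand_choice = rng.random(n_utt) < 0.5  # True -> right hand
            for i in range(n_utt):
                cat = str(categories[i])
                for art in ANALYSIS_ARTICULATORS:
                    eff = {f: _effect(config, cat, art, f) for f in FEATURES}
                    base = BURST_BASELINES[art]
                    amp_mm = max(
                        base["amplitude_mm"]
                        + eff["magnitude"]
                        + p_off[art]["magnitude"]
                        + d_off[art]["magnitude"],
                        0.5,
                    )
                    lat_mm = max(
                        base["lateral_mm"]
                        + eff["lateral_position"]
                        + p_off[art]["lateral_position"]
                        + d_off[art]["lateral_position"],
                        0.0,
                    )
                    prox_mm = (
                        base["proximal_mm"]
                        + eff["ap_position"]
                        + p_off[art]["ap_position"]
                        + d_off[art]["ap_position"]
                    )
                    dv_cms = (
                        eff["peak_velocity"]
                        + p_off[art]["peak_velocity"]
                        + d_off[art]["peak_velocity"]
                    )
                    theta = rng.uniform(0.0, 2.0 * math.pi)
                    u0 = np.array([math.cos(theta), math.sin(theta), 0.0])
                    dur_s = rng.uniform(0.3, 0.9)
                    center_s = onsets[i] + rng.uniform(-0.2, 0.4)
                    if art == "hands":
                        target = "hand_right" if hand_choice[i] else "hand_left"
                    else:
                        target = art
                    lat_sign = (
                        math.copysign(1.0, REST_POSITIONS[target][0])
                        if REST_POSITIONS[target][0] != 0.0
                        else (1.0 if rng.random() < 0.5 else -1.0)
                    )
                    D = (
                        (amp_mm / 1000.0) * u0
                        + (lat_mm / 1000.0) * lat_sign * np.array([1.0, 0.0, 0.0])
                        + (prox_mm / 1000.0) * _INTERLOCUTOR_AXIS
                    )
                    # Gaussian profile peak speed = |D| * e^-0.5 / s; widen or
                    # narrow the profile to hit the velocity target.
                    s0 = dur_s / 6.0
                    v0 = np.linalg.norm(D) * math.exp(-0.5) / s0
                    v_target = max(v0 + dv_cms / 100.0, 0.02)
                    s = float(
                        np.clip(np.linalg.norm(D) * math.exp(-0.5) / v_target, 0.03, 0.30)
                    )
                    bursts[art].append(
                        dict(target=target, center_s=center_s, s=s, D=D)
                    )

            end_s = float(onsets[-1] + max(durations[-1] / 1000.0, 0.9)) + 1.5
            n_frames = int(math.ceil(end_s * rate)) + 1
            times = np.arange(n_frames) / rate

            tracks: dict[str, MotionTrack] = {}
            noise_sd_m = config.baseline_noise_sd_mm / 1000.0
            for articulator, rest in REST_POSITIONS.items():
                pos = rest + rng.normal(0.0, noise_sd_m, size=(n_frames, 3))
                tracks[articulator] = MotionTrack(articulator, times.copy(), pos)
            for art in ANALYSIS_ARTICULATORS:
                for burst in bursts[art]:
                    pos = tracks[burst["target"]].positions
                    c, s, D = burst["center_s"], burst["s"], burst["D"]
                    lo = max(int((c - 4 * s) * rate) - 1, 0)
                    hi = min(int((c + 4 * s) * rate) + 2, n_frames)
                    g = np.exp(-0.5 * ((times[lo:hi] - c) / s) ** 2)
                    pos[lo:hi] += g[:, None] * D

            recordings.append(
                SessionRecording(
                    dyad_id=dyad_id,
                    participant_id=pid,
                    tracks=tracks,
                    interlocutor_axis=_INTERLOCUTOR_AXIS.copy(),
                    calibration_center_x=0.0,
                )
            )
            for i in range(n_utt):
                annotations.append(
                    UtteranceAnnotation(
                        utterance_id=f"{pid}_u{i:04d}",
                        participant_id=pid,
                        onset_ms=float(onsets[i] * 1000.0),
                        offset_ms=float(onsets[i] * 1000.0 + durations[i]),
                        category=str(categories[i]),
                    )
                )

    truth = dict(
        effect_table=dict(config.effect_table),
        participant_offsets=participant_offsets,
        dyad_offsets=dyad_offsets,
    )
    return SyntheticCorpus(
        recordings=recordings, annotations=annotations, truth=truth, config=config
    )
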