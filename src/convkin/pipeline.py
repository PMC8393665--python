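"""End-to-end orchestration: simulate -> (sync) -> extract -> analyze -> report.

A run is configured by a YAML file (unknown keys rejected), seeded, and writes
a run directory containing the config snapshot, a log, the feature table, the
model-comparison and contrast tables, the exclusion log, and a markdown
report. Reruns with the same config and seed produce identical result files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import pandas as pd
import yaml

from . import corpus as corpus_mod
from . import sync as sync_mod
from .datamodel import (
    ANALYSIS_ARTICULATORS,
    SessionRecording,
    StageError,
    ValidationError,
    read_annotations,
    read_motion_table,
    write_feature_table,
)
from .features import AnalysisWindow, build_feature_table
from .stats import AnalysisResults, contrasts_frame, run_full_analysis

logger = logging.getLogger("convkin")


@dataclass
class PathsConfig:
    motion_dir: str | None = None
    annotations: str | None = None
    audio_a: str | None = None
    audio_b: str | None = None


@dataclass
class AnalysisConfig:
    alpha: float = 0.05
    smooth: bool = False
    min_valid_frac: float = 0.6
    articulators: tuple[str, ...] = tuple(ANALYSIS_ARTICULATORS)


@dataclass
class PipelineConfig:
    """Full pipeline configuration; defaults reproduce the standard
    -300/+600 ms window in three 300 ms bins at 30 Hz."""

    seed: int = 0
    log_level: str = "INFO"
    output_dir: str = "runs/run"
    rate_hz: float = 30.0
    max_lag_s: float = 5.0
    window: AnalysisWindow = field(default_factory=AnalysisWindow)
    generator: corpus_mod.GeneratorConfig = field(
        default_factory=corpus_mod.GeneratorConfig
    )
    paths: PathsConfig = field(default_factory=PathsConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw or {})
        kwargs = {}
        top_fields = {f.name for f in fields(cls)}
        unknown = set(raw) - top_fields
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for name, sub_cls in (
            ("window", AnalysisWindow),
            ("paths", PathsConfig),
            ("analysis", AnalysisConfig),
            ("generator", corpus_mod.GeneratorConfig),
        ):
            if name in raw:
                section = dict(raw.pop(name) or {})
                allowed = {f.name for f in fields(sub_cls)}
                bad = set(section) - allowed
                if bad:
                    raise ValidationError(
                        f"unknown keys in config section {name!r}: {sorted(bad)}"
                    )
                if name == "generator" and "effect_table" in section:
                    section["effect_table"] = _parse_effect_table(
                        section["effect_table"]
                    )
                if name == "analysis" and "articulators" in section:
                    section["articulators"] = tuple(section["articulators"])
                kwargs[name] = sub_cls(**section)
        kwargs.update(raw)
        config = cls(**kwargs)
        # a single seed drives the whole run
        config.generator.seed = int(config.seed)
        return config

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["generator"]["effect_table"] = [
            dict(category=c, articulator=a, feature=f, effect=v)
            for (c, a, f), v in self.generator.effect_table.items()
        ]
        out["analysis"]["articulators"] = list(self.analysis.articulators)
        return out


def _parse_effect_table(entries) -> dict[tuple[str, str, str], float]:
    if isinstance(entries, dict):
        return dict(entries)
    table = {}
    for e in entries or []:
        table[(e["category"], e["articulator"], e["feature"])] = float(e["effect"])
    return table


def run_pipeline(config: PipelineConfig, mode: str = "simulate") -> Path:
    """Execute the pipeline and return the run directory.

    ``mode="simulate"`` generates the corpus from ``config.generator``;
    ``mode="real"`` reads motion tables and annotations from
    ``config.paths`` (applying the audio-estimated offset when both audio
    paths are set). A stage failure raises :class:`StageError` with partial
    artifacts preserved in the run directory.
    """
    if mode not in ("simulate", "real"):
        raise ValidationError(f"unknown pipeline mode {mode!r}")
    run_dir = Path(config.output_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    _setup_run_logging(run_dir, config.log_level)
    with open(run_dir / "config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
    logger.info(
        "run start: mode=%s seed=%d window=[%+.0f, %+.0f) ms in %d bins of %.0f ms",
        mode,
        config.seed,
        config.window.start_rel_ms,
        config.window.end_rel_ms,
        config.window.n_bins,
        config.window.bin_width_ms,
    )

    # -- acquire stage
    try:
        if mode == "simulate":
            synthetic = corpus_mod.generate_corpus(config.generator)
            recordings, annotations = synthetic.recordings, synthetic.annotations
        else:
            recordings, annotations = _load_real(config)
    except ValidationError:
        raise
    except Exception as exc:
        raise StageError("acquire", str(exc)) from exc
    logger.info(
        "acquired %d recordings, %d annotations", len(recordings), len(annotations)
    )

    # -- extract stage
    try:
        table, exclusions = build_feature_table(
            recordings,
            annotations,
            window=config.window,
            rate_hz=config.rate_hz,
            articulators=config.analysis.articulators,
            min_valid_frac=config.analysis.min_valid_frac,
            smooth=config.analysis.smooth,
        )
        if len(table):
            write_feature_table(table, run_dir / "features.csv")
        pd.DataFrame(
            exclusions, columns=["utterance_id", "articulator", "reason"]
        ).to_csv(run_dir / "exclusions.csv", index=False)
    except Exception as exc:
        raise StageError("extract", str(exc)) from exc
    logger.info("extracted %d feature rows (%d exclusion records)", len(table), len(exclusions))

    # -- analyze stage
    try:
        results = run_full_analysis(table, alpha=config.analysis.alpha)
        results.comparisons.to_csv(run_dir / "comparisons.csv", index=False)
        all_contrasts = []
        for (articulator, feature), contrast_list in results.contrasts.items():
            frame = contrasts_frame(contrast_list)
            frame.insert(0, "feature", feature)
            frame.insert(0, "articulator", articulator)
            all_contrasts.append(frame)
        contrast_frame = (
            pd.concat(all_contrasts, ignore_index=True)
            if all_contrasts
            else pd.DataFrame(
                columns=[
                    "articulator",
                    "feature",
                    "category_a",
                    "category_b",
                    "estimate",
                    "se",
                    "z_ratio",
                    "p_unadjusted",
                    "p_adjusted",
                    "significant",
                ]
            )
        )
        contrast_frame.to_csv(run_dir / "contrasts.csv", index=False)
        pd.DataFrame(results.ladder_log).to_csv(run_dir / "ladder_log.csv", index=False)
    except Exception as exc:
        raise StageError("analyze", str(exc)) from exc
    logger.info("analysis grid: %d comparisons", len(results.comparisons))

    # -- report stage
    try:
        report = make_report(results, window=config.window, seed=config.seed)
        (run_dir / "report.md").write_text(report, encoding="utf-8")
    except Exception as exc:
        raise StageError("report", str(exc)) from exc
    logger.info("run complete: %s", run_dir)
    return run_dir


def _load_real(
    config: PipelineConfig,
) -> tuple[list[SessionRecording], list]:
    paths = config.paths
    if not paths.motion_dir or not paths.annotations:
        raise ValidationError("mode='real' requires paths.motion_dir and paths.annotations")
    recordings = []
    for file in sorted(Path(paths.motion_dir).glob("*.csv")):
        stem = file.stem
        dyad_id = stem.split("_p")[0] if "_p" in stem else stem
        recordings.append(
            read_motion_table(
                file,
                dyad_id=dyad_id,
                participant_id=stem,
                nominal_rate_hz=config.rate_hz,
            )
        )
    if not recordings:
        raise ValidationError(f"no motion tables found in {paths.motion_dir}")
    annotations = read_annotations(paths.annotations)
    if paths.audio_a and paths.audio_b:
        rate_a, a = sync_mod.read_wav(paths.audio_a)
        rate_b, b = sync_mod.read_wav(paths.audio_b)
        offset = sync_mod.estimate_offset(
            a, b, rate_a, config.max_lag_s, rate_hz_b=rate_b
        )
        logger.info(
            "audio offset: %.4f s (peak correlation %.3f, confident=%s)",
            offset.offset_s,
            offset.peak_correlation,
            offset.confident,
        )
        recordings = [sync_mod.apply_offset(r, offset) for r in recordings]
    return recordings, annotations


def _setup_run_logging(run_dir: Path, level: str) -> None:
    logger.setLevel(getattr(logging, level.upper(), logging.INFO))
    for handler in list(logger.handlers):
        if getattr(handler, "_convkin_run", False):
            logger.removeHandler(handler)
            handler.close()
    handler = logging.FileHandler(run_dir / "run.log", mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    handler._convkin_run = True
    logger.addHandler(handler)


# -- reporting ---------------------------------------------------------------


def make_report(
    results: AnalysisResults, window: AnalysisWindow | None = None, seed: int | None = None
) -> str:
    """Render the analysis results as a markdown report.

    One omnibus table row per articulator x feature; pairwise contrast tables
    only for comparisons significant at ``results.alpha``. Empty results give
    a stub report with a warning.
    """
    lines = ["# Conversational kinematics by social action category", ""]
    if window is not None:
        lines.append(
            f"Analysis window: [{window.start_rel_ms:+.0f}, {window.end_rel_ms:+.0f}) ms "
            f"around utterance onset, {window.n_bins} bins of {window.bin_width_ms:.0f} ms."
        )
    if seed is not None:
        lines.append(f"Seed: {seed}.")
    lines.append("")
    comparisons = results.comparisons
    if comparisons is None or len(comparisons) == 0:
        lines.append("**Warning: no analysis results available (empty input).**")
        return "\n".join(lines) + "\n"

    n_sig = int(
        ((comparisons["p_value"] < results.alpha) & comparisons["converged"]).sum()
    )
    n_total = len(comparisons)
    lines.append(
        f"{n_sig} of {n_total} omnibus comparisons significant at "
        f"alpha = {results.alpha:g}; under a global null, about "
        f"{results.alpha * n_total:.1f} would be expected by chance."
    )
    lines.append("")
    for articulator, block in comparisons.groupby("articulator", sort=False):
        lines.append(f"## {articulator}")
        lines.append("")
        lines.append(
            "| feature | chi2 | df | p | random structure | slope | converged |"
        )
        lines.append("|---|---|---|---|---|---|---|")
        for row in block.itertuples():
            lines.append(
                f"| {row.feature} | {row.chi2:.3f} | {row.df} | {row.p_value:.4g} "
                f"| {row.random_structure_used} | "
                f"{'yes' if row.slope_retained else 'no'} | "
                f"{'yes' if row.converged else 'no'} |"
            )
        lines.append("")
        for (art, feature), contrast_list in results.contrasts.items():
            if art != articulator:
                continue
            sig = [c for c in contrast_list if c.significant]
            lines.append(
                f"### {feature}: pairwise contrasts "
                f"({len(sig)} of {len(contrast_list)} significant)"
            )
            lines.append("")
            lines.append("| contrast | estimate | SE | z | p (Tukey) |")
            lines.append("|---|---|---|---|---|")
            for c in sorted(contrast_list, key=lambda c: abs(c.z_ratio), reverse=True):
                marker = " *" if c.significant else ""
                lines.append(
                    f"| {c.category_a} - {c.category_b}{marker} | {c.estimate:.4f} "
                    f"| {c.se:.4f} | {c.z_ratio:.3f} | {c.p_adjusted:.4g} |"
                )
            lines.append("")
    return "\n".join(lines) + "\n"
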