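"""Mixed-model LRT machinery: recovery, ladder, contrasts, calibration."""

import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import convkin as ck
from convkin.datamodel import ANALYZED_LABELS
from convkin.stats import (
    ModelSpec,
    compare_models,
    fit_model,
    lrt_cell,
    marginal_means,
    posthoc_contrasts,
    prepare_rows,
    random_structure_ladder,
    run_full_analysis,
)


def simulate_table(
    n_dyads=10,
    utterances_per_participant=25,
    category_effects=None,
    participant_sd=1.0,
    dyad_sd=0.5,
    slope_sd=0.0,
    noise_sd=2.0,
    seed=0,
    one_participant_per_dyad=False,
):
    """Feature-table-shaped data simulated directly at the row level.

    Gives exact control over the generating fixed and random effects,
    independent of the motion-burst generator.
    """
    rng = np.random.default_rng(seed)
    category_effects = category_effects or {}
    rows = []
    for d in range(n_dyads):
        dyad_id = f"d{d:02d}"
        dyad_re = rng.normal(0, dyad_sd)
        sides = ("A",) if one_participant_per_dyad else ("A", "B")
        for side in sides:
            pid = f"{dyad_id}_p{side}"
            part_re = rng.normal(0, participant_sd)
            slope_re = {c: rng.normal(0, slope_sd) for c in ANALYZED_LABELS}
            for u in range(utterances_per_participant):
                category = ANALYZED_LABELS[int(rng.integers(len(ANALYZED_LABELS)))]
                duration = float(rng.lognormal(np.log(1100), 0.7))
                base = (
                    10.0
                    + category_effects.get(category, 0.0)
                    + dyad_re
                    + part_re
                    + slope_re[category]
                )
                for b in range(3):
                    rows.append(
                        dict(
                            utterance_id=f"{pid}_u{u:03d}",
                            participant_id=pid,
                            dyad_id=dyad_id,
                            articulator="torso",
                            bin_index=b,
                            magnitude=base + rng.normal(0, noise_sd),
                            lateral_position=np.nan,
                            ap_position=np.nan,
                            peak_velocity=np.nan,
                            utterance_duration_ms=duration,
                            category=category,
                            n_valid_frames=9,
                            usable=True,
                            excluded=False,
                        )
                    )
    return pd.DataFrame(rows)


def test_known_fixed_effect_recovered_within_three_se():
    """A +1.0 category effect at ~5000 rows is recovered within 3 SE."""
    table = simulate_table(
        n_dyads=17,
        utterances_per_participant=50,
        category_effects={"UndCheck": 1.0},
        seed=5,
    )
    rows = prepare_rows(table, "magnitude")
    assert len(rows) >= 5000
    fit = fit_model(rows, ModelSpec("magnitude", True, "participant", False))
    assert fit.converged and np.isfinite(fit.llf)
    contrasts = posthoc_contrasts(fit)
    target = next(
        c
        for c in contrasts
        if {c.category_a, c.category_b} == {"UndCheck", "InfReq"}
    )
    sign = 1.0 if target.category_a == "UndCheck" else -1.0
    assert abs(sign * target.estimate - 1.0) < 3 * target.se


def test_adding_a_predictor_never_lowers_the_likelihood():
    table = simulate_table(n_dyads=6, utterances_per_participant=10, seed=8)
    rows = prepare_rows(table, "magnitude")
    null = fit_model(rows, ModelSpec("magnitude", False, "participant", False))
    interest = fit_model(rows, ModelSpec("magnitude", True, "participant", False))
    assert interest.llf >= null.llf - 1e-6


def test_identical_models_compare_to_zero():
    table = simulate_table(n_dyads=4, utterances_per_participant=8, seed=2)
    rows = prepare_rows(table, "magnitude")
    fit = fit_model(rows, ModelSpec("magnitude", True, "participant", False))
    comparison = compare_models(fit, fit)
    assert comparison.chi2 == 0.0 and comparison.p_value == 1.0 and comparison.df == 0


def test_six_level_predictor_gives_df_five():
    table = simulate_table(n_dyads=6, utterances_per_participant=12, seed=3)
    comparison, fit, _ = lrt_cell(prepare_rows(table, "magnitude"), "magnitude")
    assert comparison.df == 5
    assert 0.0 <= comparison.p_value <= 1.0
    assert comparison.chi2 >= 0.0


def test_mismatched_structures_refused():
    table = simulate_table(n_dyads=4, utterances_per_participant=8, seed=2)
    rows = prepare_rows(table, "magnitude")
    a = fit_model(rows, ModelSpec("magnitude", False, "participant", False))
    b = fit_model(rows, ModelSpec("magnitude", True, "dyad_nested", False))
    with pytest.raises(ck.ValidationError, match="random structures"):
        compare_models(a, b)


def test_ladder_retains_top_rung_on_slope_rich_data():
    """With real per-participant category slopes and dyad variance, the full
    nested + slope structure converges non-singular and is kept."""
    table = simulate_table(
        n_dyads=16,
        utterances_per_participant=30,
        participant_sd=1.2,
        dyad_sd=2.0,
        slope_sd=1.5,
        seed=11,
    )
    fit, rung, log = random_structure_ladder(prepare_rows(table, "magnitude"), "magnitude")
    assert fit is not None
    assert rung == 0
    assert fit.spec.random_structure == "dyad_nested" and fit.spec.random_slope


def test_ladder_skips_nesting_without_two_participants_per_dyad():
    table = simulate_table(
        n_dyads=10,
        utterances_per_participant=20,
        one_participant_per_dyad=True,
        seed=4,
    )
    fit, rung, log = random_structure_ladder(prepare_rows(table, "magnitude"), "magnitude")
    assert fit is not None
    assert fit.spec.random_structure == "participant"
    assert all(
        entry["outcome"] == "skipped"
        for entry in log
        if entry["structure"] == "dyad_nested"
    )


def test_null_and_interest_share_the_ladder_rung():
    table = simulate_table(n_dyads=6, utterances_per_participant=12, seed=6)
    rows = prepare_rows(table, "magnitude")
    comparison, fit, _ = lrt_cell(rows, "magnitude")
    assert comparison.random_structure_used == fit.spec.random_structure
    assert comparison.slope_retained == fit.spec.random_slope


def test_posthoc_contrast_family():
    """15 contrasts; Tukey p never below the unadjusted p; estimates agree
    with marginal-mean differences and are antisymmetric."""
    table = simulate_table(
        n_dyads=8,
        utterances_per_participant=15,
        category_effects={"StanSem": 1.5},
        seed=9,
    )
    rows = prepare_rows(table, "magnitude")
    fit = fit_model(rows, ModelSpec("magnitude", True, "participant", False))
    contrasts = posthoc_contrasts(fit)
    assert len(contrasts) == 15
    means = marginal_means(fit)
    seen = set()
    for c in contrasts:
        assert c.p_adjusted >= c.p_unadjusted - 1e-12
        assert c.estimate == pytest.approx(
            means[c.category_a] - means[c.category_b], abs=1e-8
        )
        seen.add(frozenset((c.category_a, c.category_b)))
    assert len(seen) == 15  # all unordered pairs of the six categories


def test_torso_only_table_yields_four_comparisons(small_table):
    torso = small_table[small_table.articulator == "torso"]
    results = run_full_analysis(torso)
    assert len(results.comparisons) == 4
    assert set(results.comparisons["articulator"]) == {"torso"}


def test_power_increases_with_injected_effect():
    """Mean LRT statistic grows monotonically across 0.25/0.5/1.0 SD
    injected torso-magnitude effects at fixed corpus size."""
    pilot = ck.generate_corpus(
        ck.GeneratorConfig(n_dyads=6, utterances_per_participant=25, seed=55)
    )
    pilot_table, _ = ck.build_feature_table(
        pilot.recordings, pilot.annotations, articulators=("torso",)
    )
    sd = float(prepare_rows(pilot_table, "magnitude")["magnitude"].std(ddof=1))
    mean_chi2 = []
    for multiplier in (0.25, 0.5, 1.0):
        stats = []
        for seed in range(4):
            config = ck.GeneratorConfig(
                n_dyads=6,
                utterances_per_participant=25,
                effect_table={("StanSem", "torso", "magnitude"): multiplier * sd},
                seed=600 + seed,
            )
            corpus = ck.generate_corpus(config)
            table, _ = ck.build_feature_table(
                corpus.recordings, corpus.annotations, articulators=("torso",)
            )
            comparison, _, _ = lrt_cell(
                prepare_rows(table, "magnitude"), "magnitude"
            )
            stats.append(comparison.chi2)
        mean_chi2.append(np.mean(stats))
    assert mean_chi2[0] < mean_chi2[1] < mean_chi2[2]


def test_pvalues_uniform_under_global_null(null_calibration_pvalues):
    """Across replicate null corpora the omnibus p-values are approximately
    uniform (Kolmogorov-Smirnov)."""
    ps = null_calibration_pvalues[np.isfinite(null_calibration_pvalues)]
    assert len(ps) >= 290
    assert sps.kstest(ps, "uniform").pvalue > 0.01


def test_lrt_matches_lme4_oracle(tmp_path):
    """Cross-check one LRT cell against lme4 fitted through Rscript."""
    if shutil.which("Rscript") is None:
        pytest.fail("Rscript not available for the lme4 cross-check")
    corpus = ck.generate_corpus(
        ck.GeneratorConfig(n_dyads=6, utterances_per_participant=15, seed=33)
    )
    table, _ = ck.build_feature_table(
        corpus.recordings, corpus.annotations, articulators=("torso",)
    )
    rows = prepare_rows(table, "magnitude")
    spec = ModelSpec("magnitude", True, "participant", False)
    interest = fit_model(rows, spec)
    null = fit_model(
        rows, ModelSpec("magnitude", False, "participant", False), start_base=interest
    )
    ours = compare_models(null, interest)

    csv = tmp_path / "rows.csv"
    rows[["magnitude", "bin_index", "dur_z", "category", "participant_id"]].to_csv(
        csv, index=False
    )
    script = tmp_path / "check.R"
    script.write_text(
        textwrap.dedent(
            """
            suppressMessages(library(lme4))
            args <- commandArgs(trailingOnly = TRUE)
            d <- read.csv(args[1])
            d$bin_index <- factor(d$bin_index)
            d$category <- factor(d$category)
            m0 <- lmer(magnitude ~ bin_index + dur_z + (1 | participant_id), data = d, REML = FALSE)
            m1 <- lmer(magnitude ~ bin_index + dur_z + category + (1 | participant_id), data = d, REML = FALSE)
            a <- anova(m0, m1)
            cat(a$Chisq[2], a$Df[2], sep = "\\n")
            """
        )
    )
    out = subprocess.run(
        ["Rscript", "--vanilla", str(script), str(csv)],
        capture_output=True,
        text=True,
        timeout=300,
        check=True,
    )
    chi2_r, df_r = [float(x) for x in out.stdout.strip().splitlines()[-2:]]
    assert int(df_r) == ours.df == 5
    assert ours.chi2 == pytest.approx(chi2_r, abs=max(0.02 * chi2_r, 0.05))
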