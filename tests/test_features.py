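"""Windowed kinematic features: examples, invariances, aggregation, scaling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.spatial.transform import Rotation

import convkin as ck
from _oracles import (
    oracle_ap,
    oracle_lateral,
    oracle_magnitude,
    oracle_peak_velocity,
)

AXIS = np.array([0.0, 0.0, -1.0])


def uniform_track(rate=30.0, n=400, articulator="torso"):
    t = np.arange(n) / rate
    pos = np.column_stack([np.sin(t), np.cos(t), 2.0 + 0.1 * t])
    return ck.MotionTrack(articulator, t, pos)


# -- window extraction --------------------------------------------------------


def test_window_grid_arithmetic():
    """Onset 10 000 ms at 30 Hz -> bins [9.7, 10.0), [10.0, 10.3),
    [10.3, 10.6) s with 9 frames each."""
    wd = ck.extract_window(uniform_track(), 10_000.0)
    assert wd.frames_per_bin == 9 and wd.n_bins == 3
    assert wd.frame_times_s[0] == pytest.approx(9.7)
    assert wd.frame_times_s[9] == pytest.approx(10.0)
    assert wd.frame_times_s[18] == pytest.approx(10.3)
    assert wd.frame_times_s[-1] == pytest.approx(10.6 - 1 / 30.0)
    assert all(len(p) == 9 for p, _ in wd.bins())


def test_early_onset_flags_first_bin_incomplete():
    wd = ck.extract_window(uniform_track(), 100.0)
    assert not wd.bin_complete[0]
    assert wd.bin_complete[1] and wd.bin_complete[2]


def test_window_entirely_outside_track_raises():
    with pytest.raises(ck.ValidationError, match="outside"):
        ck.extract_window(uniform_track(n=60), 60_000.0)


def test_resampling_own_grid_is_identity():
    """Resampling a uniformly sampled track at its own rate and phase must
    reproduce the stored samples."""
    track = uniform_track()
    onset = 3000.0  # grid points land exactly on sample times
    wd = ck.extract_window(track, onset)
    start = int(round((onset / 1000.0 - 0.3) * 30))
    np.testing.assert_allclose(
        wd.positions, track.positions[start : start + 27], atol=1e-9
    )


# -- feature examples ---------------------------------------------------------


def test_magnitude_examples():
    constant = np.tile([0.1, 0.2, 2.0], (5, 1))
    assert ck.magnitude(constant) == 0.0
    path = np.array([[0, 0, 0], [0.010, 0, 0], [0.030, 0, 0], [0.020, 0, 0]])
    assert ck.magnitude(path) == pytest.approx(30.0)
    assert np.isnan(ck.magnitude(path[:1]))


def test_lateral_examples():
    at_center = np.tile([0.05, 0.2, 2.0], (4, 1))
    assert ck.lateral_position(at_center, 0.05) == 0.0
    swing = np.array([[-0.040, 0, 2], [0.020, 0, 2]])
    assert ck.lateral_position(swing, 0.0) == pytest.approx(40.0)
    # mirror symmetry: negating deviations about the center changes nothing
    mirrored = swing.copy()
    mirrored[:, 0] = -mirrored[:, 0]
    assert ck.lateral_position(mirrored, 0.0) == ck.lateral_position(swing, 0.0)


def test_ap_examples():
    approach = np.array([[0, 0, 2.00], [0, 0, 1.95], [0, 0, 1.90]])
    assert ck.ap_position(approach, AXIS) == pytest.approx(-1.90)
    # purely lateral/vertical motion is invisible to the projection
    lateral = np.array([[0.1, 0.3, 2.0], [-0.2, 0.1, 2.0]])
    assert ck.ap_position(lateral, AXIS) == pytest.approx(-2.0)
    with pytest.raises(ck.ValidationError, match="unit"):
        ck.ap_position(approach, [0, 0, -2.0])


def test_peak_velocity_examples():
    constant = np.tile([0.0, 0.0, 2.0], (9, 1))
    assert ck.peak_velocity(constant, 30.0) == 0.0
    jump = constant.copy()
    jump[5:, 0] += 0.010  # single 10 mm step at 30 Hz -> 30 cm/s
    assert ck.peak_velocity(jump, 30.0) == pytest.approx(30.0)
    assert ck.peak_velocity(jump[::-1], 30.0) == ck.peak_velocity(jump, 30.0)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_rotation_and_translation_invariance(seed):
    """Magnitude and peak velocity are rigid-motion invariants; the A/P
    projection is invariant when positions and axis co-rotate."""
    rng = np.random.default_rng(seed)
    positions = rng.normal(scale=0.05, size=(9, 3)) + [0, 0.5, 2.0]
    rotation = Rotation.random(random_state=seed).as_matrix()
    shift = rng.normal(size=3)

    rotated_about_origin = (positions - positions[0]) @ rotation.T + positions[0]
    assert ck.magnitude(rotated_about_origin) == pytest.approx(
        ck.magnitude(positions), abs=1e-9
    )
    assert ck.peak_velocity(positions @ rotation.T + shift, 30.0) == pytest.approx(
        ck.peak_velocity(positions, 30.0), abs=1e-9
    )
    assert ck.ap_position(positions @ rotation.T, rotation @ AXIS) == pytest.approx(
        ck.ap_position(positions, AXIS), abs=1e-9
    )


def test_homogeneity_of_degree_one(rng):
    """Doubling all displacements doubles magnitude, lateral and velocity."""
    base = rng.normal(scale=0.02, size=(9, 3))
    doubled = base * 2.0
    assert ck.magnitude(doubled) == pytest.approx(2 * ck.magnitude(base), rel=1e-12)
    assert ck.lateral_position(doubled, 0.0) == pytest.approx(
        2 * ck.lateral_position(base, 0.0), rel=1e-12
    )
    assert ck.peak_velocity(doubled, 30.0) == pytest.approx(
        2 * ck.peak_velocity(base, 30.0), rel=1e-12
    )


trajectories = arrays(
    np.float64,
    (9, 3),
    elements=st.floats(-0.5, 0.5, allow_nan=False, width=64),
)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(positions=trajectories)
def test_feature_bounds_hold_for_arbitrary_trajectories(positions):
    """Nonnegativity and simple bounds for any finite trajectory."""
    mag = ck.magnitude(positions)
    assert mag >= 0.0
    # excursion from the origin frame cannot exceed the path diameter
    diameter = max(
        np.linalg.norm(p - q) for p in positions for q in positions
    ) * 1000.0
    assert mag <= diameter + 1e-9
    assert ck.lateral_position(positions, 0.0) >= 0.0
    assert ck.peak_velocity(positions, 30.0) >= 0.0
    assert ck.ap_position(positions, AXIS) >= min(-positions[:, 2]) - 1e-12


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    positions=trajectories,
    factor=st.floats(0.125, 8.0, allow_nan=False),
)
def test_feature_homogeneity_for_arbitrary_scalings(positions, factor):
    """Magnitude, lateral and velocity scale linearly with displacements."""
    scaled = positions * factor
    assert ck.magnitude(scaled) == pytest.approx(
        factor * ck.magnitude(positions), rel=1e-9, abs=1e-9
    )
    assert ck.peak_velocity(scaled, 30.0) == pytest.approx(
        factor * ck.peak_velocity(positions, 30.0), rel=1e-9, abs=1e-9
    )


def test_features_match_exhaustive_oracle(rng):
    """Spot-check the implementations against the loop-based oracle on random
    9-frame trajectories (the full 1000-trajectory sweep runs in the
    acceptance suite)."""
    for _ in range(50):
        positions = rng.normal(scale=0.05, size=(9, 3)) + [0, 0.5, 2.0]
        assert ck.magnitude(positions) == pytest.approx(
            oracle_magnitude(positions), abs=1e-9
        )
        assert ck.lateral_position(positions, 0.1) == pytest.approx(
            oracle_lateral(positions, 0.1), abs=1e-9
        )
        assert ck.ap_position(positions, AXIS) == pytest.approx(
            oracle_ap(positions, AXIS), abs=1e-9
        )
        assert ck.peak_velocity(positions, 30.0) == pytest.approx(
            oracle_peak_velocity(positions, 30.0), abs=1e-9
        )


# -- hand aggregation ---------------------------------------------------------


def hand(mag, lat, ap, vel, n=9):
    return dict(
        magnitude=mag,
        lateral_position=lat,
        ap_position=ap,
        peak_velocity=vel,
        n_valid_frames=n,
    )


def test_aggregate_hands_rules():
    left = hand(10.0, 5.0, 0.30, 12.0)
    right = hand(20.0, 3.0, 0.50, 8.0)
    merged = ck.aggregate_hands(left, right)
    assert merged["magnitude"] == 20.0
    assert merged["lateral_position"] == 5.0
    assert merged["ap_position"] == 0.50  # larger = more proximal wins
    assert merged["peak_velocity"] == 12.0
    assert not merged["hand_missing"]


def test_aggregate_hands_idempotent_and_missing():
    both = hand(7.0, 2.0, 0.1, 5.0)
    merged = ck.aggregate_hands(both, dict(both))
    assert {k: merged[k] for k in both} == both
    gone = hand(np.nan, np.nan, np.nan, np.nan, n=0)
    carried = ck.aggregate_hands(both, gone)
    assert carried["magnitude"] == 7.0 and carried["hand_missing"]
    assert ck.aggregate_hands(dict(gone), dict(gone)) is None


# -- proximity rescaling ------------------------------------------------------


def test_scale_proximity_unit_sd_and_oracle_values():
    rows = pd.DataFrame(
        dict(articulator=["torso"] * 3, ap_position=[-2.0, 0.0, 2.0])
    )
    scaled, scales = ck.scale_proximity(rows)
    # hand-computed sample SD of {-2, 0, 2} is 2 -> {-1, 0, 1}
    np.testing.assert_allclose(scaled["ap_position"], [-1.0, 0.0, 1.0], atol=1e-12)
    assert scales["torso"] == pytest.approx(2.0)
    assert scaled["ap_position"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)


def test_scale_proximity_rejects_zero_spread():
    rows = pd.DataFrame(dict(articulator=["head"] * 4, ap_position=[1.0] * 4))
    with pytest.raises(ck.ValidationError, match="head"):
        ck.scale_proximity(rows)


# -- table construction -------------------------------------------------------


def test_feature_table_has_unit_sd_proximity(small_table):
    for articulator in ck.ANALYSIS_ARTICULATORS:
        vals = small_table.loc[
            small_table.articulator == articulator, "ap_position"
        ].dropna()
        assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-6)


def test_injected_burst_shows_up_in_magnitude():
    """An utterance with a strongly injected torso burst must exceed the
    corpus median torso magnitude."""
    config = ck.GeneratorConfig(
        n_dyads=2,
        utterances_per_participant=10,
        effect_table={("OIR", "torso", "magnitude"): 40.0},
        seed=13,
    )
    corpus = ck.generate_corpus(config)
    table, _ = ck.build_feature_table(
        corpus.recordings, corpus.annotations, articulators=("torso",)
    )
    oir = table[table.category == "OIR"]
    assert len(oir) > 0
    # peak-bin magnitude for boosted utterances clears the overall median
    boosted = oir.groupby("utterance_id")["magnitude"].max()
    assert (boosted > table["magnitude"].median()).all()


def test_empty_annotations_give_empty_table(caplog):
    config = ck.GeneratorConfig(n_dyads=1, utterances_per_participant=2, seed=1)
    corpus = ck.generate_corpus(config)
    with caplog.at_level("WARNING", logger="convkin"):
        table, log = ck.build_feature_table(corpus.recordings, [])
    assert len(table) == 0
    assert any("empty" in r.message for r in caplog.records)


def test_unknown_participant_raises(small_corpus):
    ghost = ck.UtteranceAnnotation("ux", "nobody", 1000.0, 2000.0, "InfReq")
    with pytest.raises(ck.ValidationError, match="nobody"):
        ck.build_feature_table(small_corpus.recordings, [ghost])


def test_all_features_nonnegative_where_defined(small_table):
    for column in ("magnitude", "lateral_position", "peak_velocity"):
        vals = small_table[column].dropna()
        assert (vals >= 0).all()
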