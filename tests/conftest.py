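import numpy as np
import pytest

import convkin as ck
from convkin.stats import lrt_cell, prepare_rows


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """Desk-scale null corpus shared by read-only tests."""
    config = ck.GeneratorConfig(n_dyads=4, utterances_per_participant=12, seed=7)
    return ck.generate_corpus(config)


@pytest.fixture(scope="session")
def small_table(small_corpus):
    table, _ = ck.build_feature_table(
        small_corpus.recordings, small_corpus.annotations
    )
    return table


def null_lrt_pvalue(seed: int, articulator: str = "torso", feature: str = "magnitude"):
    """One zero-effect corpus at the default scale -> omnibus LRT p-value."""
    config = ck.GeneratorConfig(seed=seed)
    corpus = ck.generate_corpus(config)
    table, _ = ck.build_feature_table(
        corpus.recordings, corpus.annotations, articulators=(articulator,)
    )
    rows = prepare_rows(table, feature)
    comparison, _, _ = lrt_cell(rows, feature, articulator=articulator)
    return comparison.p_value


@pytest.fixture(scope="session")
def null_calibration_pvalues():
    """Torso-magnitude LRT p-values over 300 null corpora (the heavy fixture).

    Shared between the type-I-rate check and the p-uniformity check so the
    simulation runs once per session.
    """
    return np.array([null_lrt_pvalue(30_000 + i) for i in range(300)])
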