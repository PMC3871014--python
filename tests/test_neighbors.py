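"""Neighbor-type features, balanced sampling, the MLR, and Bayes factors."""

import numpy as np
import pytest

import spinestats as ss
from spinestats.exceptions import SampleShortageError, ValidationError
from spinestats.neighbors import TYPE_CODES, dummy_code

from conftest import spines_on_interval


# ------------------------------------------------------------------- features
def test_feature_vector_example(interval):
    # spines at 10, 20, 35, 60; the spine at 20 has neighbors 10 (d=10),
    # 35 (d=15), 60 (d=40) → types mushroom, stubby, thin
    pat = spines_on_interval(
        interval, [10.0, 20.0, 35.0, 60.0], types=["mushroom", "thin", "stubby", "thin"], div=14
    )
    feats = ss.build_neighbor_features(pat)
    assert feats.n == 4
    row = feats.X[1]
    assert row == pytest.approx([1, 0, 0, 1, 0, 0, 14.0])
    assert feats.y[1] == TYPE_CODES["thin"]
    assert feats.distances[1] == pytest.approx([10.0, 15.0, 40.0])


def test_small_pattern_excluded(interval):
    small = spines_on_interval(interval, [10.0, 20.0, 30.0])  # only 2 neighbors each
    big = spines_on_interval(interval, [5.0, 15.0, 25.0, 35.0, 45.0])
    feats = ss.build_neighbor_features([small, big])
    assert feats.n == 5
    assert feats.n_excluded == 3


def test_dummy_coding_table():
    assert dummy_code("mushroom") == (1, 0)
    assert dummy_code("stubby") == (0, 1)
    assert dummy_code("thin") == (0, 0)
    with pytest.raises(ValidationError):
        dummy_code("filopodium")


# ------------------------------------------------------------ balanced sample
def synthetic_features(n=600, seed=0, div=7, experiment=1):
    """Feature set sampled from a known MLR, bypassing spatial construction."""
    rng = np.random.default_rng(seed)
    types = ["mushroom", "stubby", "thin"]
    X = np.empty((n, 7))
    for i in range(n):
        nbrs = rng.choice(types, size=3)
        X[i] = ss.neighbor_vector(*nbrs, div)
    import pandas as pd

    meta = pd.DataFrame(
        dict(
            experiment=experiment,
            div=div,
            dendrite_id="synth",
            x=rng.uniform(0, 100, n),
            y=rng.uniform(0, 100, n),
        )
    )
    y = rng.integers(0, 3, size=n)
    return ss.NeighborFeatures(X=X, y=y, distances=np.zeros((n, 3)), meta=meta), rng


def test_balanced_sample_counts_and_margin():
    feats, rng = synthetic_features(seed=1)
    samp = ss.sample_balanced(feats, window=(0, 100, 0, 100), n_per_type=30, margin=10.0, rng=rng)
    assert len(samp.indices) == 90
    counts = np.bincount(feats.y[samp.indices], minlength=3)
    assert list(counts) == [30, 30, 30]
    x = feats.meta["x"].to_numpy()[samp.indices]
    yy = feats.meta["y"].to_numpy()[samp.indices]
    assert np.all((x >= 10) & (x <= 90) & (yy >= 10) & (yy <= 90))


def test_balanced_sample_shortage():
    feats, rng = synthetic_features(n=60, seed=2)
    with pytest.raises(SampleShortageError) as exc:
        ss.sample_balanced(feats, window=(0, 100, 0, 100), n_per_type=50, rng=rng)
    assert exc.value.requested == 50


def test_balanced_sample_no_window():
    feats, rng = synthetic_features(seed=3)
    samp = ss.sample_balanced(feats, window=None, n_per_type=40, rng=rng)
    assert len(samp.indices) == 120


# ------------------------------------------------------------------ model fit
def simulate_from_model(model, n, seed):
    """Draw responses from a known MLR; DIV varies so all 8 β are identified."""
    rng = np.random.default_rng(seed)
    types = ["mushroom", "stubby", "thin"]
    X = np.empty((n, 7))
    y = np.empty(n, dtype=int)
    for i in range(n):
        nbrs = rng.choice(types, size=3)
        X[i] = ss.neighbor_vector(*nbrs, int(rng.choice([7, 14, 21])))
        p = ss.predict_probs(model, X[i])
        y[i] = rng.choice(3, p=[p["mushroom"], p["stubby"], p["thin"]])
    import pandas as pd

    meta = pd.DataFrame(dict(experiment=1, div=7, dendrite_id="sim", x=0.0, y=0.0), index=range(n))
    return ss.NeighborFeatures(X=X, y=y, distances=np.zeros((n, 3)), meta=meta)


def test_fit_recovers_known_coefficients():
    true = ss.MLRModel.from_coefficients(
        beta_stubby=[0.2, 0.5, -0.3, 0.4, 0.1, -0.2, 0.3, 0.0],
        beta_thin=[-0.1, -0.4, 0.2, -0.5, 0.3, 0.1, -0.3, 0.02],
    )
    feats = simulate_from_model(true, n=2000, seed=4)
    fit = ss.fit_mlr(feats)
    for est, tru, se in [
        (fit.beta_stubby, true.beta_stubby, fit.se_stubby),
        (fit.beta_thin, true.beta_thin, fit.se_thin),
    ]:
        dev = np.abs(est - tru) / se
        assert dev.max() < 3.0


def test_fit_invariant_to_duplication():
    true = ss.MLRModel.from_coefficients(
        beta_stubby=[0.1, 0.4, -0.2, 0.3, 0.0, -0.1, 0.2, 0.0],
        beta_thin=[0.0, -0.3, 0.1, -0.4, 0.2, 0.0, -0.2, 0.0],
    )
    feats = simulate_from_model(true, n=400, seed=5)
    doubled = ss.NeighborFeatures(
        X=np.vstack([feats.X, feats.X]),
        y=np.concatenate([feats.y, feats.y]),
        distances=np.vstack([feats.distances, feats.distances]),
        meta=feats.meta,
    )
    f1 = ss.fit_mlr(feats)
    f2 = ss.fit_mlr(doubled)
    assert f2.beta_stubby == pytest.approx(f1.beta_stubby, abs=1e-4)
    assert f2.beta_thin == pytest.approx(f1.beta_thin, abs=1e-4)


def test_fit_missing_category_error():
    feats, _ = synthetic_features(n=100, seed=6)
    feats.y[feats.y == 2] = 0  # remove all thin responses
    with pytest.raises(ValidationError):
        ss.fit_mlr(feats)


# ----------------------------------------------------------------- prediction
def published_model(experiment):
    coef = ss.MLR_COEFFICIENTS[experiment]
    return ss.MLRModel.from_coefficients(coef[0], coef[1])


def test_published_probability_exp1_div7_mushroom():
    m = published_model(1)
    p = ss.predict_probs(m, ss.neighbor_vector("mushroom", "mushroom", "mushroom", 7))
    assert round(p["mushroom"], 2) == 0.45
    assert round(p["stubby"], 2) == 0.30
    assert round(p["thin"], 2) == 0.25


def test_published_probability_exp1_div7_stubby():
    m = published_model(1)
    p = ss.predict_probs(m, ss.neighbor_vector("stubby", "stubby", "stubby", 7))
    assert round(p["stubby"], 2) == 0.55


def test_published_probability_exp2_exp3():
    p2 = ss.predict_probs(
        published_model(2), ss.neighbor_vector("mushroom", "mushroom", "mushroom", 7)
    )
    assert round(p2["mushroom"], 2) == 0.51
    p3 = ss.predict_probs(
        published_model(3), ss.neighbor_vector("stubby", "stubby", "stubby", 21)
    )
    assert round(p3["stubby"], 2) == 0.60


def test_zero_coefficients_uniform():
    m = ss.MLRModel.from_coefficients(np.zeros(8), np.zeros(8))
    p = ss.predict_probs(m, ss.neighbor_vector("thin", "stubby", "mushroom", 14))
    assert p["mushroom"] == pytest.approx(1 / 3)
    assert p["stubby"] == pytest.approx(1 / 3)
    assert p["thin"] == pytest.approx(1 / 3)


def test_log_odds_identity():
    m = published_model(2)
    rng = np.random.default_rng(7)
    for _ in range(10):
        nbrs = rng.choice(["mushroom", "stubby", "thin"], size=3)
        X = ss.neighbor_vector(*nbrs, int(rng.choice([7, 14, 21])))
        p = ss.predict_probs(m, X)
        Xc = np.concatenate([[1.0], X])
        assert np.log(p["stubby"] / p["mushroom"]) == pytest.approx(
            float(Xc @ m.beta_stubby), abs=1e-12
        )
        assert np.log(p["thin"] / p["mushroom"]) == pytest.approx(
            float(Xc @ m.beta_thin), abs=1e-12
        )
        assert p["mushroom"] + p["stubby"] + p["thin"] == pytest.approx(1.0)


def test_invalid_dummy_pair_rejected():
    m = published_model(1)
    X = np.array([1, 1, 0, 0, 0, 0, 7.0])
    with pytest.raises(ValidationError):
        ss.predict_probs(m, X)


def test_probs_simplex_batch():
    m = published_model(3)
    X = np.vstack(
        [
            ss.neighbor_vector("thin", "thin", "thin", 7),
            ss.neighbor_vector("mushroom", "stubby", "thin", 21),
        ]
    )
    p = ss.predict_probs(m, X)
    total = p["mushroom"] + p["stubby"] + p["thin"]
    assert total == pytest.approx(np.ones(2))
    assert all(np.all(v > 0) for v in p.values())


# -------------------------------------------------------------- Bayes factors
def test_published_bayes_factor():
    m = published_model(1)
    bf = ss.bayes_factor(
        m, ss.neighbor_vector("mushroom", "mushroom", "mushroom", 7), ss.type_priors(1)
    )
    assert round(bf["mushroom"], 2) == 1.02


def test_bayes_factor_unit_when_priors_match():
    m = published_model(1)
    X = ss.neighbor_vector("stubby", "thin", "mushroom", 14)
    probs = ss.predict_probs(m, X)
    bf = ss.bayes_factor(m, X, probs)
    for v in bf.values():
        assert v == pytest.approx(1.0)


def test_thin_bf_highest_on_published_inputs():
    """Same-type Bayes factors: thin exceeds mushroom and stubby in every
    experiment at DIV 7, the direction reported for the published tables."""
    for exp in (1, 2, 3):
        m = published_model(exp)
        priors = ss.type_priors(exp)
        same = {}
        for t in ("mushroom", "stubby", "thin"):
            same[t] = ss.bayes_factor(m, ss.neighbor_vector(t, t, t, 7), priors)[t]
        assert same["thin"] > same["mushroom"]
        assert same["thin"] > same["stubby"]


def test_bayes_factor_bad_priors():
    m = published_model(1)
    X = ss.neighbor_vector("thin", "thin", "thin", 7)
    with pytest.raises(ValidationError):
        ss.bayes_factor(m, X, {"mushroom": 0.5, "stubby": 0.5, "thin": 0.2})
    with pytest.raises(ValidationError):
        ss.bayes_factor(m, X, {"mushroom": 1.0, "stubby": 0.0, "thin": 0.0})
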