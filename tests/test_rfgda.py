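"""Two-layer scorer: forest training, per-individual GDA, posteriors,
serialization."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import multivariate_normal

from scsnp import (
    ModelError,
    RFGDAModel,
    fit_gda,
    load_model,
    save_model,
    score,
    train_model,
    train_rf,
)
from scsnp.rfgda import GDALayer, GaussianClass

FEATS = ("m", "a")


def _gaussian_table(rng, n_pos, n_neg, mu_pos, mu_neg, sd=0.5,
                    individual="I1"):
    pos = rng.normal(mu_pos, sd, size=(n_pos, 2))
    neg = rng.normal(mu_neg, sd, size=(n_neg, 2))
    X = np.vstack([pos, neg])
    t = pd.DataFrame(X, columns=list(FEATS))
    t["individual"] = individual
    t["gtype"] = "AA"
    labels = np.r_[np.ones(n_pos, bool), np.zeros(n_neg, bool)]
    return t, labels


# ---------------------------------------------------------------------------
# first layer

def test_separable_classes_reach_perfect_training_accuracy():
    rng = np.random.default_rng(0)
    t, y = _gaussian_table(rng, 300, 300, (4.0, 10.0), (0.0, 4.0), sd=0.2)
    rf = train_rf(t, y, features=FEATS, n_estimators=30, seed=0)
    prob = rf.predict_proba(t)
    assert ((prob > 0.5) == y).mean() == 1.0


def test_uninformative_labels_score_near_majority_rate():
    rng = np.random.default_rng(1)
    t, _ = _gaussian_table(rng, 3000, 0, (0.0, 0.0), (0.0, 0.0), sd=1.0)
    y = rng.random(3000) < 2 / 3  # labels independent of the features
    rf = train_rf(t.iloc[:2000], y[:2000], features=FEATS,
                  n_estimators=30, seed=1)
    held = rf.predict_proba(t.iloc[2000:]) > 0.5
    majority = y[:2000].mean()
    acc = (held == y[2000:]).mean()
    assert abs(acc - max(majority, 1 - majority)) < 0.15


def test_training_is_deterministic_under_fixed_seed():
    rng = np.random.default_rng(2)
    t, y = _gaussian_table(rng, 400, 400, (4.0, 10.0), (0.0, 7.0))
    p1 = train_rf(t, y, features=FEATS, seed=9).predict_proba(t)
    p2 = train_rf(t, y, features=FEATS, seed=9).predict_proba(t)
    assert np.array_equal(p1, p2)


def test_single_class_labels_rejected():
    rng = np.random.default_rng(3)
    t, _ = _gaussian_table(rng, 100, 0, (0, 0), (0, 0))
    with pytest.raises(ModelError, match="single class"):
        train_rf(t, np.ones(100, bool), features=FEATS)


# ---------------------------------------------------------------------------
# second layer

def test_gda_recovers_generating_means_with_oracle_first_layer():
    rng = np.random.default_rng(4)
    mu_pos, mu_neg = np.array([4.0, 10.0]), np.array([0.0, 7.0])
    t, y = _gaussian_table(rng, 8000, 2000, mu_pos, mu_neg, sd=0.5)
    layers, pooled, fb = fit_gda(t, y.astype(float), features=FEATS)
    layer = layers["I1"]
    se_pos = 0.5 / np.sqrt(8000)
    se_neg = 0.5 / np.sqrt(2000)
    assert np.all(np.abs(layer.pos.mean - mu_pos) < 3 * se_pos)
    assert np.all(np.abs(layer.neg.mean - mu_neg) < 3 * se_neg)
    assert layer.pos.prior == pytest.approx(0.8)
    assert not fb


def test_small_individual_uses_pooled_fallback():
    rng = np.random.default_rng(5)
    big, y_big = _gaussian_table(rng, 2000, 2000, (4, 10), (0, 7),
                                 individual="big")
    tiny, y_tiny = _gaussian_table(rng, 5, 5, (4, 10), (0, 7),
                                   individual="tiny")
    t = pd.concat([big, tiny], ignore_index=True)
    y = np.r_[y_big, y_tiny]
    layers, pooled, fb = fit_gda(t, y.astype(float), features=FEATS)
    assert fb == ["tiny"]
    assert layers["tiny"].pooled
    assert not layers["big"].pooled


def test_identical_individuals_get_identical_layers():
    rng = np.random.default_rng(6)
    a, y = _gaussian_table(rng, 1000, 1000, (4, 10), (0, 7), individual="A")
    b = a.copy()
    b["individual"] = "B"
    t = pd.concat([a, b], ignore_index=True)
    layers, _, _ = fit_gda(t, np.r_[y, y].astype(float), features=FEATS)
    assert np.array_equal(layers["A"].pos.mean, layers["B"].pos.mean)
    assert np.array_equal(layers["A"].neg.cov, layers["B"].neg.cov)


def test_corrupting_one_individual_leaves_others_untouched():
    """Per-individual fitting isolates outlier-ridden cells."""
    rng = np.random.default_rng(7)
    a, ya = _gaussian_table(rng, 1000, 1000, (4, 10), (0, 7), individual="A")
    b, yb = _gaussian_table(rng, 1000, 1000, (4, 10), (0, 7), individual="B")
    t = pd.concat([a, b], ignore_index=True)
    y = np.r_[ya, yb].astype(float)
    ref, _, _ = fit_gda(t, y, features=FEATS)
    corrupted = t.copy()
    corrupted.loc[corrupted["individual"] == "B", "m"] += 50.0
    alt, _, _ = fit_gda(corrupted, y, features=FEATS)
    assert np.array_equal(ref["A"].pos.mean, alt["A"].pos.mean)
    assert np.array_equal(ref["A"].neg.cov, alt["A"].neg.cov)
    assert not np.array_equal(ref["B"].pos.mean, alt["B"].pos.mean)


# ---------------------------------------------------------------------------
# posterior

def _layer(mu_pos, mu_neg, cov=None, prior=0.5):
    cov = np.eye(2) if cov is None else cov
    return GDALayer(GaussianClass(np.asarray(mu_pos, float), cov, prior),
                    GaussianClass(np.asarray(mu_neg, float), cov, 1 - prior))


def test_point_at_positive_mean_scores_above_half():
    layer = _layer((4, 10), (0, 7))
    assert layer.posterior(np.array([[4.0, 10.0]]))[0] > 0.5


def test_equidistant_point_scores_exactly_half():
    layer = _layer((1, 0), (-1, 0))
    assert layer.posterior(np.array([[0.0, 5.0]]))[0] == pytest.approx(
        0.5, abs=1e-12
    )


def test_posterior_complement_sums_to_one():
    layer = _layer((4, 10), (0, 7), prior=0.7)
    rng = np.random.default_rng(8)
    X = rng.normal(2, 3, size=(500, 2))
    p = layer.posterior(X)
    flipped = GDALayer(layer.neg, layer.pos)
    q = flipped.posterior(X)
    assert np.all(p >= 0) and np.all(p <= 1)
    assert np.allclose(p + q, 1.0, atol=1e-12)


def test_posterior_matches_direct_density_oracle():
    rng = np.random.default_rng(9)
    cov_p = np.array([[0.3, 0.1], [0.1, 0.5]])
    cov_n = np.array([[0.8, -0.2], [-0.2, 0.6]])
    layer = GDALayer(GaussianClass(np.array([4.0, 10.0]), cov_p, 0.8),
                     GaussianClass(np.array([0.0, 7.0]), cov_n, 0.2))
    X = rng.normal(2, 4, size=(1000, 2))
    num = 0.8 * multivariate_normal(layer.pos.mean, cov_p).pdf(X)
    den = num + 0.2 * multivariate_normal(layer.neg.mean, cov_n).pdf(X)
    expected = num / den
    assert np.allclose(layer.posterior(X), expected, atol=1e-10)


# ---------------------------------------------------------------------------
# end-to-end model + serialization

@pytest.fixture(scope="module")
def toy_model_and_table():
    rng = np.random.default_rng(10)
    frames, labels = [], []
    for ind in ("I1", "I2"):
        t, y = _gaussian_table(rng, 1500, 700, (4, 10), (0, 7),
                               individual=ind)
        frames.append(t)
        labels.append(y)
    table = pd.concat(frames, ignore_index=True)
    y = np.concatenate(labels)
    model = train_model(table, y, features=FEATS, n_estimators=30, seed=11)
    return model, table


def test_scores_lie_in_unit_interval(toy_model_and_table):
    model, table = toy_model_and_table
    out = score(table, model)
    assert out["rfgda_score"].between(0, 1).all()


def test_model_round_trip_reproduces_scores(tmp_path, toy_model_and_table):
    model, table = toy_model_and_table
    expected = score(table, model)["rfgda_score"]
    save_model(model, tmp_path / "m.model")
    reloaded = load_model(tmp_path / "m.model")
    assert np.array_equal(score(table, reloaded)["rfgda_score"], expected)


def test_corrupted_model_file_raises(tmp_path):
    path = tmp_path / "bad.model"
    path.write_bytes(b"RFGDA\x01" + b"not a pickle")
    with pytest.raises(ModelError, match="corrupt"):
        load_model(path)
    path.write_bytes(b"RFGDA\x63" + b"anything")
    with pytest.raises(ModelError, match="version"):
        load_model(path)
    path.write_bytes(b"WRONG!" + b"anything")
    with pytest.raises(ModelError, match="not an RF-GDA"):
        load_model(path)


def test_unseen_individual_without_pooled_layer_rejected(toy_model_and_table):
    model, table = toy_model_and_table
    stripped = RFGDAModel(model.rf, dict(model.gda), None, model.features,
                          model.provenance)
    other = table.copy()
    other["individual"] = "I99"
    with pytest.raises(ModelError, match="I99"):
        score(other, stripped)


def test_nc_calls_are_scored_but_stay_nc(toy_model_and_table):
    model, table = toy_model_and_table
    t = table.copy()
    t.loc[t.index[:10], "gtype"] = "NC"
    out = score(t, model)
    assert out["rfgda_score"].notna().all()
    assert (out.loc[out.index[:10], "gtype"] == "NC").all()
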