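"""Chi-square ranking, top-k selection and pooled-covariance LDA."""

import numpy as np
import pytest

from neolus.modeling import (FeatureTable, PooledCovarianceLDA,
                             QuantileChi2Selector, chi2_rank, fit_lda,
                             predict, select_top_k)

CLASSES6 = np.array(["Normal", "TTN", "PTX", "RDS", "CLD", "CON"])


def make_table(n_per_class=20, n_noise=30, n_informative=0, seed=0,
               classes=CLASSES6):
    """Synthetic table: informative features shift their mean per class."""
    rng = np.random.default_rng(seed)
    n = n_per_class * len(classes)
    labels = np.repeat(classes, n_per_class)
    X = rng.standard_normal((n, n_noise + n_informative + 3))
    for f in range(n_informative):
        X[:, f] += 3.0 * np.repeat(np.arange(len(classes)), n_per_class)
    names = ([f"inf_{f}" for f in range(n_informative)]
             + [f"noise_{f}" for f in range(n_noise)]
             + ["ga_weeks", "cgats_weeks", "dol_days"])
    mask = np.zeros(X.shape[1], dtype=bool)
    mask[-3:] = True
    groups = np.array([f"S{i // (n_per_class // 2 or 1)}" for i in range(n)])
    return FeatureTable(X, names, labels, groups, mask)


# ---------------------------------------------------------------------------
# chi-square ranking
# ---------------------------------------------------------------------------

def test_constant_feature_ranked_last_with_p_one():
    t = make_table(seed=1)
    t.matrix[:, 5] = 7.0          # a noise column made constant
    r = chi2_rank(t)
    assert r.names[-1] == "noise_5" or r.pvalues[-1] == 1.0
    assert r.pvalues[list(r.names).index("noise_5")] == 1.0


def test_planted_feature_ranked_first():
    t = make_table(n_per_class=100, n_informative=1, seed=2)
    r = chi2_rank(t)
    assert r.names[0] == "inf_0"
    assert r.pvalues[0] < 1e-10


def test_clinical_columns_never_ranked():
    t = make_table(seed=3)
    r = chi2_rank(t)
    assert not set(r.names) & {"ga_weeks", "cgats_weeks", "dol_days"}
    assert np.all(np.diff(r.pvalues) >= -1e-15)     # ascending


def test_null_pvalues_roughly_uniform():
    """Type-I error of the binned chi-square near the nominal level."""
    rng = np.random.default_rng(4)
    n = 600
    labels = np.repeat(CLASSES6, n // 6)
    X = rng.standard_normal((n, 500))
    mask = np.zeros(500, dtype=bool)
    t = FeatureTable(X, [f"f{i}" for i in range(500)], labels,
                     np.array(["s"] * n), mask)
    r = chi2_rank(t)
    frac = float((r.pvalues < 0.05).mean())
    assert abs(frac - 0.05) < 0.03


def test_single_class_rejected():
    t = make_table(classes=np.array(["Normal"]))
    with pytest.raises(ValueError):
        chi2_rank(t)


# ---------------------------------------------------------------------------
# top-k selection
# ---------------------------------------------------------------------------

def test_top_15_plus_clinical_gives_18_columns():
    t = make_table(n_per_class=30, n_informative=5, seed=5)
    out = select_top_k(chi2_rank(t), 15, t)
    assert out.matrix.shape[1] == 18
    assert {"ga_weeks", "cgats_weeks", "dol_days"} <= set(out.names)
    assert out.clinical_mask.sum() == 3


def test_k_equal_all_is_identity_on_image_features():
    t = make_table(seed=6)
    out = select_top_k(chi2_rank(t), 30, t)
    assert set(out.names) == set(t.names)


def test_tied_pvalues_break_by_column_order():
    rng = np.random.default_rng(7)
    n = 60
    labels = np.repeat(CLASSES6, 10)
    base = rng.standard_normal(n)
    X = np.column_stack([base, base, rng.standard_normal(n)])
    t = FeatureTable(X, ["a", "b", "c"], labels, np.array(["s"] * n),
                     np.zeros(3, dtype=bool))
    r = chi2_rank(t)
    ia, ib = list(r.names).index("a"), list(r.names).index("b")
    assert ia < ib                 # identical columns keep original order


def test_selector_is_sklearn_compatible():
    from sklearn.pipeline import Pipeline

    t = make_table(n_per_class=30, n_informative=4, seed=8)
    pipe = Pipeline([
        ("select", QuantileChi2Selector(k=10, protected=t.clinical_mask)),
        ("lda", PooledCovarianceLDA()),
    ])
    pipe.fit(t.matrix, t.labels)
    acc = (pipe.predict(t.matrix) == t.labels).mean()
    assert acc > 0.9
    assert pipe.named_steps["select"].support_.sum() == 13


# ---------------------------------------------------------------------------
# LDA
# ---------------------------------------------------------------------------

def test_two_gaussians_threshold_at_midpoint():
    rng = np.random.default_rng(9)
    xa = rng.normal(0.0, 1.0, 500)
    xb = rng.normal(10.0, 1.0, 500)
    X = np.concatenate([xa, xb])[:, None]
    y = np.array(["A"] * 500 + ["B"] * 500)
    m = fit_lda(FeatureTable(X, ["x"], y, np.array(["s"] * 1000),
                             np.zeros(1, dtype=bool)))
    grid = np.linspace(3, 7, 4001)[:, None]
    pred, _ = predict(m, grid)
    threshold = grid[np.argmax(pred == "B"), 0]
    assert threshold == pytest.approx(5.0, abs=0.2)


def test_empirical_priors_match_class_counts():
    counts = {"Normal": 185, "CLD": 180, "CON": 305, "PTX": 105,
              "RDS": 245, "TTN": 530}
    rng = np.random.default_rng(10)
    X, y = [], []
    for c, n in counts.items():
        X.append(rng.standard_normal((n, 2)))
        y += [c] * n
    t = FeatureTable(np.vstack(X), ["a", "b"], np.array(y),
                     np.array(["s"] * 1550), np.zeros(2, dtype=bool))
    m = fit_lda(t, priors_mode="empirical")
    pri = dict(zip(m.classes_, m.priors_))
    assert pri["TTN"] == pytest.approx(530 / 1550)
    m_eq = fit_lda(t, priors_mode="equal")
    np.testing.assert_allclose(m_eq.priors_, 1 / 6)


def test_separable_blobs_perfect_training_accuracy():
    rng = np.random.default_rng(11)
    X = np.vstack([rng.normal(loc, 0.2, (40, 3))
                   for loc in (0.0, 5.0, 10.0, 15.0, 20.0, 25.0)])
    y = np.repeat(CLASSES6, 40)
    m = PooledCovarianceLDA().fit(X, y)
    assert (m.predict(X) == y).all()
    # every class mean maps to its own class
    for c in m.classes_:
        mu = X[y == c].mean(axis=0)
        assert m.predict(mu[None, :])[0] == c


def test_prior_shift_flips_borderline_prediction():
    X = np.array([[-1.0], [-1.2], [-0.8], [1.0], [1.2], [0.8],
                  [1.0], [1.2], [0.8]])
    y = np.array(["A", "A", "A", "B", "B", "B", "B", "B", "B"])
    eq = PooledCovarianceLDA(priors="equal").fit(X, y)
    emp = PooledCovarianceLDA(priors="empirical").fit(X, y)
    midpoint = np.array([[0.0]])
    assert eq.predict(midpoint)[0] == "A"       # tie -> first class
    assert emp.predict(midpoint)[0] == "B"      # prior mass pulls to B


def test_scores_invariant_to_affine_feature_rescaling():
    rng = np.random.default_rng(12)
    X = rng.standard_normal((90, 4))
    y = np.repeat(np.array(["A", "B", "C"]), 30)
    m1 = PooledCovarianceLDA().fit(X, y)
    m2 = PooledCovarianceLDA().fit(X * np.array([10, 0.1, 3, 7]) + 5.0, y)
    s1 = m1.decision_function(X)
    s2 = m2.decision_function(X * np.array([10, 0.1, 3, 7]) + 5.0)
    np.testing.assert_allclose(s1, s2, rtol=1e-8, atol=1e-8)


def test_lda_matches_sklearn_on_shared_settings():
    """Cross-check against sklearn's LDA with matching priors."""
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    rng = np.random.default_rng(13)
    X = np.vstack([rng.normal(0, 1, (60, 3)), rng.normal(2, 1, (60, 3)),
                   rng.normal(4, 1, (60, 3))])
    y = np.repeat(np.array(["A", "B", "C"]), 60)
    ours = PooledCovarianceLDA(standardize=False, ridge=0.0).fit(X, y)
    ref = LinearDiscriminantAnalysis(solver="lsqr",
                                     priors=[1 / 3] * 3).fit(X, y)
    grid = rng.normal(2, 2, (200, 3))
    assert (ours.predict(grid) == ref.predict(grid)).mean() > 0.99


def test_small_class_rejected_and_dimension_mismatch():
    X = np.array([[0.0], [1.0], [2.0]])
    y = np.array(["A", "A", "B"])
    with pytest.raises(ValueError):
        PooledCovarianceLDA().fit(X, y)
    m = PooledCovarianceLDA().fit(np.array([[0.], [.1], [1.], [1.1]]),
                                  np.array(["A", "A", "B", "B"]))
    with pytest.raises(ValueError):
        m.predict(np.zeros((2, 3)))


def test_equal_priors_invariant_to_class_duplication():
    rng = np.random.default_rng(14)
    X = np.vstack([rng.normal(0, 0.5, (30, 2)), rng.normal(4, 0.5, (30, 2))])
    y = np.repeat(np.array(["A", "B"]), 30)
    Xd = np.vstack([X, X[y == "B"]])
    yd = np.concatenate([y, y[y == "B"]])
    # points clear of the class boundary; duplication reweights the pooled
    # covariance slightly, so only razor-edge points could ever flip
    grid = np.vstack([rng.uniform(-1, 1, (50, 2)), rng.uniform(3, 5, (50, 2))])
    p1 = PooledCovarianceLDA(priors="equal").fit(X, y).predict(grid)
    p2 = PooledCovarianceLDA(priors="equal").fit(Xd, yd).predict(grid)
    assert (p1 == p2).all()
    assert (p1 == np.array(["A"] * 50 + ["B"] * 50)).all()


def test_feature_table_validation():
    with pytest.raises(ValueError):
        FeatureTable(np.zeros((2, 2)), ["a"], np.array(["x", "y"]),
                     np.array(["s", "s"]), np.zeros(2, dtype=bool))
    with pytest.raises(ValueError):
        FeatureTable(np.array([[np.nan, 0.0]]), ["a", "b"],
                     np.array(["x"]), np.array(["s"]),
                     np.zeros(2, dtype=bool))


def test_model_serialization_roundtrip(tmp_path):
    """Saved models reload with identical predictions and metadata."""
    t = make_table(n_per_class=20, n_informative=3, seed=15)
    m = fit_lda(t, priors_mode="empirical")
    path = tmp_path / "model.json"
    m.save(str(path), feature_names=t.names[:5])
    loaded, names = PooledCovarianceLDA.load(str(path))
    assert names == t.names[:5]
    np.testing.assert_array_equal(loaded.classes_, m.classes_)
    np.testing.assert_allclose(loaded.priors_, m.priors_)
    np.testing.assert_array_equal(loaded.predict(t.matrix),
                                  m.predict(t.matrix))
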