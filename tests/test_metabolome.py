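"""Metabolome preprocessing, PLS-DA/VIP, differential calls, origin split."""
import numpy as np
import pandas as pd
import pytest

from heterosim import metabolome as mb
from heterosim._pls import PLSDA
from heterosim.simulate import generate_design
from conftest import gaussian_groups


def _df(arr, prefix="m"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=[f"s{j}" for j in range(arr.shape[1])])


# ---------------------------------------------------------------------------
# Annotation-level filter
# ---------------------------------------------------------------------------

def test_annotation_level_filter_assignments():
    ann = pd.DataFrame({
        "metabolite_id": ["a", "b", "c", "d"],
        "rt_error": [0.1, 0.3, 0.2, 0.35],
        "fragmentation_score": [50.0, 45.0, 44.9, 80.0],
    })
    out = mb.annotation_level_filter(ann).set_index("metabolite_id")
    assert out.loc["a", "level"] == 1
    assert out.loc["b", "level"] == 1   # boundary: |rt| = 0.3, score = 45
    assert out.loc["c", "level"] == 2
    assert "d" not in out.index         # rt outside the window


def test_annotation_level_filter_missing_fields():
    ann = pd.DataFrame({"metabolite_id": ["a", "b"],
                        "rt_error": [0.1, np.nan],
                        "fragmentation_score": [50.0, 60.0]})
    with pytest.warns(UserWarning):
        out = mb.annotation_level_filter(ann)
    assert list(out["metabolite_id"]) == ["a"]
    with pytest.raises(ValueError, match="lacks columns"):
        mb.annotation_level_filter(pd.DataFrame({"metabolite_id": ["a"]}))


# ---------------------------------------------------------------------------
# Missingness filter (strict, per-group)
# ---------------------------------------------------------------------------

def test_missingness_filter_strict_within_any_group():
    design = generate_design((10, 10, 10), 0)
    X = pd.DataFrame(np.ones((3, 30)), index=["keep_half", "drop_six", "keep_full"],
                     columns=design["sample_id"].tolist())
    p1 = design.loc[design["group"] == "P1", "sample_id"].tolist()
    X.loc["keep_half", p1[:5]] = np.nan   # exactly 50% in P1 -> retained
    X.loc["drop_six", p1[:6]] = np.nan    # 60% in P1 -> removed
    out = mb.filter_missingness(X, design, max_frac=0.5)
    assert list(out.index) == ["keep_half", "keep_full"]


# ---------------------------------------------------------------------------
# Half-minimum imputation
# ---------------------------------------------------------------------------

def test_half_min_imputation_global_value():
    X = _df([[4.0, np.nan, 16.0], [8.0, 32.0, np.nan]])
    out = mb.impute_half_min(X)
    assert out.loc["m0", "s1"] == 2.0  # half of the global minimum 4
    assert out.loc["m1", "s2"] == 2.0  # same value for every missing cell
    assert out.loc["m0", "s0"] == 4.0  # observed cells untouched


def test_half_min_imputation_no_missing_is_identity():
    X = _df([[1.0, 2.0], [3.0, 4.0]])
    pd.testing.assert_frame_equal(mb.impute_half_min(X), X)


def test_half_min_imputation_all_missing_raises():
    with pytest.raises(ValueError, match="no non-missing"):
        mb.impute_half_min(_df([[np.nan, np.nan]]))


# ---------------------------------------------------------------------------
# log10 + autoscaling
# ---------------------------------------------------------------------------

def test_log10_autoscale_hand_example():
    # one feature over three samples: (1, 10, 100) -> (-1.2247, 0, 1.2247)
    X = _df([[1.0, 10.0, 100.0]])
    out = mb.log10_autoscale(X)
    np.testing.assert_allclose(out.loc["m0"], [-np.sqrt(1.5), 0.0, np.sqrt(1.5)],
                               atol=1e-6)


def test_log10_autoscale_moments_and_constant_dropped():
    rng = np.random.default_rng(0)
    X = _df(10.0 ** rng.normal(3, 1, size=(6, 20)))
    X.loc["m3"] = 7.0  # constant feature
    with pytest.warns(UserWarning, match="zero-variance"):
        out = mb.log10_autoscale(X)
    assert "m3" not in out.index
    np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-10)
    np.testing.assert_allclose(out.std(axis=1, ddof=0), 1.0, atol=1e-10)


def test_log10_autoscale_pareto_variance():
    rng = np.random.default_rng(1)
    X = _df(10.0 ** rng.normal(0, 1, size=(4, 15)))
    out = mb.log10_autoscale(X, scaling="pareto")
    L = np.log10(X)
    sd = L.std(axis=1, ddof=0)
    np.testing.assert_allclose(out.std(axis=1, ddof=0), np.sqrt(sd), rtol=1e-9)
    with pytest.raises(ValueError, match="unknown scaling"):
        mb.log10_autoscale(X, scaling="weird")


def test_log10_requires_positive_observed():
    with pytest.raises(ValueError, match="positive"):
        mb.log10_autoscale(_df([[0.0, 1.0]]))
    with pytest.raises(ValueError, match="observed"):
        mb.log10_autoscale(_df([[np.nan, 1.0]]))


# ---------------------------------------------------------------------------
# PLS-DA and VIP
# ---------------------------------------------------------------------------

def _two_class_data(seed=0, n=30, p=8, shift=2.0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(2 * n, p))
    X[n:, :2] += shift
    y = np.array(["A"] * n + ["B"] * n)
    return X, y


def test_plsda_separates_shifted_classes():
    X, y = _two_class_data(shift=3.0)
    model = PLSDA(n_components=2, cv=5).fit(X, y)
    assert (model.predict(X) == y).mean() > 0.95
    assert model.q2_ > 0.3
    # the informative features carry the largest VIPs
    top2 = set(np.argsort(model.vip_)[-2:])
    assert top2 == {0, 1}


def test_plsda_matches_sklearn_pls_regression():
    """Scores/weights agree with sklearn's NIPALS PLS2 on one-hot targets,
    up to per-component sign."""
    from sklearn.cross_decomposition import PLSRegression
    X, y = _two_class_data(seed=3)
    model = PLSDA(n_components=3).fit(X, y)
    Y = np.column_stack([(y == c).astype(float) for c in model.classes_])
    ref = PLSRegression(n_components=3, scale=False).fit(
        X - X.mean(axis=0), Y - Y.mean(axis=0))
    for a in range(3):
        w_ours = model.x_weights_[:, a]
        w_ref = ref.x_weights_[:, a]
        sign = np.sign(w_ours @ w_ref)
        np.testing.assert_allclose(w_ours, sign * w_ref, atol=1e-10)
        np.testing.assert_allclose(model.x_scores_[:, a],
                                   sign * ref.x_scores_[:, a], atol=1e-8)


def test_plsda_explained_variance_non_increasing():
    X, y = _two_class_data(seed=5, p=12)
    model = PLSDA(n_components=4).fit(X, y)
    ev = model.explained_y_variance_
    assert (np.diff(ev) <= 1e-9).all()
    assert ev.sum() <= 1.0 + 1e-9


def test_vip_mean_square_is_one_and_symmetry():
    X, y = _two_class_data(seed=7)
    model = PLSDA(n_components=2).fit(X, y)
    assert np.mean(model.vip_ ** 2) == pytest.approx(1.0, abs=1e-10)
    # a matrix with two exchangeable informative features gives equal VIPs
    rng = np.random.default_rng(11)
    n = 40
    z = np.repeat([0.0, 2.0], n)
    Xs = np.column_stack([z + rng.normal(scale=1e-6, size=2 * n),
                          z + rng.normal(scale=1e-6, size=2 * n),
                          rng.normal(size=2 * n)])
    ms = PLSDA(n_components=1).fit(Xs, np.repeat(["A", "B"], n))
    assert ms.vip_[0] == pytest.approx(ms.vip_[1], rel=1e-3)
    assert ms.vip_[0] > 1.0 > ms.vip_[2]


def test_vip_single_feature_is_one():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(20, 1)) + np.repeat([0.0, 1.0], 10)[:, None]
    model = PLSDA(n_components=1).fit(X, np.repeat(["A", "B"], 10))
    assert model.vip_[0] == pytest.approx(1.0, abs=1e-10)


# ---------------------------------------------------------------------------
# Differential calling
# ---------------------------------------------------------------------------

def test_differential_calls_require_both_gates():
    # feature 0: strong F1 shift (called in F1 comparisons); others null
    X, design = gaussian_groups((0.0, 3.0, 0.0), n=(20, 20, 20), seed=9,
                                n_features=6)
    calls = mb.differential_metabolites(X, design, vip_threshold=1.0, alpha=0.05)
    by = calls.set_index(["metabolite_id", "comparison"])
    assert by.loc[("f0", "F1vP2"), "called"]
    # P1vP2: VIP > 1 on noise but p = 0.26 -> the p gate blocks the call
    assert by.loc[("f0", "P1vP2"), "vip"] > 1.0
    assert not by.loc[("f0", "P1vP2"), "called"]
    # F1vP1: p ~ 1e-7 but VIP = 0.95 -> the VIP gate blocks the call
    assert by.loc[("f0", "F1vP1"), "p_value"] < 0.05
    assert not by.loc[("f0", "F1vP1"), "called"]
    called = calls[calls["called"]]
    assert ((called["vip"] > 1.0) & (called["p_value"] < 0.05)).all()
    assert set(called.loc[called["comparison"] == "F1vP1", "direction"]) <= {"up"}


def test_differential_threshold_is_strict():
    X, design = gaussian_groups((0.0, 3.0, 0.0), n=(20, 20, 20), seed=9,
                                n_features=6)
    calls = mb.differential_metabolites(X, design, vip_threshold=np.inf)
    assert not calls["called"].any()


def test_differential_summary_counts():
    calls = pd.DataFrame({
        "metabolite_id": ["a", "b", "c", "d"],
        "comparison": ["F1vP1"] * 3 + ["F1vP2"],
        "direction": ["up", "down", "up", "up"],
        "called": [True, True, False, True],
        "vip": 1.5, "p_value": 0.01,
    })
    s = mb.differential_summary(calls)
    assert s.loc["F1vP1"].to_dict() == {"n_called": 2, "n_up": 1, "n_down": 1}
    assert s.loc["F1vP2", "n_called"] == 1


# ---------------------------------------------------------------------------
# Origin partition
# ---------------------------------------------------------------------------

def test_source_partition_counts_and_overlap():
    ann = pd.DataFrame({
        "metabolite_id": ["a", "b", "c"],
        "origin": ["host", "microbiota", "co_metabolism"],
    })
    part = mb.source_partition(["a", "b", "c"], ann)
    assert part["counts"]["host"] == 2          # a + co-metabolized c
    assert part["counts"]["microbiota"] == 2    # b + co-metabolized c
    assert part["overlap"] == ["c"]
    assert part["counts"]["unknown"] == 0


def test_source_partition_unknown_and_multi_origin():
    ann = pd.DataFrame({"metabolite_id": ["a", "b"],
                        "origin": ["host|other", "weird"]})
    part = mb.source_partition(["a", "b", "zz"], ann)
    assert "a" in part["host"] and "a" in part["other"]
    assert set(part["unknown"]) == {"b", "zz"}


# ---------------------------------------------------------------------------
# End-to-end preprocessing audit
# ---------------------------------------------------------------------------

def test_preprocess_audit_is_monotone(tiny_study):
    X, audit = mb.preprocess(tiny_study.metabolite_intensities,
                             tiny_study.design, tiny_study.annotations)
    keys = ["input", "after_level_filter", "after_missingness_filter",
            "after_imputation", "after_log10_autoscale"]
    vals = [audit[k] for k in keys]
    assert vals[0] == 60
    assert all(a >= b for a, b in zip(vals, vals[1:]))
    assert X.shape[0] == vals[-1]
    assert not X.isna().any().any()
    np.testing.assert_allclose(X.mean(axis=1), 0.0, atol=1e-9)
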