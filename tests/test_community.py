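"""Community analysis: filtering, CLR, diversity, Bray-Curtis, NMDS,
phylum summaries and co-occurrence networks."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import networkx as nx
from heterosim import community as cm
from heterosim._nmds import NMDS, kruskal_stress
from heterosim.design import GROUP_ALIASES
from heterosim.simulate import generate_design


def _df(arr, prefix="f"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(arr, index=[f"{prefix}{i}" for i in range(arr.shape[0])],
                        columns=[f"s{j}" for j in range(arr.shape[1])])


# ---------------------------------------------------------------------------
# Prevalence filter / relative abundance / CLR
# ---------------------------------------------------------------------------

def test_prevalence_filter_strict_at_threshold():
    counts = _df(np.vstack([
        np.ones(10),                          # 10/10 -> kept
        [1] * 6 + [0] * 4,                    # exactly 60% -> removed
        [1] * 7 + [0] * 3,                    # 70% -> kept
    ]))
    out = cm.prevalence_filter(counts, 0.6)
    assert list(out.index) == ["f0", "f2"]


def test_relative_abundance_closure_and_zero_sample():
    counts = _df([[2.0, 0.0], [2.0, 5.0]])
    rel = cm.relative_abundance(counts)
    np.testing.assert_allclose(rel["s0"], [0.5, 0.5])
    np.testing.assert_allclose(rel["s1"], [0.0, 1.0])
    np.testing.assert_allclose(rel.sum(axis=0), 1.0, atol=1e-12)
    with pytest.raises(ValueError, match="s1"):
        cm.relative_abundance(_df([[1.0, 0.0], [1.0, 0.0]]))


def test_clr_hand_example_and_zero_sum():
    prop = _df([[0.8], [0.2]])
    out = cm.clr_transform(prop)
    np.testing.assert_allclose(out["s0"], [np.log(2), -np.log(2)], atol=1e-12)
    uniform = _df([[0.25]] * 4)
    np.testing.assert_allclose(cm.clr_transform(uniform).to_numpy(), 0.0, atol=1e-12)


@settings(derandomize=True, max_examples=20)
@given(scale=st.floats(0.01, 1000.0))
def test_clr_invariant_to_sample_rescaling(scale):
    rng = np.random.default_rng(5)
    counts = _df(rng.integers(0, 50, size=(8, 4)) + 0.0)
    counts.iloc[:, 0] += 1  # keep a nonzero sample
    a = cm.clr_transform(cm.relative_abundance(counts + 1))
    scaled = (counts + 1).copy()
    scaled.iloc[:, 0] *= scale
    b = cm.clr_transform(cm.relative_abundance(scaled))
    np.testing.assert_allclose(a.to_numpy(), b.to_numpy(), atol=1e-9)
    assert np.abs(a.sum(axis=0)).max() < 1e-10


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------

def test_gini_simpson_values():
    prop = _df([[1.0, 0.5, 0.25], [0.0, 0.25, 0.25], [0.0, 0.25, 0.5]])
    gs = cm.gini_simpson(prop)
    np.testing.assert_allclose(gs, [0.0, 0.625, 1 - (0.0625 + 0.0625 + 0.25)])
    k = 7
    even = _df(np.full((k, 1), 1.0 / k))
    assert cm.gini_simpson(even).iloc[0] == pytest.approx(1 - 1 / k)


def test_observed_richness_and_scale_invariance():
    counts = _df([[0.0, 1.0], [0.0, 0.0], [0.0, 3.0]])
    rich = cm.observed_richness(counts)
    assert list(rich) == [0, 2]
    assert list(cm.observed_richness(counts * 10)) == [0, 2]


def test_diversity_group_shift_detected_with_high_power():
    """A one-SD evenness shift in the hybrid group is detected by the
    pairwise Wilcoxon on Gini-Simpson at n = 85/group."""
    design = generate_design((85, 85, 85), 0)
    n_sig = 0
    n_seeds = 10
    for seed in range(n_seeds):
        rng = np.random.default_rng(100 + seed)
        logs = rng.normal(0, 1.0, size=(50, 255))
        # F1 samples get one dominant genus -> lower evenness
        f1 = (design["group"] == "F1").to_numpy()
        logs[0, f1] += 2.5
        rel = _df(np.exp(logs))
        rel.columns = design["sample_id"].tolist()
        rel = cm.relative_abundance(rel)
        div = cm.gini_simpson(rel)
        res = cm.diversity_tests(div, design)
        n_sig += res.loc["F1vP1", "p_value"] < 0.05
    assert n_sig / n_seeds > 0.8


# ---------------------------------------------------------------------------
# Bray-Curtis and NMDS
# ---------------------------------------------------------------------------

def test_bray_curtis_values_and_bounds():
    X = _df(np.array([[2.0, 0.0, 1.0], [2.0, 2.0, 1.0], [0.0, 2.0, 1.0]]))
    D = cm.bray_curtis(X)
    assert D.loc["s0", "s1"] == pytest.approx(4 / 8)
    assert D.loc["s0", "s0"] == 0.0
    disjoint = _df([[1.0, 0.0], [0.0, 1.0]])
    assert cm.bray_curtis(disjoint).iloc[0, 1] == pytest.approx(1.0)
    assert (D.to_numpy() <= 1.0 + 1e-12).all() and (D.to_numpy() >= 0).all()
    with pytest.raises(ValueError, match="all-zero"):
        cm.bray_curtis(_df([[0.0, 0.0], [0.0, 0.0]]))


def test_nmds_perfect_planar_configuration():
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(9, 2))
    D = pd.DataFrame(np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1)))
    model = cm.nmds(D, k=2, seed=0)
    assert model.stress_ < 1e-3
    assert model.converged_


def test_nmds_stress_nesting_and_reference_agreement():
    from sklearn.manifold import MDS
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(20, 5))
    D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    Ddf = pd.DataFrame(D)
    m2 = cm.nmds(Ddf, k=2, n_restarts=4, seed=0)
    m3 = cm.nmds(Ddf, k=3, n_restarts=4, seed=0)
    assert m3.stress_ <= m2.stress_ + 1e-9
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        ref = MDS(n_components=2, metric=False, dissimilarity="precomputed",
                  n_init=4, random_state=0, max_iter=500).fit(D)
    # compare via the same stress-1 evaluator on both embeddings
    ref_stress = kruskal_stress(D, ref.embedding_)
    assert abs(m2.stress_ - ref_stress) < 0.01


def test_nmds_input_validation():
    with pytest.raises(ValueError):
        NMDS(n_components=2).fit(np.zeros((3, 3)))  # too few samples


# ---------------------------------------------------------------------------
# Phylum summary
# ---------------------------------------------------------------------------

def test_phylum_summary_single_and_mixed():
    design = generate_design((3, 3, 3), 0)
    counts = pd.DataFrame(np.ones((2, 9)), index=["g0", "g1"],
                          columns=design["sample_id"].tolist())
    tax_one = pd.DataFrame({"genus": ["g0", "g1"], "phylum": ["Firmicutes"] * 2})
    out = cm.phylum_summary(counts, tax_one, design)
    np.testing.assert_allclose(out["Firmicutes"], 1.0)
    tax_two = pd.DataFrame({"genus": ["g0", "g1"],
                            "phylum": ["Firmicutes", "Bacteroidota"]})
    out2 = cm.phylum_summary(counts, tax_two, design)
    np.testing.assert_allclose(out2.to_numpy(), 0.5)
    np.testing.assert_allclose(out2.sum(axis=1), 1.0)
    assert set(out2.index) == set(GROUP_ALIASES.values())


def test_phylum_summary_is_mean_of_sample_compositions():
    design = generate_design((4, 4, 4), 0)
    rng = np.random.default_rng(0)
    counts = pd.DataFrame(rng.integers(1, 20, size=(3, 12)).astype(float),
                          index=["g0", "g1", "g2"],
                          columns=design["sample_id"].tolist())
    tax = pd.DataFrame({"genus": ["g0", "g1", "g2"],
                        "phylum": ["A", "A", "B"]})
    out = cm.phylum_summary(counts, tax, design)
    rel = cm.relative_abundance(counts)
    p1_cols = design.loc[design["group"] == "P1", "sample_id"]
    expected_B = rel.loc["g2", p1_cols].mean()
    assert out.loc["CC", "B"] == pytest.approx(expected_B)


# ---------------------------------------------------------------------------
# Co-occurrence networks
# ---------------------------------------------------------------------------

def brute_force_edges(X: pd.DataFrame, r_min, q_max):
    """O(p^2) per-pair recomputation with scipy, BH over all pairs."""
    from statsmodels.stats.multitest import multipletests
    ids = list(X.index)
    pairs, ps, rs = [], [], []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            r, p = sps.spearmanr(X.iloc[i], X.iloc[j])
            pairs.append((ids[i], ids[j]))
            ps.append(p)
            rs.append(r)
    q = multipletests(ps, method="fdr_bh")[1]
    return {pair for pair, r, qq in zip(pairs, rs, q)
            if abs(r) > r_min and qq < q_max}


def test_network_edges_match_brute_force_oracle():
    rng = np.random.default_rng(4)
    base = rng.normal(size=(10, 30))
    base[1] = base[0] * 0.9 + rng.normal(scale=0.3, size=30)
    base[2] = -base[0] + rng.normal(scale=0.2, size=30)
    X = _df(base, prefix="g")
    net = cm.cooccurrence_network(X, 0.4, 0.05)
    got = {(s, t) for s, t in zip(net.edges["source"], net.edges["target"])}
    assert got == brute_force_edges(X, 0.4, 0.05)
    # every retained edge satisfies the strict thresholds
    assert (net.edges["rho"].abs() > 0.4).all()
    assert (net.edges["q"] < 0.05).all()


def test_network_null_edge_count_within_fdr_bounds():
    rng = np.random.default_rng(6)
    X = _df(rng.normal(size=(50, 100)), prefix="g")
    net = cm.cooccurrence_network(X, 0.0, 0.05)  # FDR gate only
    # under the global null BH yields discoveries with probability ~alpha
    assert net.n_edges <= 5


def test_monotone_pair_always_connected():
    rng = np.random.default_rng(7)
    x = rng.normal(size=20)
    X = _df(np.vstack([x, np.exp(x), rng.normal(size=20)]), prefix="g")
    net = cm.cooccurrence_network(X, 0.4, 0.05)
    assert {("g0", "g1")} <= {(s, t) for s, t in
                              zip(net.edges["source"], net.edges["target"])}


def test_network_topology_metrics():
    tri = nx.complete_graph(3)
    topo = cm.network_topology(tri)
    assert topo["density"] == pytest.approx(1.0)
    assert topo["mean_clustering"] == pytest.approx(1.0)
    path = nx.path_graph(3)
    assert cm.network_topology(path)["density"] == pytest.approx(2 / 3)
    two_tri = nx.disjoint_union(nx.complete_graph(3), nx.complete_graph(3))
    assert cm.network_topology(two_tri)["modularity"] == pytest.approx(0.5)
    with pytest.warns(UserWarning):
        empty = cm.network_topology(nx.empty_graph(3))
    assert empty["n_edges"] == 0
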