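"""Unit tests for community-ecology analytics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from mesotox import community as cm


# ---------------------------------------------------------------------------
# Shannon diversity


@pytest.mark.parametrize("counts,expected", [
    ([25, 25, 25, 25], np.log(4)),
    ([100], 0.0),
    ([300, 100], -(0.75 * np.log(0.75) + 0.25 * np.log(0.25))),
])
def test_shannon_values(counts, expected):
    assert cm.shannon_index(np.array(counts)) == pytest.approx(expected, abs=1e-10)


def test_shannon_uniform_is_maximal(rng):
    k = 7
    uniform = cm.shannon_index(np.full(k, 10.0))
    for _ in range(50):
        w = rng.dirichlet(np.ones(k)) * 1000
        assert cm.shannon_index(w) <= uniform + 1e-12
    with pytest.raises(ValueError):
        cm.shannon_index(np.zeros(3))


# ---------------------------------------------------------------------------
# Bray-Curtis


def test_bray_curtis_examples():
    mat = pd.DataFrame([[2.0, 0.0], [1.0, 1.0], [2.0, 0.0], [0.0, 5.0]],
                       index=list("abcd"))
    D = cm.bray_curtis(mat)
    assert D.loc["a", "c"] == 0.0
    assert D.loc["a", "d"] == 1.0          # disjoint taxa
    assert D.loc["a", "b"] == pytest.approx(0.5)  # (1+1)/(3+1)


def test_bray_curtis_metric_properties(rng):
    mat = rng.integers(0, 50, size=(12, 8)).astype(float) + 0.1
    D = cm.bray_curtis(pd.DataFrame(mat)).to_numpy()
    assert np.allclose(D, D.T)
    assert np.allclose(np.diag(D), 0.0)
    assert np.all((D >= 0) & (D <= 1))
    with pytest.raises(ValueError):
        cm.bray_curtis(pd.DataFrame([[0.0, 0.0], [1.0, 2.0]]))


# ---------------------------------------------------------------------------
# NMDS


def test_nmds_exact_embedding_has_near_zero_stress(rng):
    pts = rng.normal(size=(12, 2))
    D = squareform(pdist(pts))
    res = cm.nmds(pd.DataFrame(D), k=2, n_starts=8, seed=0)
    assert res.stress < 1e-3
    assert res.converged


def test_nmds_stress_matches_independent_recomputation(rng):
    mat = rng.integers(1, 60, size=(10, 6)).astype(float)
    D = cm.bray_curtis(pd.DataFrame(mat))
    res = cm.nmds(D, k=2, n_starts=10, seed=3)
    # independent Kruskal stress-1: sqrt(sum (d - dhat)^2 / sum d^2) with dhat
    # the monotone (PAVA) regression of configuration distances on
    # dissimilarities, re-implemented here from the pool-adjacent-violators
    # algorithm rather than reusing the package's isotonic-regression path
    X = res.coordinates.to_numpy()
    iu = np.triu_indices(10, 1)
    d_conf = squareform(pdist(X))[iu]
    diss = D.to_numpy()[iu]
    order = np.argsort(diss, kind="stable")
    y = d_conf[order]
    blocks = [[v, 1.0] for v in y]  # (mean, weight) pools
    merged = []
    for b in blocks:
        merged.append(b)
        while len(merged) > 1 and merged[-2][0] > merged[-1][0]:
            m2, m1 = merged.pop(), merged.pop()
            w = m1[1] + m2[1]
            merged.append([(m1[0] * m1[1] + m2[0] * m2[1]) / w, w])
    dhat_sorted = np.concatenate([[m[0]] * int(m[1]) for m in merged])
    dhat = np.empty_like(y)
    dhat[np.arange(len(order))] = dhat_sorted
    resid = ((y - dhat) ** 2).sum()
    stress = np.sqrt(resid / (d_conf ** 2).sum())
    assert res.stress == pytest.approx(stress, abs=1e-8)


def test_nmds_stress_invariant_to_rigid_motions(rng):
    """Stress depends only on the configuration's interpoint distances."""
    pts = rng.normal(size=(9, 2))
    D = squareform(pdist(rng.normal(size=(9, 3))))
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    s1 = cm._stress1(D, pts)
    s2 = cm._stress1(D, 3.0 * pts @ R + 5.0)
    assert s1 == pytest.approx(s2, rel=1e-9)


def test_nmds_deterministic_under_seed(rng):
    mat = rng.integers(1, 60, size=(10, 6)).astype(float)
    D = cm.bray_curtis(pd.DataFrame(mat))
    r1 = cm.nmds(D, n_starts=5, seed=11)
    r2 = cm.nmds(D, n_starts=5, seed=11)
    assert r1.stress == r2.stress
    assert np.allclose(r1.coordinates, r2.coordinates)


# ---------------------------------------------------------------------------
# PERMANOVA


def test_permanova_euclidean_two_groups_equals_anova_f(rng):
    """With Euclidean distance on 1-D coordinates, pseudo-F is the classical
    one-way ANOVA F statistic."""
    a, b = rng.normal(0, 1, 10), rng.normal(1.2, 1, 12)
    vals = np.concatenate([a, b])
    groups = np.array(["a"] * 10 + ["b"] * 12)
    D = np.abs(vals[:, None] - vals[None, :])
    res = cm.permanova(pd.DataFrame(D), groups, n_perm=99, seed=0)
    F_classic = stats.f_oneway(a, b).statistic
    assert res.pseudo_f == pytest.approx(F_classic, rel=1e-10)
    assert 0 <= res.r2 <= 1


def test_permanova_matches_scikit_bio(rng):
    """Independent oracle: scikit-bio's PERMANOVA on the same matrix."""
    skbio_stats = pytest.importorskip("skbio.stats.distance")
    mat = rng.integers(1, 80, size=(15, 7)).astype(float)
    D = cm.bray_curtis(pd.DataFrame(mat, index=[f"t{i}" for i in range(15)]))
    groups = np.repeat(["a", "b", "c"], 5)
    res = cm.permanova(D, groups, n_perm=99, seed=1)
    dm = skbio_stats.DistanceMatrix(D.to_numpy(), ids=list(D.index))
    sk = skbio_stats.permanova(dm, grouping=list(groups), permutations=99)
    assert res.pseudo_f == pytest.approx(float(sk["test statistic"]), rel=1e-10)


def test_permanova_p_resolution_and_guards(rng):
    mat = rng.integers(1, 80, size=(12, 5)).astype(float)
    D = cm.bray_curtis(pd.DataFrame(mat))
    groups = np.repeat(["a", "b"], 6)
    res = cm.permanova(D, groups, n_perm=99, seed=2)
    assert res.p >= 1.0 / (99 + 1)
    with pytest.raises(ValueError, match="singleton"):
        cm.permanova(D, np.array(["a"] * 11 + ["b"]), n_perm=99, seed=2)


def test_permanova_detects_separated_groups(rng):
    base = rng.integers(5, 20, size=(12, 6)).astype(float)
    base[6:, :2] += 200.0  # group b dominated by first two taxa
    D = cm.bray_curtis(pd.DataFrame(base))
    res = cm.permanova(D, np.repeat(["a", "b"], 6), n_perm=199, seed=3)
    assert res.p <= 0.01
    assert res.r2 > 0.3


# ---------------------------------------------------------------------------
# dispersion homogeneity


def test_dispersion_positive_control(rng):
    """One group's points scaled x3 around its centroid -> small p."""
    a = rng.normal(0, 0.5, size=(10, 3))
    b = rng.normal(0, 1.5, size=(10, 3))
    pts = np.vstack([a, b])
    D = squareform(pdist(pts))
    p, disp = cm.dispersion_homogeneity(pd.DataFrame(D),
                                        np.repeat(["a", "b"], 10),
                                        n_perm=199, seed=4)
    assert p < 0.05
    assert disp["b"] > disp["a"]


def test_dispersion_null_is_calibrated(rng):
    """Groups drawn from one dispersion: rejection rate ~ alpha."""
    rej = 0
    n_sim = 120
    for s in range(n_sim):
        pts = rng.normal(size=(12, 3))
        D = squareform(pdist(pts))
        p, _ = cm.dispersion_homogeneity(pd.DataFrame(D),
                                         np.repeat(["a", "b", "c"], 4),
                                         n_perm=99, seed=s)
        rej += p <= 0.05
    assert rej / n_sim < 0.15


# ---------------------------------------------------------------------------
# diversity contrasts, dominance, chlorophyll


def test_diversity_contrasts_recover_construction(rng):
    """Constructed shift at day 7 only: contrasts flag it, day 0 stays null."""
    rows = []
    for day, shift in ((0, 0.0), (7, -0.8)):
        for treat in (0.0, 100.0):
            for rep in range(8):
                H = 2.0 + (shift if treat > 0 else 0.0) + rng.normal(0, 0.1)
                rows.append({"H": H, "treatment": treat, "day": day})
    df = pd.DataFrame(rows)
    cells, contrasts = cm.diversity_lm_contrasts(df["H"], df["treatment"],
                                                 df["day"], control_label=0.0)
    c0 = contrasts[(contrasts["day"] == 0)].iloc[0]
    c7 = contrasts[(contrasts["day"] == 7)].iloc[0]
    assert c7["p_holm"] < 0.001
    assert c7["estimate"] == pytest.approx(-0.8, abs=0.15)
    assert c0["p_holm"] > 0.05


def test_dominance_share_exact_fractions():
    counts = pd.DataFrame({"A": [90.0, 10.0], "B": [10.0, 90.0]},
                          index=["t1", "t2"])
    treat = pd.Series(["x", "y"], index=["t1", "t2"])
    matrix = cm.CommunityMatrix(counts=counts, day=7, treatment=treat)
    share = cm.dominance_share(matrix, ["A"])
    assert share["x"] == pytest.approx(0.9)
    assert share["y"] == pytest.approx(0.1)
    assert cm.dominance_share(matrix, [])["x"] == 0.0
    single = cm.CommunityMatrix(counts=pd.DataFrame({"A": [50.0]}, index=["t1"]),
                                day=7, treatment=pd.Series(["x"], index=["t1"]))
    assert cm.dominance_share(single, ["A"])["x"] == 1.0
    with pytest.raises(KeyError):
        cm.dominance_share(matrix, ["Z"])


def test_chlorophyll_biomass_r2(rng):
    x = rng.uniform(1, 50, 60)
    y = 3.0 * x + rng.normal(0, 20, 60)
    r2, p = cm.chlorophyll_biomass_r2(x, y)
    assert 0 < r2 <= 1 and p < 0.05
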