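"""PCA, OPLS-DA (fit, CV, permutation, VIP) and RDA variance
partitioning."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from grapemet.chemometrics import OPLSDA, RDA, pca, vip_ranking
from grapemet.simulate import make_varpart_dataset


def test_pca_rank_one_matrix():
    rng = np.random.default_rng(0)
    X = np.outer(rng.normal(size=30), rng.normal(size=10))
    with pytest.warns(UserWarning, match="rank"):
        scores, loadings, evr = pca(X, n_components=3)
    assert evr[0] == pytest.approx(1.0)


def test_pca_orthonormal_loadings_and_cluster_separation():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(40, 12))
    X[:20] += 6.0  # two clusters along the grand diagonal
    scores, loadings, evr = pca(X, n_components=3)
    assert np.allclose(loadings.T @ loadings, np.eye(3), atol=1e-9)
    from sklearn.metrics import silhouette_score

    sil = silhouette_score(scores[:, :1], [0] * 20 + [1] * 20)
    assert sil > 0.5
    assert evr.sum() <= 1.0 + 1e-12
    assert (np.diff(evr) <= 1e-12).all()


def test_opls_zero_orthogonal_equals_pls1():
    """With no orthogonal filtering the predictive scores coincide with a
    one-component PLS regression (sklearn as independent reference)."""
    from sklearn.cross_decomposition import PLSRegression

    rng = np.random.default_rng(2)
    X = rng.normal(size=(30, 15))
    y = np.where(rng.random(30) > 0.5, "a", "b")
    model = OPLSDA(X, y, n_orthogonal=0, cv_folds=3, n_permutations=9)
    res = model.fit(seed=0)
    yv = np.where(y == model.classes_[1], 1.0, -1.0)
    sk = PLSRegression(n_components=1, scale=False).fit(X, yv)
    t_sk = sk.x_scores_[:, 0]
    t = res.scores
    sign = np.sign(t_sk @ t)
    assert np.allclose(t, sign * t_sk, atol=1e-8)


def test_vip_normalization_identity(marker_study):
    res = OPLSDA(
        marker_study["scaled"],
        marker_study["design"]["variety"].to_numpy(),
        n_permutations=9,
    ).fit(seed=3)
    assert (res.vip**2).mean() == pytest.approx(1.0, abs=1e-9)
    assert (res.vip >= 0).all()


def test_opls_null_labels_fail_validation():
    rng = np.random.default_rng(4)
    X = rng.normal(size=(40, 100))
    y = np.array(["a", "b"] * 20)  # independent of X
    res = OPLSDA(X, y, n_permutations=99).fit(seed=5)
    assert res.q2 <= 0.0
    assert res.p_permutation > 0.05


def test_orthogonal_components_never_decrease_r2y():
    rng = np.random.default_rng(6)
    X = rng.normal(size=(30, 20))
    X[:15] += 1.0
    y = np.array(["a"] * 15 + ["b"] * 15)
    r2 = []
    for k in (0, 1, 2):
        r2.append(OPLSDA(X, y, n_orthogonal=k, cv_folds=3,
                         n_permutations=9).fit(seed=7).r2y)
    assert r2[0] <= r2[1] + 1e-10 <= r2[2] + 2e-10


def test_permutation_p_uniform_under_null():
    """Over 200 null datasets the permutation p-value is uniform
    (Kolmogorov band at alpha = 0.01)."""
    rng = np.random.default_rng(8)
    pvals = []
    for b in range(200):
        X = rng.normal(size=(24, 15))
        y = np.array(["a", "b"] * 12)
        res = OPLSDA(X, y, cv_folds=4, n_permutations=19).fit(
            seed=int(rng.integers(2**31)))
        pvals.append(res.p_permutation)
    pvals = np.sort(pvals)
    grid = np.arange(1, 201) / 200
    d = np.max(np.abs(pvals - grid))
    assert d < 1.628 / np.sqrt(200)


def test_single_class_rejected():
    X = np.random.default_rng(9).normal(size=(10, 5))
    with pytest.raises(ValueError, match="two-class"):
        OPLSDA(X, np.array(["a"] * 10))


def test_vip_ranking_breakdown(marker_study):
    res = OPLSDA(
        marker_study["scaled"],
        marker_study["design"]["variety"].to_numpy(),
        n_permutations=9,
    ).fit(seed=10)
    fm = marker_study["features"]
    annot = pd.DataFrame(
        {"formula": "", "class": "CHO"}, index=fm.features.index
    )
    table, pct = vip_ranking(res, annot, threshold=1.0)
    assert (table["vip"] > 1.0).all()
    assert list(table["vip"]) == sorted(table["vip"], reverse=True)
    assert pct.sum() == pytest.approx(100.0)


def test_all_equal_vips_select_none():
    rng = np.random.default_rng(11)
    # one informative direction shared equally by all features
    y = np.array(["a", "b"] * 10)
    base = np.where(y == "a", 1.0, -1.0)
    X = np.outer(base, np.ones(6)) + rng.normal(0, 1e-6, size=(20, 6))
    res = OPLSDA(X, y, n_orthogonal=0, cv_folds=3, n_permutations=9).fit(seed=12)
    assert np.allclose(res.vip.to_numpy(), 1.0, atol=1e-3)
    table, _ = vip_ranking(res, threshold=1.0 + 1e-3)
    assert len(table) == 0


# -- RDA -------------------------------------------------------------------


def _toy_rda():
    rng = np.random.default_rng(13)
    Y = rng.normal(size=(8, 5))
    factors = pd.DataFrame({"f": ["a", "a", "b", "b", "c", "c", "a", "b"]})
    return Y, factors


def test_rda_equals_regression_then_pca_oracle():
    """Canonical eigenvalues equal the PCA eigenvalues of the fitted
    values from an explicit dummy regression (naive oracle)."""
    Y, factors = _toy_rda()
    rr = RDA(Y, factors).fit(seed=0, n_permutations=9)
    # oracle: explicit hat-matrix regression, then eigen of fitted values
    D = pd.get_dummies(factors["f"], drop_first=True, dtype=float).to_numpy()
    D = D - D.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    H = D @ np.linalg.pinv(D.T @ D) @ D.T
    fitted = H @ Yc
    eig = np.linalg.eigvalsh(fitted.T @ fitted / (Y.shape[0] - 1))[::-1]
    eig = eig[: len(rr.eigenvalues)]
    assert np.allclose(np.sort(rr.eigenvalues)[::-1], eig, atol=1e-9)
    # total constrained variance identity
    assert rr.eigenvalues.sum() == pytest.approx(
        (fitted**2).sum() / (Y.shape[0] - 1), abs=1e-9)
    # R2 identity
    assert rr.r2 == pytest.approx((fitted**2).sum() / (Yc**2).sum(), abs=1e-12)


def test_rda_matches_vegan_reference():
    """Cross-check R2, adjusted R2 and eigenvalues against vegan's rda()
    on a fixed small matrix (independent reference implementation)."""
    rng = np.random.default_rng(14)
    Y = rng.normal(size=(12, 4)).round(6)
    labels = ["a", "b", "c"] * 4
    rr = RDA(Y, pd.DataFrame({"f": labels})).fit(seed=0, n_permutations=9)
    script = f"""
    suppressMessages(library(vegan))
    Y <- matrix(c({','.join(str(v) for v in Y.flatten(order='F'))}), nrow=12)
    f <- factor(c({','.join(repr(l) for l in labels)}))
    m <- rda(Y ~ f)
    cat(RsquareAdj(m)$r.squared, RsquareAdj(m)$adj.r.squared,
        paste(m$CCA$eig, collapse=' '), sep='\\n')
    """
    try:
        out = subprocess.run(
            ["Rscript", "-e", script], capture_output=True, text=True,
            timeout=120,
        )
    except FileNotFoundError:
        pytest.skip("Rscript unavailable")
    assert out.returncode == 0, out.stderr
    lines = [l for l in out.stdout.strip().splitlines() if l]
    r2_v, adj_v = float(lines[0]), float(lines[1])
    eig_v = np.array([float(x) for x in lines[2].split()])
    assert rr.r2 == pytest.approx(r2_v, abs=1e-8)
    assert rr.adj_r2 == pytest.approx(adj_v, abs=1e-8)
    assert np.allclose(np.sort(rr.eigenvalues)[::-1],
                       np.sort(eig_v)[::-1], atol=1e-8)


def test_varpart_null_fractions_near_zero():
    rng = np.random.default_rng(15)
    Y = rng.normal(size=(100, 20))
    factors = pd.DataFrame({
        "variety": rng.choice(["a", "b"], 100),
        "region": rng.choice(["r1", "r2", "r3"], 100),
    })
    rr = RDA(Y, factors).fit(seed=1, n_permutations=99)
    for v in rr.partition.unique.values():
        assert abs(v) < 0.02
    assert rr.p_global > 0.01
    assert rr.partition.total() == pytest.approx(1.0, abs=1e-9)


def test_varpart_recovers_planted_fractions():
    Y, factors = make_varpart_dataset(7, 100, 50, variety_frac=0.16,
                                      region_frac=0.10)
    rr = RDA(Y, factors).fit(seed=2, n_permutations=199)
    assert rr.partition.unique["variety"] == pytest.approx(0.16, abs=0.03)
    assert rr.partition.unique["region"] == pytest.approx(0.10, abs=0.04)
    assert rr.p_marginal["variety"] < 0.01
    assert rr.partition.total() == pytest.approx(1.0, abs=1e-9)
    assert "unexplained" in rr.summary()


def test_varpart_three_factors_identity():
    rng = np.random.default_rng(16)
    Y = rng.normal(size=(60, 10))
    factors = pd.DataFrame({
        "variety": rng.choice(["a", "b"], 60),
        "region": rng.choice(["r1", "r2", "r3"], 60),
        "vintage": rng.choice(["2019", "2020", "2021"], 60),
    })
    rr = RDA(Y, factors).fit(seed=3, n_permutations=49)
    part = rr.partition
    assert len(part.unique) == 3 and len(part.shared) == 4
    assert part.total() == pytest.approx(1.0, abs=1e-9)
    for v in list(part.unique.values()) + list(part.shared.values()):
        assert -0.05 <= v <= 1.0
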