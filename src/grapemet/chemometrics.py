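"""Multivariate discrimination and variance decomposition.

This module follows the statsmodels idiom: a model object is built from
data, ``fit()`` returns a results object carrying estimates,
diagnostics and a ``summary()`` table.

* :func:`pca` — unsupervised overview (thin wrapper over an SVD of the
  centered matrix);
* :class:`OPLSDA` — two-class orthogonal projections to latent
  structures discriminant analysis, with one predictive component,
  k orthogonal components, cross-validated Q², label-permutation
  validation and combined VIP scores;
* :class:`RDA` — redundancy analysis (constrained ordination) of a
  response matrix on categorical factors, with permutation tests and
  adjusted-R² variance partitioning over up to three factors.

OPLS-DA separates the between-class direction from systematic variation
orthogonal to it. With a centered class indicator y, each orthogonal
round removes from X the component of its loading p that is not aligned
with the predictive weight w; the single predictive component is then a
plain PLS component of the filtered matrix. R²Y measures the fit, Q²
the cross-validated prediction, and the permutation p-value guards
against over-fitting, which for p ≫ n data is the main failure mode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .align import FeatureMatrix

__all__ = ["pca", "OPLSDA", "OPLSDAResults", "RDA", "RDAResults",
           "VariancePartition", "vip_ranking"]


def pca(X, n_components: int = 2):
    """PCA of a (transformed/scaled) matrix via SVD of the centered data.

    Returns ``(scores, loadings, explained_variance_ratio)``. Requesting
    more components than the matrix rank truncates with a warning.
    Accepts a :class:`FeatureMatrix` or an array.
    """
    if isinstance(X, FeatureMatrix):
        X = X.intensities.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    Xc = X - X.mean(axis=0)
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    tol = s.max() * max(Xc.shape) * np.finfo(float).eps if s.size else 0.0
    rank = int((s > tol).sum())
    if n_components > rank:
        warnings.warn(f"requested {n_components} components, rank is {rank}")
        n_components = rank
    # deterministic sign: largest-magnitude loading positive
    for k in range(n_components):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components].T
    total = (s**2).sum()
    evr = (s[:n_components] ** 2) / total if total > 0 else np.zeros(n_components)
    return scores, loadings, evr


# --------------------------------------------------------------------------
# OPLS-DA
# --------------------------------------------------------------------------


def _opls_core(X: np.ndarray, y: np.ndarray, n_orthogonal: int):
    """One-predictive-component OPLS on centered X, y.

    Returns dict with predictive (w, t, p, c) and per-orthogonal-round
    (w_o, t_o, p_o) arrays. Weight vectors are unit norm.
    """
    Xc = X.copy()
    W_o, T_o, P_o = [], [], []
    for _ in range(n_orthogonal):
        w = Xc.T @ y
        nw = np.linalg.norm(w)
        if nw == 0:
            break
        w /= nw
        t = Xc @ w
        p = Xc.T @ t / (t @ t)
        w_o = p - (w @ p) * w
        n_o = np.linalg.norm(w_o)
        if n_o < 1e-12:
            break
        w_o /= n_o
        t_o = Xc @ w_o
        denom = t_o @ t_o
        if denom < 1e-30:
            break
        p_o = Xc.T @ t_o / denom
        Xc -= np.outer(t_o, p_o)
        W_o.append(w_o)
        T_o.append(t_o)
        P_o.append(p_o)
    w = Xc.T @ y
    nw = np.linalg.norm(w)
    w = w / nw if nw > 0 else w
    t = Xc @ w
    tt = t @ t
    p = Xc.T @ t / tt if tt > 0 else np.zeros(X.shape[1])
    c = (y @ t) / tt if tt > 0 else 0.0
    return {"w": w, "t": t, "p": p, "c": c,
            "W_o": W_o, "T_o": T_o, "P_o": P_o}


def _opls_predict(model: dict, X: np.ndarray) -> np.ndarray:
    Xf = X.copy()
    for w_o, p_o in zip(model["W_o"], model["P_o"]):
        t_o = Xf @ w_o
        Xf -= np.outer(t_o, p_o)
    return (Xf @ model["w"]) * model["c"]


def _stratified_folds(y01: np.ndarray, k: int, rng: np.random.Generator
                      ) -> list[np.ndarray]:
    """Class-stratified fold assignment; returns list of test-index arrays."""
    folds: list[list[int]] = [[] for _ in range(k)]
    for cls in np.unique(y01):
        idx = np.flatnonzero(y01 == cls)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % k].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds]


class OPLSDA:
    """Two-class OPLS-DA model over a scaled feature matrix.

    Parameters
    ----------
    X : array or FeatureMatrix
        Samples × features, already log-transformed and Pareto-scaled.
    labels : sequence
        Two-class sample labels; the second sorted class is coded +1.
    n_orthogonal : int
        Orthogonal components (default 1); ``n_orthogonal="auto"``
        grows components while cross-validated Q² gains ≥ 0.01.
    cv_folds : int
        Stratified folds for Q² (default 7).
    n_permutations : int
        Label permutations for the validation p-value (default 500).
    """

    def __init__(self, X, labels, n_orthogonal: int | str = 1, cv_folds: int = 7,
                 n_permutations: int = 500):
        if isinstance(X, FeatureMatrix):
            self.feature_names = list(X.intensities.columns)
            X = X.intensities.to_numpy(dtype=float)
        else:
            X = np.asarray(X, dtype=float)
            self.feature_names = [f"x{j}" for j in range(X.shape[1])]
        labels = np.asarray(labels)
        classes = np.unique(labels)
        if len(classes) != 2:
            raise ValueError(f"OPLS-DA is two-class; got {len(classes)} class(es)")
        counts = np.array([(labels == c).sum() for c in classes])
        if counts.max() > 10 * counts.min():
            warnings.warn("class imbalance beyond 10:1; Q2 may be unstable")
        if counts.min() < cv_folds:
            raise ValueError("each class must have at least cv_folds samples")
        self.classes_ = classes
        self.y01 = (labels == classes[1]).astype(int)
        self.X = X
        self.n_orthogonal = n_orthogonal
        self.cv_folds = cv_folds
        self.n_permutations = n_permutations

    @classmethod
    def from_feature_matrix(cls, matrix: FeatureMatrix, label_col: str, **kw
                            ) -> "OPLSDA":
        if matrix.metadata is None or label_col not in matrix.metadata.columns:
            raise ValueError(f"metadata column {label_col!r} not available")
        labels = matrix.metadata[label_col].reindex(matrix.intensities.index)
        return cls(matrix, labels.to_numpy(), **kw)

    # ------------------------------------------------------------------
    def _q2(self, X: np.ndarray, y: np.ndarray, n_ortho: int,
            rng: np.random.Generator) -> float:
        y01 = (y > y.mean()).astype(int)
        folds = _stratified_folds(y01, self.cv_folds, rng)
        press = 0.0
        ss = 0.0
        for test_idx in folds:
            train = np.setdiff1d(np.arange(len(y)), test_idx)
            Xm = X[train].mean(axis=0)
            ym = y[train].mean()
            model = _opls_core(X[train] - Xm, y[train] - ym, n_ortho)
            yhat = _opls_predict(model, X[test_idx] - Xm) + ym
            press += ((y[test_idx] - yhat) ** 2).sum()
            ss += ((y[test_idx] - ym) ** 2).sum()
        return 1.0 - press / ss

    def fit(self, seed: int, n_orthogonal: int | str | None = None
            ) -> "OPLSDAResults":
        """Fit the model; ``seed`` drives CV folds and permutations."""
        n_ortho = self.n_orthogonal if n_orthogonal is None else n_orthogonal
        rng = np.random.default_rng(seed)
        X = self.X
        y = self.y01.astype(float)
        y = np.where(y > 0, 1.0, -1.0)

        if n_ortho == "auto":
            best, n_ortho = -np.inf, 0
            for k in range(0, 6):
                q2 = self._q2(X, y, k, np.random.default_rng(seed + 1))
                if q2 > best + 0.01:
                    best, n_ortho = q2, k
                else:
                    break

        Xm, ym = X.mean(axis=0), y.mean()
        Xc, yc = X - Xm, y - ym
        core = _opls_core(Xc, yc, int(n_ortho))
        t, p, c = core["t"], core["p"], core["c"]
        resid = yc - t * c
        ssy = float(yc @ yc)
        r2y = 1.0 - float(resid @ resid) / ssy
        ssx = float((Xc**2).sum())
        ssx_pred = float((t @ t) * (p @ p))
        ssx_orth = [float((t_o @ t_o) * (p_o @ p_o))
                    for t_o, p_o in zip(core["T_o"], core["P_o"])]
        r2x = (ssx_pred + sum(ssx_orth)) / ssx if ssx > 0 else 0.0

        q2 = self._q2(X, y, int(n_ortho), np.random.default_rng(seed + 1))

        # permutation validation: the null distribution of Q2 under
        # shuffled labels, with the add-one correction
        q2_perm = np.empty(self.n_permutations)
        for b in range(self.n_permutations):
            yp = rng.permutation(y)
            q2_perm[b] = self._q2(X, yp, int(n_ortho),
                                  np.random.default_rng(seed + 2 + b))
        p_perm = (float((q2_perm >= q2).sum()) + 1.0) / (self.n_permutations + 1.0)

        # combined VIP over predictive + orthogonal variation
        # (Galindo-Prieto "VIP total"): the predictive component is
        # weighted by the fractions of Y- and X-variance it explains,
        # each orthogonal component by its X-variance fraction alone
        # (orthogonal components explain no Y by construction).
        # Unit-norm weight vectors keep mean(VIP^2) = 1 exactly.
        ssy_pred = float(c * c * (t @ t))
        weights2 = [core["w"] ** 2] + [w_o**2 for w_o in core["W_o"]]
        share = [ssy_pred / ssy + ssx_pred / ssx] + [s / ssx for s in ssx_orth]
        nfeat = X.shape[1]
        num = sum(s * w2 for s, w2 in zip(share, weights2))
        vip = np.sqrt(nfeat * num / sum(share))

        return OPLSDAResults(
            model=self,
            n_orthogonal=int(n_ortho),
            weights=core["w"],
            loadings=p,
            scores=t,
            y_loading=float(c),
            ortho_weights=np.array(core["W_o"]) if core["W_o"] else np.empty((0, nfeat)),
            ortho_loadings=np.array(core["P_o"]) if core["P_o"] else np.empty((0, nfeat)),
            ortho_scores=np.array(core["T_o"]).T if core["T_o"] else np.empty((len(y), 0)),
            r2x=float(r2x),
            r2y=float(r2y),
            q2=float(q2),
            p_permutation=float(p_perm),
            q2_permuted=q2_perm,
            vip=pd.Series(vip, index=self.feature_names, name="VIP"),
            seed=seed,
        )


@dataclass
class OPLSDAResults:
    """Fitted OPLS-DA model: scores, quality metrics, VIP, validation."""

    model: OPLSDA
    n_orthogonal: int
    weights: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    y_loading: float
    ortho_weights: np.ndarray
    ortho_loadings: np.ndarray
    ortho_scores: np.ndarray
    r2x: float
    r2y: float
    q2: float
    p_permutation: float
    q2_permuted: np.ndarray
    vip: pd.Series
    seed: int

    def summary(self) -> str:
        cls0, cls1 = self.model.classes_
        lines = [
            "OPLS-DA results",
            "=" * 46,
            f"classes               {cls0} (-1) vs {cls1} (+1)",
            f"n samples             {len(self.scores)}",
            f"n features            {len(self.vip)}",
            f"components            1 predictive + {self.n_orthogonal} orthogonal",
            f"R2X (cum)             {self.r2x:.4f}",
            f"R2Y                   {self.r2y:.4f}",
            f"Q2 ({self.model.cv_folds}-fold CV)        {self.q2:.4f}",
            f"permutation p         {self.p_permutation:.4g} "
            f"({self.model.n_permutations} permutations)",
            f"seed                  {self.seed}",
        ]
        return "\n".join(lines)

    def write_report(self, directory, prefix: str = "oplsda") -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        with open(os.path.join(directory, f"{prefix}_report.txt"), "w") as fh:
            fh.write(self.summary() + "\n")
        self.vip.sort_values(ascending=False).to_csv(
            os.path.join(directory, f"{prefix}_vip.tsv"), sep="\t")
        pd.DataFrame(
            {"t_pred": self.scores,
             **{f"t_orth{k+1}": self.ortho_scores[:, k]
                for k in range(self.n_orthogonal)}}
        ).to_csv(os.path.join(directory, f"{prefix}_scores.tsv"), sep="\t",
                 index=False)


def vip_ranking(
    results: OPLSDAResults,
    annotations: pd.DataFrame | None = None,
    threshold: float = 1.0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Features with VIP above ``threshold``, ranked, with class breakdown.

    ``annotations``: optional per-feature table with ``formula`` and
    ``class`` columns (as produced by assignment). Returns the ranked
    marker table and the percentage class composition of the VIP set
    (percentages sum to 100 whenever the set is non-empty).
    """
    vip = results.vip.sort_values(ascending=False)
    selected = vip[vip > threshold]
    table = pd.DataFrame({"vip": selected})
    table["rank"] = np.arange(1, len(table) + 1)
    if annotations is not None:
        table = table.join(annotations.reindex(table.index)[["formula", "class"]])
    else:
        table["formula"] = ""
        table["class"] = ""
    counts = table["class"].replace("", "unannotated").value_counts()
    pct = 100.0 * counts / counts.sum() if len(table) else counts.astype(float)
    return table, pct


# --------------------------------------------------------------------------
# RDA and variance partitioning
# --------------------------------------------------------------------------


def _dummy_code(factors: pd.DataFrame) -> dict[str, np.ndarray]:
    """Treatment-coded (drop-first), centered design block per factor."""
    blocks = {}
    for col in factors.columns:
        d = pd.get_dummies(factors[col].astype(str), drop_first=True, dtype=float)
        Z = d.to_numpy()
        blocks[col] = Z - Z.mean(axis=0)
    return blocks


def _drop_collinear(Z: np.ndarray) -> np.ndarray:
    """Keep a maximal independent column subset (QR pivot order)."""
    if Z.shape[1] == 0:
        return Z
    from scipy.linalg import qr

    q, r, piv = qr(Z, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(Z.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < Z.shape[1]:
        warnings.warn("collinear factor columns dropped")
    keep = np.sort(piv[:rank])
    return Z[:, keep]


def _fit_stats(Y: np.ndarray, Z: np.ndarray) -> tuple[float, float, int]:
    """(R2, adjusted R2, rank) of the multivariate regression Y ~ Z."""
    n = Y.shape[0]
    ss_tot = float((Y**2).sum())
    if Z.shape[1] == 0 or ss_tot == 0:
        return 0.0, 0.0, 0
    coef, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
    fitted = Z @ coef
    r2 = float((fitted**2).sum()) / ss_tot
    m = int(rank)
    if n - m - 1 <= 0:
        raise ValueError("not enough samples for the requested factors")
    adj = 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)  # Ezekiel correction
    return r2, adj, m


class RDA:
    """Redundancy analysis of a response matrix on categorical factors.

    ``Y`` is the (transformed) samples × features matrix, centered
    internally; ``factors`` a DataFrame of up to three categorical
    columns (e.g. variety, region, vintage), dummy-coded internally.
    ``fit()`` runs the global and marginal permutation tests and the
    all-subsets adjusted-R² variance partition.
    """

    def __init__(self, Y, factors: pd.DataFrame):
        if isinstance(Y, FeatureMatrix):
            Y = Y.intensities.to_numpy(dtype=float)
        Y = np.asarray(Y, dtype=float)
        self.Y = Y - Y.mean(axis=0)
        self.factors = factors.reset_index(drop=True)
        if not 1 <= factors.shape[1] <= 3:
            raise ValueError("variance partitioning supports 1-3 factors")
        self.blocks = {k: _drop_collinear(v)
                       for k, v in _dummy_code(self.factors).items()}
        total_cols = sum(b.shape[1] for b in self.blocks.values())
        if Y.shape[0] <= total_cols + 2:
            raise ValueError("need n samples > total dummy columns + 2")

    def _design(self, names) -> np.ndarray:
        mats = [self.blocks[n] for n in names]
        if not mats:
            return np.empty((self.Y.shape[0], 0))
        return _drop_collinear(np.hstack(mats))

    @staticmethod
    def _pseudo_f(Y: np.ndarray, Z: np.ndarray) -> float:
        n = Y.shape[0]
        coef, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
        fitted = Z @ coef
        ss_fit = float((fitted**2).sum())
        ss_res = float(((Y - fitted) ** 2).sum())
        m = max(int(rank), 1)
        return (ss_fit / m) / (ss_res / (n - m - 1))

    def fit(self, seed: int | None = None, n_permutations: int = 999
            ) -> "RDAResults":
        rng = np.random.default_rng(seed)
        names = list(self.blocks)
        Z_all = self._design(names)
        n = self.Y.shape[0]

        r2, adj, m = _fit_stats(self.Y, Z_all)
        coef, _, _, _ = np.linalg.lstsq(Z_all, self.Y, rcond=None)
        fitted = Z_all @ coef
        U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
        eigvals = (s**2) / (n - 1)
        eigvals = eigvals[eigvals > eigvals.max() * 1e-12] if eigvals.size else eigvals

        # global permutation test (rows of Y permuted)
        f_obs = self._pseudo_f(self.Y, Z_all)
        count = 0
        for _ in range(n_permutations):
            Yp = self.Y[rng.permutation(n)]
            if self._pseudo_f(Yp, Z_all) >= f_obs:
                count += 1
        p_global = (count + 1.0) / (n_permutations + 1.0)

        # marginal (partial) tests: Freedman-Lane — permute residuals of
        # the reduced model, test the added factor
        p_marginal = {}
        for name in names:
            others = [x for x in names if x != name]
            Z_red = self._design(others)
            if Z_red.shape[1]:
                coef_r, _, _, _ = np.linalg.lstsq(Z_red, self.Y, rcond=None)
                fit_r = Z_red @ coef_r
            else:
                fit_r = np.zeros_like(self.Y)
            resid_r = self.Y - fit_r
            f_part = self._partial_f(self.Y, Z_all, Z_red)
            count = 0
            for _ in range(n_permutations):
                Yp = fit_r + resid_r[rng.permutation(n)]
                if self._partial_f(Yp, Z_all, Z_red) >= f_part:
                    count += 1
            p_marginal[name] = (count + 1.0) / (n_permutations + 1.0)

        partition = self._varpart() if len(names) >= 2 else None
        return RDAResults(
            model=self, eigenvalues=eigvals, r2=r2, adj_r2=adj, rank=m,
            pseudo_f=f_obs, p_global=p_global, p_marginal=p_marginal,
            partition=partition, seed=seed, n_permutations=n_permutations,
            scores=U[:, : len(eigvals)] * s[: len(eigvals)],
        )

    def _partial_f(self, Y: np.ndarray, Z_full: np.ndarray, Z_red: np.ndarray
                   ) -> float:
        n = Y.shape[0]

        def ssfit(Z):
            if Z.shape[1] == 0:
                return 0.0, 0
            coef, _, rank, _ = np.linalg.lstsq(Z, Y, rcond=None)
            return float(((Z @ coef) ** 2).sum()), int(rank)

        ss_full, m_full = ssfit(Z_full)
        ss_red, m_red = ssfit(Z_red)
        df_add = max(m_full - m_red, 1)
        ss_res = float((Y**2).sum()) - ss_full
        return ((ss_full - ss_red) / df_add) / (ss_res / (n - m_full - 1))

    def _varpart(self) -> "VariancePartition":
        names = list(self.blocks)
        adj = {}
        for r in range(1, len(names) + 1):
            for combo in combinations(names, r):
                _, a, _ = _fit_stats(self.Y, self._design(combo))
                adj[frozenset(combo)] = a
        full = frozenset(names)
        unique = {}
        for name in names:
            others = frozenset(n for n in names if n != name)
            unique[name] = adj[full] - (adj[others] if others else 0.0)
        # inclusion-exclusion shared fractions
        shared = {}
        if len(names) == 2:
            a, b = names
            shared[frozenset((a, b))] = (
                adj[frozenset((a,))] + adj[frozenset((b,))] - adj[full]
            )
        elif len(names) == 3:
            a, b, c = names
            fa, fb, fc = (frozenset((x,)) for x in names)
            fab, fac, fbc = (frozenset((a, b)), frozenset((a, c)),
                             frozenset((b, c)))
            # pairwise-only intersections and the triple intersection
            # (vegan's d..g fractions)
            g = (adj[fa] + adj[fb] + adj[fc]
                 - adj[fab] - adj[fac] - adj[fbc] + adj[full])
            d_ab = adj[fa] + adj[fb] - adj[fab] - g      # shared by a,b only
            d_ac = adj[fa] + adj[fc] - adj[fac] - g      # shared by a,c only
            d_bc = adj[fb] + adj[fc] - adj[fbc] - g      # shared by b,c only
            shared = {
                frozenset((a, b)): d_ab,
                frozenset((a, c)): d_ac,
                frozenset((b, c)): d_bc,
                frozenset((a, b, c)): g,
            }
        unexplained = 1.0 - adj[full]
        return VariancePartition(
            factors=names, unique=unique, shared=shared,
            unexplained=unexplained, adj_r2=dict(adj),
        )


@dataclass
class VariancePartition:
    """Adjusted-R² decomposition into unique and shared fractions.

    Adjusted fractions may be slightly negative (Ezekiel correction);
    unique + shared + unexplained sums to 1 by construction.
    """

    factors: list[str]
    unique: dict[str, float]
    shared: dict[frozenset, float]
    unexplained: float
    adj_r2: dict[frozenset, float]

    def total(self) -> float:
        return sum(self.unique.values()) + sum(self.shared.values()) + \
            self.unexplained

    def summary(self) -> str:
        lines = ["Variance partition (adjusted R2)", "-" * 40]
        for name in self.factors:
            lines.append(f"unique [{name:<12}] {self.unique[name]:8.4f}")
        for key, val in self.shared.items():
            lines.append(f"shared [{'+'.join(sorted(key)):<12}] {val:8.4f}")
        lines.append(f"unexplained          {self.unexplained:8.4f}")
        return "\n".join(lines)


@dataclass
class RDAResults:
    """Fitted RDA: canonical eigenvalues, R², permutation tests,
    variance partition."""

    model: RDA
    eigenvalues: np.ndarray
    r2: float
    adj_r2: float
    rank: int
    pseudo_f: float
    p_global: float
    p_marginal: dict[str, float]
    partition: VariancePartition | None
    seed: int | None
    n_permutations: int
    scores: np.ndarray

    def summary(self) -> str:
        lines = [
            "RDA results",
            "=" * 46,
            f"constrained R2        {self.r2:.4f}",
            f"adjusted R2           {self.adj_r2:.4f}",
            f"pseudo-F              {self.pseudo_f:.3f}",
            f"global p (perm)       {self.p_global:.4g} "
            f"({self.n_permutations} permutations)",
        ]
        for name, p in self.p_marginal.items():
            lines.append(f"marginal p [{name:<10}] {p:.4g}")
        if self.partition is not None:
            lines.append("")
            lines.append(self.partition.summary())
        return "\n".join(lines)
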