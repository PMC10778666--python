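"""Filtering, imputation, transformation, batch correction and
univariate screening of feature matrices.

The canonical processing order is: presence filter → zero imputation
(2/3 of the per-feature minimum) → batch correction on the imputed raw
scale → log10 → Pareto scaling → multivariate models. Correcting batches
on the imputed raw scale keeps undetected cells from dominating the
per-batch location estimates; the order is an explicit argument of
:func:`run_pipeline` in :mod:`grapemet.cli` for sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .align import FeatureMatrix

__all__ = [
    "PreprocessConfig",
    "UnivariateResult",
    "impute_zeros",
    "transform_scale",
    "batch_correct",
    "univariate_screen",
]


@dataclass(frozen=True)
class PreprocessConfig:
    imputation_factor: float = 2.0 / 3.0
    fdr_alpha: float = 0.05
    batch_key: str = "batch"
    normality_alpha: float = 0.05  # Shapiro threshold for the t-test branch

    def __post_init__(self) -> None:
        if not 0 < self.imputation_factor <= 1:
            raise ValueError("imputation factor must be in (0, 1]")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("alpha must be in (0, 1)")


def impute_zeros(matrix: FeatureMatrix, factor: float = 2.0 / 3.0) -> FeatureMatrix:
    """Replace zeros by ``factor`` × the feature's minimum nonzero value.

    Nonzero cells are untouched. An all-zero feature cannot be imputed
    and is rejected — the presence filter is expected upstream.
    """
    X = matrix.intensities.to_numpy(dtype=float).copy()
    nonzero_min = np.where(X > 0, X, np.inf).min(axis=0)
    dead = ~np.isfinite(nonzero_min)
    if dead.any():
        bad = list(matrix.intensities.columns[dead])
        raise ValueError(f"all-zero features cannot be imputed: {bad[:5]}...")
    fill = factor * nonzero_min
    X = np.where(X == 0, fill[None, :], X)
    out = FeatureMatrix(
        matrix.features.copy(),
        pd.DataFrame(X, index=matrix.intensities.index,
                     columns=matrix.intensities.columns),
        matrix.metadata,
        "imputed",
        list(matrix.history),
    )
    out.history.append({"op": "impute_zeros", "factor": factor})
    return out


def transform_scale(matrix: FeatureMatrix) -> FeatureMatrix:
    """Log10 then Pareto scaling (center, divide by √sd per feature).

    Pareto scaling shrinks the leverage of intense features without
    flattening the intensity structure entirely, which is the standard
    compromise for (FT-)MS metabolomics before PCA/PLS. Features that are
    constant after the log transform scale to all zeros. Scaling an
    already-scaled matrix is refused.
    """
    if matrix.state == "scaled":
        raise ValueError("matrix is already scaled; transform_scale is one-shot")
    X = matrix.intensities.to_numpy(dtype=float)
    if (X <= 0).any():
        bad = matrix.intensities.columns[(X <= 0).any(axis=0)]
        raise ValueError(
            f"non-positive intensities (impute first); first offender: {bad[0]}"
        )
    L = np.log10(X)
    mean = L.mean(axis=0)
    sd = L.std(axis=0, ddof=1) if L.shape[0] > 1 else np.zeros(L.shape[1])
    # a feature constant up to float rounding has no information: zero it
    # rather than amplifying representation noise
    constant = sd <= 1e-12 * np.maximum(np.abs(mean), 1.0)
    scale = np.sqrt(np.where(constant, 1.0, sd))
    centered = L - mean
    Z = np.where(constant, 0.0, centered / scale)
    out = FeatureMatrix(
        matrix.features.copy(),
        pd.DataFrame(Z, index=matrix.intensities.index,
                     columns=matrix.intensities.columns),
        matrix.metadata,
        "scaled",
        list(matrix.history),
    )
    out.history.append({"op": "transform_scale", "transform": "log10+pareto"})
    return out


def batch_correct(
    matrix: FeatureMatrix, batches: pd.Series | None = None, batch_key: str = "batch"
) -> FeatureMatrix:
    """Two-stage per-feature location/scale batch adjustment.

    Stage 1 removes the additive batch offset (each batch mean is moved
    to the grand mean, estimated by least squares, i.e. the batch mean
    itself). Stage 2 rescales each batch's spread around the grand mean
    to the pooled within-batch value, so that both first and second
    moments agree across batches afterwards. Singleton batches (or
    batches constant in a feature) skip the scale stage with a warning.
    Applying the correction twice is a no-op to numerical precision.
    """
    if batches is None:
        if matrix.metadata is None or batch_key not in matrix.metadata.columns:
            raise ValueError("no batch labels available")
        batches = matrix.metadata[batch_key]
    batches = batches.reindex(matrix.intensities.index)
    labels = pd.unique(batches.dropna())
    if len(labels) < 2:
        raise ValueError("batch correction needs at least two batches")
    X = matrix.intensities.to_numpy(dtype=float).copy()
    n, p = X.shape
    grand = X.mean(axis=0)
    masks = [np.asarray(batches == b) for b in labels]
    sizes = np.array([m.sum() for m in masks])
    if (sizes == 1).any():
        warnings.warn("singleton batch: scale adjustment skipped for it")

    # stage 1: location
    for mask in masks:
        X[mask] += grand - X[mask].mean(axis=0)
    # stage 2: scale around the grand mean, to the pooled within-batch sd
    within = np.zeros(p)
    dof = 0
    for mask, size in zip(masks, sizes):
        if size > 1:
            within += ((X[mask] - grand) ** 2).sum(axis=0)
            dof += size - 1
    pooled_sd = np.sqrt(within / max(dof, 1))
    for mask, size in zip(masks, sizes):
        if size < 2:
            continue
        sb = X[mask].std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where((sb > 0) & (pooled_sd > 0), pooled_sd / sb, 1.0)
        X[mask] = grand + (X[mask] - grand) * ratio
    # the affine adjustment can cross zero for weak cells when applied on
    # the raw intensity scale; floor them at 2/3 of the feature's smallest
    # positive corrected value so a downstream log stays defined
    if matrix.state == "imputed" and (X <= 0).any():
        bad_cols = np.flatnonzero((X <= 0).any(axis=0))
        for j in bad_cols:
            pos = X[X[:, j] > 0, j]
            if pos.size == 0:
                raise ValueError(
                    "batch correction drove a feature entirely non-positive"
                )
            X[X[:, j] <= 0, j] = (2.0 / 3.0) * pos.min()
        warnings.warn(
            f"{len(bad_cols)} feature(s) had non-positive corrected cells; "
            "floored at 2/3 of the smallest positive value"
        )
    out = FeatureMatrix(
        matrix.features.copy(),
        pd.DataFrame(X, index=matrix.intensities.index,
                     columns=matrix.intensities.columns),
        matrix.metadata,
        matrix.state,
        list(matrix.history),
    )
    out.history.append({"op": "batch_correct", "n_batches": int(len(labels))})
    return out


# --------------------------------------------------------------------------
# Univariate screening
# --------------------------------------------------------------------------


@dataclass
class UnivariateResult:
    """Per-feature univariate statistics.

    ``table`` columns: ``statistic``, ``test``, ``p``, ``p_adj``,
    ``fold_change``, ``log2_fc``, per-group means and medians, and a
    ``constant`` flag. ``pairwise``: long DataFrame of Dunn's post-hoc z
    and p per group pair (≥ 3 groups only).
    """

    table: pd.DataFrame
    pairwise: pd.DataFrame
    alpha: float

    @property
    def significant(self) -> pd.Index:
        return self.table.index[self.table["p_adj"] < self.alpha]

    def write(self, path, sep: str = "\t") -> None:
        self.table.to_csv(path, sep=sep)


def _dunn_posthoc(values: np.ndarray, groups: list[np.ndarray]) -> list[tuple]:
    """Dunn's z for all group pairs on one feature.

    Pooled ranks with mid-rank ties; the tie correction enters the
    standard error as N(N+1)/12 − Σ(t³−t)/(12(N−1)).
    """
    n_tot = len(values)
    ranks = stats.rankdata(values)
    offsets = np.cumsum([0] + [len(g) for g in groups])
    mean_ranks = [
        ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(groups))
    ]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / (12.0 * (n_tot - 1))
    var_base = n_tot * (n_tot + 1) / 12.0 - tie_term
    out = []
    for i, j in combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / len(groups[i]) + 1.0 / len(groups[j])))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        out.append((i, j, z, p))
    return out


def univariate_screen(
    matrix: FeatureMatrix,
    groups: pd.Series,
    config: PreprocessConfig | None = None,
) -> UnivariateResult:
    """Feature-wise group comparison with FDR control.

    With ≥ 3 groups: Kruskal–Wallis followed by Dunn's post-hoc pairwise
    z tests. With 2 groups: Student's t when Shapiro–Wilk does not
    reject normality in either group (at ``normality_alpha``), otherwise
    Mann–Whitney U. Primary p-values are Benjamini–Hochberg adjusted
    across features. Fold change is the ratio of group means of the
    (imputed, unlogged) intensities, so call this on the imputed matrix
    rather than the Pareto-scaled one. Constant features get p = 1 by
    convention and are flagged.
    """
    config = config or PreprocessConfig()
    groups = groups.reindex(matrix.intensities.index)
    names = list(pd.unique(groups.dropna()))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    masks = {g: np.asarray(groups == g) for g in names}
    for g, m in masks.items():
        if m.sum() < 3:
            raise ValueError(f"group {g!r} has fewer than 3 samples")

    X = matrix.intensities.to_numpy(dtype=float)
    rows = []
    pair_rows = []
    for k, fid in enumerate(matrix.intensities.columns):
        col = X[:, k]
        parts = [col[masks[g]] for g in names]
        rec: dict = {"id": fid}
        constant = np.ptp(col) == 0
        rec["constant"] = bool(constant)
        if constant:
            rec.update(statistic=0.0, test="constant", p=1.0)
        elif len(names) == 2:
            normal = all(
                len(part) >= 3 and stats.shapiro(part).pvalue > config.normality_alpha
                for part in parts
            )
            if normal:
                res = stats.ttest_ind(parts[0], parts[1])
                rec.update(statistic=float(res.statistic), test="t", p=float(res.pvalue))
            else:
                res = stats.mannwhitneyu(parts[0], parts[1], alternative="two-sided")
                rec.update(statistic=float(res.statistic), test="mannwhitney",
                           p=float(res.pvalue))
        else:
            try:
                res = stats.kruskal(*parts)
                rec.update(statistic=float(res.statistic), test="kruskal",
                           p=float(res.pvalue))
            except ValueError:  # all identical within groups but not across
                rec.update(statistic=0.0, test="kruskal", p=1.0)
            for i, j, z, p in _dunn_posthoc(col, parts):
                pair_rows.append(
                    {"id": fid, "group_a": names[i], "group_b": names[j],
                     "z": z, "p": p}
                )
        for g, part in zip(names, parts):
            rec[f"mean_{g}"] = float(part.mean())
            rec[f"median_{g}"] = float(np.median(part))
        mean_a, mean_b = parts[0].mean(), parts[1].mean()
        fc = mean_a / mean_b if mean_b > 0 else np.inf
        rec["fold_change"] = float(fc)
        rec["log2_fc"] = float(np.log2(fc)) if 0 < fc < np.inf else np.nan
        rows.append(rec)

    table = pd.DataFrame(rows).set_index("id")
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    pairwise = pd.DataFrame(pair_rows, columns=["id", "group_a", "group_b", "z", "p"])
    if len(pairwise):
        pairwise["p_adj"] = multipletests(pairwise["p"].to_numpy(),
                                          method="fdr_bh")[1]
    return UnivariateResult(table=table, pairwise=pairwise, alpha=config.fdr_alpha)
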