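"""Feature-matrix construction and cross-platform peak alignment.

Per-sample peak lists (direct-infusion: m/z, intensity, S/N; LC: m/z, RT,
intensity) are clustered into features, filtered on presence, grouped
into isobars, and matched across datasets/platforms:

* within-platform alignment at a ppm window (0.5 ppm for FT-ICR data);
* LC features first grouped at 2 ppm into isobar groups (one exact mass,
  several retention times), whose unweighted mean m/z is then matched to
  direct-infusion features at 5 ppm;
* LC-vs-LC alignment additionally requires retention times to agree
  within a tolerance (10 s default).

Ambiguous matches are resolved by a deterministic tie cascade (smallest
|ppm| first, then smallest RT delta, then lower m/z — RT first for
LC-vs-LC), and the resulting map is one-to-at-most-one in both
directions.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem import ppm_error

__all__ = [
    "PeakList",
    "FeatureMatrix",
    "AlignmentMap",
    "read_peaklist",
    "write_peaklist",
    "align_samples",
    "presence_filter",
    "group_isobars",
    "cross_align",
    "lc_lc_align",
    "isobar_statistics",
    "coverage_venn",
]


@dataclass
class PeakList:
    """Peaks observed in one sample.

    ``peaks`` columns: ``mz`` (Da, required), ``intensity`` (≥ 0,
    defaults to 1), ``snr`` (optional), ``rt_s`` (seconds, LC only).
    """

    sample_id: str
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.peaks.copy()
        if "mz" not in df.columns:
            raise ValueError(f"peak list {self.sample_id}: missing 'mz' column")
        if "intensity" not in df.columns:
            df["intensity"] = 1.0
        if (df["mz"] <= 0).any():
            raise ValueError(f"peak list {self.sample_id}: non-positive m/z")
        if (df["intensity"] < 0).any():
            raise ValueError(f"peak list {self.sample_id}: negative intensity")
        self.peaks = df.reset_index(drop=True)

    @property
    def has_rt(self) -> bool:
        return "rt_s" in self.peaks.columns


def read_peaklist(path, sample_id: str | None = None, sep: str = "\t") -> PeakList:
    """Read a delimited peak list; header required, RT column is ``rt_s``
    (seconds by convention of the suffix)."""
    df = pd.read_csv(path, sep=sep)
    if "mz" not in df.columns:
        raise ValueError(f"{path}: header must contain an 'mz' column")
    name = sample_id if sample_id is not None else _stem(path)
    return PeakList(name, df)


def write_peaklist(pl: PeakList, path, sep: str = "\t") -> None:
    pl.peaks.to_csv(path, sep=sep, index=False, float_format="%.10g")


def _stem(path) -> str:
    import os

    return os.path.splitext(os.path.basename(str(path)))[0]


# --------------------------------------------------------------------------
# FeatureMatrix
# --------------------------------------------------------------------------


@dataclass
class FeatureMatrix:
    """Samples × features intensity table plus descriptors and metadata.

    ``features``: DataFrame indexed by feature id, columns ``mz``,
    ``rt_s`` (NaN for direct infusion), ``formula``, ``class`` (empty
    until annotated). ``intensities``: DataFrame, rows = samples,
    columns = feature ids, 0 meaning "not detected". ``metadata``:
    per-sample table (variety, region, vintage, batch, preparation...).

    ``state`` tracks what has been done to the values ("raw",
    "imputed", "scaled") so that, e.g., scaling twice is a type error
    rather than a silent statistical mistake.
    """

    features: pd.DataFrame
    intensities: pd.DataFrame
    metadata: pd.DataFrame | None = None
    state: str = "raw"
    history: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.features.index.equals(pd.Index(self.intensities.columns)):
            raise ValueError("feature table and intensity columns disagree")
        mz = self.features["mz"].to_numpy()
        rt = (
            self.features["rt_s"].fillna(-1.0).to_numpy()
            if "rt_s" in self.features.columns
            else np.full(len(mz), -1.0)
        )
        order = np.lexsort((rt, mz))
        if not (np.diff(mz[order]) >= 0).all():  # pragma: no cover - lexsort
            raise AssertionError
        if list(order) != list(range(len(mz))):
            self.features = self.features.iloc[order]
            self.intensities = self.intensities.iloc[:, order]

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[0]

    @property
    def n_features(self) -> int:
        return self.intensities.shape[1]

    @property
    def has_rt(self) -> bool:
        return "rt_s" in self.features.columns and self.features["rt_s"].notna().any()

    def copy(self) -> "FeatureMatrix":
        return FeatureMatrix(
            self.features.copy(),
            self.intensities.copy(),
            None if self.metadata is None else self.metadata.copy(),
            self.state,
            list(self.history),
        )

    def presence_counts(self) -> pd.Series:
        return (self.intensities > 0).sum(axis=0)

    # ------------------------------------------------------------------
    # Wide-TSV round-trip (features as rows, bit-exact floats via repr)
    # ------------------------------------------------------------------
    def write(self, path, sep: str = "\t") -> None:
        cols = ["id", "mz", "rt_s", "formula", "class"] + list(
            self.intensities.index
        )
        with open(path, "w") as fh:
            fh.write(sep.join(map(str, cols)) + "\n")
            for fid, row in self.features.iterrows():
                rt = row.get("rt_s", float("nan"))
                cells = [
                    str(fid),
                    repr(float(row["mz"])),
                    "" if pd.isna(rt) else repr(float(rt)),
                    str(row.get("formula", "") or ""),
                    str(row.get("class", "") or ""),
                ]
                cells += [repr(float(v)) for v in self.intensities[fid]]
                fh.write(sep.join(cells) + "\n")

    @classmethod
    def read(cls, path, metadata: pd.DataFrame | None = None, sep: str = "\t"
             ) -> "FeatureMatrix":
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
        sample_ids = list(raw.columns[5:])
        features = pd.DataFrame(
            {
                "mz": raw["mz"].astype(float).to_numpy(),
                "rt_s": [float(v) if v else float("nan") for v in raw["rt_s"]],
                "formula": raw["formula"].to_numpy(),
                "class": raw["class"].to_numpy(),
            },
            index=pd.Index(raw["id"], name="id"),
        )
        inten = pd.DataFrame(
            raw[sample_ids].astype(float).to_numpy().T,
            index=pd.Index(sample_ids, name="sample"),
            columns=features.index,
        )
        return cls(features, inten, metadata)


# --------------------------------------------------------------------------
# Within-platform alignment
# --------------------------------------------------------------------------


def _sweep_clusters(mz: np.ndarray, weights: np.ndarray, window_ppm: float
                    ) -> np.ndarray:
    """Single m/z-sorted sweep; a peak joins the open cluster while it is
    within ``window_ppm`` of the running intensity-weighted centroid.

    ``mz`` must be sorted ascending. Returns integer cluster labels.
    """
    labels = np.empty(len(mz), dtype=np.int64)
    if len(mz) == 0:
        return labels
    lab = 0
    centroid = mz[0]
    wsum = max(weights[0], 1e-300)
    msum = centroid * wsum
    labels[0] = 0
    for i in range(1, len(mz)):
        if abs(ppm_error(mz[i], centroid)) <= window_ppm:
            labels[i] = lab
            w = max(weights[i], 1e-300)
            wsum += w
            msum += mz[i] * w
            centroid = msum / wsum
        else:
            lab += 1
            labels[i] = lab
            centroid = mz[i]
            wsum = max(weights[i], 1e-300)
            msum = centroid * wsum
    return labels


def align_samples(
    peaklists: Sequence[PeakList],
    window_ppm: float = 0.5,
    min_snr: float | None = 3.0,
    rt_tol_s: float | None = None,
    metadata: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Cluster per-sample peaks into features within a ppm window.

    Peaks below ``min_snr`` (when an ``snr`` column exists) are dropped
    before clustering. All peaks are pooled, sorted by m/z and swept
    once; the result is invariant to sample order and within-sample peak
    order. When peak lists carry retention times, clusters are further
    split wherever consecutive RTs (sorted) gap by more than
    ``rt_tol_s`` (default 10 s), so isomers at distinct RTs become
    distinct features.

    When one sample contributes several peaks to a feature, the maximum
    intensity is kept. Consensus m/z is the intensity-weighted mean of
    member peaks; consensus RT the unweighted mean.
    """
    if not peaklists:
        raise ValueError("need at least one peak list")
    if window_ppm <= 0:
        raise ValueError("window must be positive")
    has_rt = any(pl.has_rt for pl in peaklists)
    if has_rt and rt_tol_s is None:
        rt_tol_s = 10.0

    frames = []
    for pl in peaklists:
        df = pl.peaks.copy()
        if min_snr is not None and "snr" in df.columns:
            df = df[df["snr"] >= min_snr]
        df = df[["mz", "intensity"] + (["rt_s"] if "rt_s" in df.columns else [])]
        df["sample"] = pl.sample_id
        frames.append(df)
    pool = pd.concat(frames, ignore_index=True)
    if "rt_s" not in pool.columns:
        pool["rt_s"] = np.nan
    sample_ids = [pl.sample_id for pl in peaklists]
    if pool.empty:
        features = pd.DataFrame(columns=["mz", "rt_s", "formula", "class"])
        inten = pd.DataFrame(index=pd.Index(sample_ids, name="sample"))
        return FeatureMatrix(features, inten, metadata)

    # deterministic pooling order: m/z, then sample id, then intensity
    pool = pool.sort_values(
        ["mz", "sample", "intensity"], kind="mergesort"
    ).reset_index(drop=True)
    labels = _sweep_clusters(
        pool["mz"].to_numpy(), pool["intensity"].to_numpy(), window_ppm
    )
    pool["cluster"] = labels

    if has_rt:
        # split m/z clusters on RT gaps
        next_label = 0
        new_labels = np.empty(len(pool), dtype=np.int64)
        for _, idx in pool.groupby("cluster", sort=True).groups.items():
            sub = pool.loc[idx].sort_values(["rt_s", "sample"], kind="mergesort")
            rts = sub["rt_s"].to_numpy()
            sub_lab = np.zeros(len(sub), dtype=np.int64)
            for k in range(1, len(sub)):
                gap = rts[k] - rts[k - 1]
                sub_lab[k] = sub_lab[k - 1] + (
                    1 if (np.isfinite(gap) and gap > rt_tol_s) else 0
                )
            for j, orig in zip(sub_lab, sub.index):
                new_labels[orig] = next_label + j
            next_label += sub_lab[-1] + 1
        pool["cluster"] = new_labels

    grouped = pool.groupby("cluster", sort=True)
    consensus = []
    for cl, sub in grouped:
        w = sub["intensity"].to_numpy()
        w = np.where(w > 0, w, 1e-300)
        cmz = float(np.average(sub["mz"], weights=w))
        crt = float(sub["rt_s"].mean()) if sub["rt_s"].notna().any() else np.nan
        consensus.append((cmz, crt, cl))
    consensus.sort()
    inten_mat = np.zeros((len(sample_ids), len(consensus)))
    sample_pos = {s: i for i, s in enumerate(sample_ids)}
    fids = []
    feats = []
    for k, (cmz, crt, cl) in enumerate(consensus):
        fid = f"F{k:06d}"
        fids.append(fid)
        feats.append((cmz, crt, "", ""))
        sub = grouped.get_group(cl)
        for s, v in sub.groupby("sample")["intensity"].max().items():
            inten_mat[sample_pos[s], k] = v
    features = pd.DataFrame(
        feats, columns=["mz", "rt_s", "formula", "class"],
        index=pd.Index(fids, name="id"),
    )
    inten = pd.DataFrame(
        inten_mat, index=pd.Index(sample_ids, name="sample"), columns=features.index
    )
    fm = FeatureMatrix(features, inten, metadata)
    fm.history.append(
        {"op": "align_samples", "n_peaks": len(pool), "n_features": len(fids),
         "window_ppm": window_ppm}
    )
    return fm


def presence_filter(
    matrix: FeatureMatrix,
    min_samples: int | None = None,
    min_fraction: float | None = None,
) -> FeatureMatrix:
    """Drop features detected in too few samples.

    ``min_samples`` is an absolute count ("present in at least four
    samples"); ``min_fraction`` a proportion with ceiling semantics
    ("at least 33% of the samples" of a 10-sample set means ≥ 4).
    Exactly one of the two must be given; the boundary is inclusive.
    """
    if (min_samples is None) == (min_fraction is None):
        raise ValueError("give exactly one of min_samples / min_fraction")
    if min_fraction is not None:
        if min_fraction <= 0:
            raise ValueError("min_fraction must be positive")
        threshold = math.ceil(matrix.n_samples * min_fraction)
    else:
        if min_samples is None or min_samples <= 0:
            raise ValueError("min_samples must be positive")
        threshold = min_samples
    present = matrix.presence_counts()
    keep = present[present >= threshold].index
    out = FeatureMatrix(
        matrix.features.loc[keep],
        matrix.intensities[keep],
        matrix.metadata,
        matrix.state,
        list(matrix.history),
    )
    out.history.append(
        {
            "op": "presence_filter",
            "threshold": threshold,
            "retained": int(len(keep)),
            "removed": int(matrix.n_features - len(keep)),
        }
    )
    return out


# --------------------------------------------------------------------------
# Isobar grouping and cross-platform alignment
# --------------------------------------------------------------------------


def group_isobars(matrix: FeatureMatrix, window_ppm: float = 2.0) -> pd.DataFrame:
    """Group LC features sharing one exact mass at several RTs.

    Features whose m/z agree within ``window_ppm`` merge into one group
    keyed by the unweighted mean m/z; the group stores all member RTs
    sorted ascending, and its isobar multiplicity is the number of
    distinct RTs. Returns a DataFrame indexed by group id with columns
    ``mean_mz``, ``rts`` (tuple), ``multiplicity``, ``members`` (tuple of
    feature ids).
    """
    if not matrix.has_rt:
        raise ValueError("isobar grouping requires LC features with RT")
    feats = matrix.features.sort_values("mz", kind="mergesort")
    mz = feats["mz"].to_numpy()
    labels = _sweep_clusters(mz, np.ones(len(mz)), window_ppm)
    rows = []
    for lab in np.unique(labels):
        sub = feats.iloc[labels == lab]
        rts = tuple(sorted(float(r) for r in sub["rt_s"] if np.isfinite(r)))
        rows.append(
            {
                "mean_mz": float(sub["mz"].mean()),
                "rts": rts,
                "multiplicity": int(len(np.unique(rts))) if rts else 1,
                "members": tuple(sub.index),
            }
        )
    rows.sort(key=lambda r: r["mean_mz"])
    out = pd.DataFrame(rows, index=pd.Index(
        [f"G{k:06d}" for k in range(len(rows))], name="group"))
    return out


@dataclass
class AlignmentMap:
    """One-to-at-most-one correspondences between two feature sets.

    ``pairs`` columns: ``id_a``, ``id_b``, ``ppm_error``, ``rt_delta_s``
    (NaN when either side lacks RT), ``multiplicity`` (isobar count
    carried over from the B side when it is a group table).
    """

    pairs: pd.DataFrame

    def __len__(self) -> int:
        return len(self.pairs)

    def write(self, path, sep: str = "\t") -> None:
        self.pairs.to_csv(path, sep=sep, index=False, float_format="%.6f")


def _resolve_ties(cands: list[tuple], rt_first: bool) -> pd.DataFrame:
    """Greedy one-to-one resolution of candidate matches.

    ``cands`` items: (id_a, id_b, abs_ppm, signed_ppm, rt_delta, mz,
    multiplicity). Sorted by (|ppm|, ΔRT, mz) — or ΔRT first for LC-LC —
    then accepted greedily so each id appears in at most one pair.
    """
    def key(c):
        abs_ppm, rt_delta, mz = c[2], c[4], c[5]
        rt_key = rt_delta if np.isfinite(rt_delta) else np.inf
        return (rt_key, abs_ppm, mz) if rt_first else (abs_ppm, rt_key, mz)

    used_a: set = set()
    used_b: set = set()
    rows = []
    for c in sorted(cands, key=key):
        id_a, id_b = c[0], c[1]
        if id_a in used_a or id_b in used_b:
            continue
        used_a.add(id_a)
        used_b.add(id_b)
        rows.append(
            {"id_a": id_a, "id_b": id_b, "ppm_error": c[3],
             "rt_delta_s": c[4], "multiplicity": c[6]}
        )
    rows.sort(key=lambda r: str(r["id_a"]))
    return pd.DataFrame(rows, columns=["id_a", "id_b", "ppm_error",
                                       "rt_delta_s", "multiplicity"])


def cross_align(
    di_features: FeatureMatrix,
    lc_groups: pd.DataFrame,
    window_ppm: float = 5.0,
) -> AlignmentMap:
    """Match LC isobar groups (by grouped mean m/z) to direct-infusion
    features within a ppm window.

    Among multiple candidates the smallest |ppm error| wins, then the
    smaller RT delta (vacuous here — DI features carry no RT), then the
    lower m/z. The map records the signed ppm error (DI as reference)
    and the group's isobar multiplicity.
    """
    di = di_features.features
    cands = []
    di_mz = di["mz"].to_numpy()
    order = np.argsort(di_mz)
    for gid, row in lc_groups.iterrows():
        gm = row["mean_mz"]
        lo = gm * (1 - window_ppm * 1e-6)
        hi = gm * (1 + window_ppm * 1e-6)
        i0, i1 = np.searchsorted(di_mz[order], [lo, hi])
        for j in order[i0:i1]:
            fid = di.index[j]
            # ppm relative to the LC group mean (the query side), so that
            # symmetric +-x ppm candidates tie exactly
            err = ppm_error(gm, di_mz[j])
            if abs(err) <= window_ppm:
                cands.append(
                    (fid, gid, abs(err), err, np.nan, di_mz[j],
                     int(row["multiplicity"]))
                )
    return AlignmentMap(_resolve_ties(cands, rt_first=False))


def lc_lc_align(
    a: FeatureMatrix,
    b: FeatureMatrix,
    window_ppm: float = 5.0,
    rt_tol_s: float = 10.0,
) -> AlignmentMap:
    """Match LC features across two datasets: mass agreement within the
    ppm window AND retention times within ``rt_tol_s``. Ties are resolved
    with the RT delta first, then |ppm|, then lower m/z."""
    if not (a.has_rt and b.has_rt):
        raise ValueError("LC-LC alignment requires RT on both sides")
    fb = b.features
    b_mz = fb["mz"].to_numpy()
    order = np.argsort(b_mz)
    cands = []
    for fid_a, row in a.features.iterrows():
        mza, rta = row["mz"], row["rt_s"]
        lo = mza * (1 - window_ppm * 1e-6)
        hi = mza * (1 + window_ppm * 1e-6)
        i0, i1 = np.searchsorted(b_mz[order], [lo, hi])
        for j in order[i0:i1]:
            fid_b = fb.index[j]
            err = ppm_error(mza, b_mz[j])
            dt = abs(rta - fb["rt_s"].iloc[j])
            if abs(err) <= window_ppm and dt <= rt_tol_s:
                cands.append((fid_a, fid_b, abs(err), err, dt, mza, 1))
    return AlignmentMap(_resolve_ties(cands, rt_first=True))


def isobar_statistics(
    amap: AlignmentMap, classes: Mapping[str, str]
) -> pd.DataFrame:
    """Per-chemical-class isobar table for a DI-vs-LC alignment map.

    ``classes`` maps DI feature id → chemical class (from assignment).
    For each class: number of matched compositions, the mean isobar
    multiplicity (average number of RTs per composition) and its
    min–max range; an ``all`` row totals the table and carries the class
    percentages of matched compositions.
    """
    if len(amap) == 0:
        return pd.DataFrame(
            columns=["class", "n", "pct", "isobar_mean", "isobar_min", "isobar_max"]
        )
    df = amap.pairs.copy()
    df["class"] = [classes.get(i, "unclassified") for i in df["id_a"]]
    rows = []
    total = len(df)
    for cls, sub in df.groupby("class", sort=True):
        mult = sub["multiplicity"].to_numpy()
        rows.append(
            {
                "class": cls,
                "n": int(len(sub)),
                "pct": 100.0 * len(sub) / total,
                "isobar_mean": float(mult.mean()),
                "isobar_min": int(mult.min()),
                "isobar_max": int(mult.max()),
            }
        )
    mult = df["multiplicity"].to_numpy()
    rows.append(
        {
            "class": "all",
            "n": total,
            "pct": 100.0,
            "isobar_mean": float(mult.mean()),
            "isobar_min": int(mult.min()),
            "isobar_max": int(mult.max()),
        }
    )
    return pd.DataFrame(rows)


def coverage_venn(
    matrix: FeatureMatrix,
    groups: pd.Series,
    min_samples_per_group: int = 4,
) -> pd.DataFrame:
    """Shared/unique feature counts between sample groups (Venn-style).

    A feature counts as present in a group iff detected (> 0) in at
    least ``min_samples_per_group`` of that group's samples. For each
    unordered group pair the table reports counts and percentages of the
    pair's union — shared + unique_a + unique_b sums to 100%.
    Groups with fewer samples than the threshold raise a warning.
    """
    groups = groups.reindex(matrix.intensities.index)
    names = [g for g in pd.unique(groups.dropna())]
    if len(names) < 2:
        raise ValueError("need at least two groups")
    present: dict[str, set] = {}
    for g in names:
        samples = groups.index[groups == g]
        if len(samples) < min_samples_per_group:
            warnings.warn(
                f"group {g!r} has {len(samples)} samples, below the "
                f"presence threshold {min_samples_per_group}"
            )
        counts = (matrix.intensities.loc[samples] > 0).sum(axis=0)
        present[g] = set(counts.index[counts >= min_samples_per_group])
    rows = []
    for i, ga in enumerate(names):
        for gb in names[i + 1:]:
            shared = present[ga] & present[gb]
            only_a = present[ga] - present[gb]
            only_b = present[gb] - present[ga]
            union = len(shared) + len(only_a) + len(only_b)
            denom = union if union else 1
            rows.append(
                {
                    "group_a": ga,
                    "group_b": gb,
                    "shared": len(shared),
                    "unique_a": len(only_a),
                    "unique_b": len(only_b),
                    "shared_pct": 100.0 * len(shared) / denom,
                    "unique_a_pct": 100.0 * len(only_a) / denom,
                    "unique_b_pct": 100.0 * len(only_b) / denom,
                }
            )
    return pd.DataFrame(rows)
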