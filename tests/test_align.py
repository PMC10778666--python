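"""Feature-matrix construction, isobar grouping, cross-platform
alignment, coverage statistics."""

import numpy as np
import pandas as pd
import pytest

from grapemet.align import (
    FeatureMatrix,
    PeakList,
    align_samples,
    coverage_venn,
    cross_align,
    group_isobars,
    isobar_statistics,
    lc_lc_align,
    presence_filter,
    read_peaklist,
)


def pl(sample, mzs, intensities=None, rts=None, snrs=None):
    df = pd.DataFrame({"mz": mzs})
    df["intensity"] = intensities if intensities is not None else 1.0
    if rts is not None:
        df["rt_s"] = rts
    if snrs is not None:
        df["snr"] = snrs
    return PeakList(sample, df)


def test_identical_peaks_form_one_feature():
    fm = align_samples([pl("a", [300.0]), pl("b", [300.0])], window_ppm=0.5)
    assert fm.n_features == 1
    assert (fm.intensities.to_numpy() > 0).all()


def test_one_ppm_apart_splits_at_half_ppm_window():
    # 0.0003 / 300 x 1e6 = 1.0 ppm > 0.5
    fm = align_samples([pl("a", [300.00000]), pl("b", [300.00030])],
                       window_ppm=0.5)
    assert fm.n_features == 2


def test_no_chaining_on_ladder():
    """A ladder of 0.4-ppm-spaced peaks must not chain into one feature:
    max in-feature spread stays within the window."""
    base = 400.0
    mzs = [base * (1 + k * 0.4e-6) for k in range(8)]
    fm = align_samples([pl(f"s{k}", [mz]) for k, mz in enumerate(mzs)],
                       window_ppm=0.5)
    assert fm.n_features >= 4
    # reconstruct member peaks per feature from the intensity table
    for fid in fm.features.index:
        members = [mzs[k] for k, s in enumerate(fm.intensities.index)
                   if fm.intensities.loc[s, fid] > 0]
        if len(members) > 1:
            spread = (max(members) - min(members)) / max(members) * 1e6
            assert spread <= 0.5 + 1e-9


def test_order_invariance():
    rng = np.random.default_rng(3)
    lists = []
    for s in range(6):
        mzs = 200 + np.arange(20) * 7.3 + rng.normal(0, 1e-5, 20)
        perm = rng.permutation(20)
        lists.append(pl(f"s{s}", mzs[perm], intensities=rng.uniform(1, 5, 20)))
    a = align_samples(lists, 0.5)
    b = align_samples(lists[::-1], 0.5)
    assert np.allclose(a.features["mz"].to_numpy(), b.features["mz"].to_numpy())
    pd.testing.assert_frame_equal(
        a.intensities.sort_index(), b.intensities.sort_index()
    )


def test_snr_filter_and_max_intensity_rule():
    lists = [
        pl("a", [300.0, 300.0], intensities=[5.0, 9.0], snrs=[10.0, 10.0]),
        pl("b", [300.0], intensities=[4.0], snrs=[2.0]),  # below S/N 3
    ]
    fm = align_samples(lists, 0.5, min_snr=3.0)
    assert fm.n_features == 1
    fid = fm.features.index[0]
    assert fm.intensities.loc["a", fid] == 9.0   # max of duplicate peaks
    assert fm.intensities.loc["b", fid] == 0.0   # filtered out


def test_presence_filter_boundaries():
    X = np.zeros((10, 3))
    X[:3, 0] = 1.0   # 3 samples -> removed at min_samples=4
    X[:4, 1] = 1.0   # 4 samples -> retained ("at least four")
    X[:5, 2] = 1.0
    from conftest import make_feature_matrix

    fm = make_feature_matrix(X)
    kept = presence_filter(fm, min_samples=4)
    assert kept.n_features == 2
    # 33% of 10 samples -> ceiling -> 4
    kept_frac = presence_filter(fm, min_fraction=0.33)
    assert kept_frac.n_features == 2
    assert kept_frac.history[-1]["threshold"] == 4
    with pytest.raises(ValueError):
        presence_filter(fm, min_samples=4, min_fraction=0.33)


def test_group_isobars_mean_and_multiplicity():
    feats = pd.DataFrame(
        {"mz": [400.0000, 400.0006, 500.0], "rt_s": [60.0, 180.0, 90.0],
         "formula": "", "class": ""},
        index=pd.Index(["F0", "F1", "F2"], name="id"),
    )
    inten = pd.DataFrame(
        np.ones((2, 3)), index=pd.Index(["a", "b"], name="sample"),
        columns=feats.index,
    )
    fm = FeatureMatrix(feats, inten)
    groups = group_isobars(fm, window_ppm=2.0)  # 1.5 ppm apart -> one group
    assert len(groups) == 2
    g = groups.iloc[0]
    assert g["mean_mz"] == pytest.approx(400.0003, abs=1e-7)
    assert g["multiplicity"] == 2
    assert g["rts"] == (60.0, 180.0)
    assert groups.iloc[1]["multiplicity"] == 1


def _di_matrix(mzs):
    feats = pd.DataFrame(
        {"mz": mzs, "rt_s": np.nan, "formula": "", "class": ""},
        index=pd.Index([f"D{k}" for k in range(len(mzs))], name="id"),
    )
    inten = pd.DataFrame(np.ones((1, len(mzs))),
                         index=pd.Index(["s"], name="sample"),
                         columns=feats.index)
    return FeatureMatrix(feats, inten)


def _groups(rows):
    return pd.DataFrame(
        rows, index=pd.Index([f"G{k}" for k in range(len(rows))], name="group")
    )


def test_cross_align_within_window():
    di = _di_matrix([400.0000])
    groups = _groups([{"mean_mz": 400.0016, "rts": (60.0,), "multiplicity": 1,
                       "members": ("F0",)}])
    amap = cross_align(di, groups, window_ppm=5.0)  # 4 ppm <= 5
    assert len(amap) == 1
    assert abs(amap.pairs["ppm_error"].iloc[0]) == pytest.approx(4.0, abs=0.01)


def test_cross_align_tie_goes_to_lower_mz():
    # LC group exactly between two DI features (+-3 ppm): tie cascade
    # ends at the lower-mz feature
    gm = 400.0
    di = _di_matrix([gm * (1 - 3e-6), gm * (1 + 3e-6)])
    groups = _groups([{"mean_mz": gm, "rts": (60.0,), "multiplicity": 1,
                       "members": ()}])
    amap = cross_align(di, groups, window_ppm=5.0)
    assert len(amap) == 1
    assert amap.pairs["id_a"].iloc[0] == "D0"


def test_cross_align_disjoint_ranges_empty():
    amap = cross_align(_di_matrix([200.0]), _groups(
        [{"mean_mz": 800.0, "rts": (1.0,), "multiplicity": 1, "members": ()}]),
        window_ppm=5.0)
    assert len(amap) == 0


def _lc_matrix(mzs, rts, prefix):
    feats = pd.DataFrame(
        {"mz": mzs, "rt_s": rts, "formula": "", "class": ""},
        index=pd.Index([f"{prefix}{k}" for k in range(len(mzs))], name="id"),
    )
    inten = pd.DataFrame(np.ones((1, len(mzs))),
                         index=pd.Index(["s"], name="sample"),
                         columns=feats.index)
    return FeatureMatrix(feats, inten)


def test_lc_lc_align_rt_tolerance():
    a = _lc_matrix([400.0], [100.0], "A")
    b11 = _lc_matrix([400.0], [111.0], "B")  # delta RT 11 s > 10 s
    assert len(lc_lc_align(a, b11, 5.0, 10.0)) == 0
    b_same = _lc_matrix([400.0], [100.0], "B")
    amap = lc_lc_align(a, b_same, 5.0, 10.0)
    assert len(amap) == 1
    assert amap.pairs["ppm_error"].iloc[0] == 0.0
    assert amap.pairs["rt_delta_s"].iloc[0] == 0.0


def test_lc_lc_align_one_to_one():
    rng = np.random.default_rng(9)
    mzs = 200 + np.arange(30) * 11.0
    a = _lc_matrix(mzs, np.full(30, 120.0), "A")
    b = _lc_matrix(mzs * (1 + rng.uniform(-1e-6, 1e-6, 30)),
                   120.0 + rng.normal(0, 2, 30), "B")
    amap = lc_lc_align(a, b, 5.0, 10.0)
    assert len(amap) <= 30
    assert amap.pairs["id_a"].is_unique and amap.pairs["id_b"].is_unique
    assert len(amap) == 30  # planted pairs all recovered


def test_isobar_statistics_table():
    pairs = pd.DataFrame(
        {"id_a": ["D0", "D1"], "id_b": ["G0", "G1"],
         "ppm_error": [0.1, -0.2], "rt_delta_s": [np.nan, np.nan],
         "multiplicity": [2, 4]}
    )
    from grapemet.align import AlignmentMap

    table = isobar_statistics(AlignmentMap(pairs),
                              {"D0": "CHO", "D1": "CHO"})
    cho = table[table["class"] == "CHO"].iloc[0]
    assert cho["n"] == 2
    assert cho["isobar_mean"] == 3.0
    assert (cho["isobar_min"], cho["isobar_max"]) == (2, 4)
    empty = isobar_statistics(AlignmentMap(pairs.iloc[:0]), {})
    assert len(empty) == 0


def test_coverage_venn():
    from conftest import make_feature_matrix

    X = np.zeros((10, 3))
    X[:5, 0] = 1.0          # group A only (5 of first five)
    X[:, 1] = 1.0           # both groups
    X[5:, 2] = 1.0          # group B only
    fm = make_feature_matrix(X)
    groups = pd.Series(["A"] * 5 + ["B"] * 5, index=fm.intensities.index)
    venn = coverage_venn(fm, groups, min_samples_per_group=4)
    row = venn.iloc[0]
    assert (row["shared"], row["unique_a"], row["unique_b"]) == (1, 1, 1)
    assert row["shared_pct"] + row["unique_a_pct"] + row["unique_b_pct"] == \
        pytest.approx(100.0, abs=0.1)
    # identical groups -> 100% shared
    venn2 = coverage_venn(fm, pd.Series(["A", "B"] * 5,
                                        index=fm.intensities.index),
                          min_samples_per_group=2)
    # features present in >=2 samples of each interleaved half
    assert venn2.iloc[0]["shared_pct"] == pytest.approx(100.0)


def test_feature_matrix_roundtrip_bit_exact(tmp_path):
    rng = np.random.default_rng(1)
    from conftest import make_feature_matrix

    fm = make_feature_matrix(rng.lognormal(10, 1, size=(5, 8)))
    fm.features.loc[fm.features.index[0], "formula"] = "C6H12O6"
    fm.features.loc[fm.features.index[0], "class"] = "CHO"
    path = tmp_path / "matrix.tsv"
    fm.write(path)
    back = FeatureMatrix.read(path)
    assert (back.intensities.to_numpy() == fm.intensities.to_numpy()).all()
    assert (back.features["mz"].to_numpy() == fm.features["mz"].to_numpy()).all()
    assert back.features["formula"].iloc[0] == "C6H12O6"
    # second round trip is byte-identical
    path2 = tmp_path / "matrix2.tsv"
    back.write(path2)
    assert path.read_bytes() == path2.read_bytes()


def test_peaklist_reader_requires_mz(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("mass\tintensity\n100.0\t1.0\n")
    with pytest.raises(ValueError, match="mz"):
        read_peaklist(bad)
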