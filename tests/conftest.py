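import numpy as np
import pandas as pd
import pytest

from grapemet.align import align_samples, presence_filter
from grapemet.preprocess import batch_correct, impute_zeros, transform_scale
from grapemet.simulate import (
    NoiseSpec,
    emit_peaklists,
    make_design,
    make_library,
    make_markers,
)


def make_feature_matrix(X, sample_ids=None, mz=None):
    """Wrap a plain intensity array into a FeatureMatrix for tests."""
    from grapemet.align import FeatureMatrix

    n, p = X.shape
    rng = np.random.default_rng(0)
    fids = [f"F{k:06d}" for k in range(p)]
    feats = pd.DataFrame(
        {
            "mz": np.sort(rng.uniform(100, 900, p)) if mz is None else mz,
            "rt_s": np.nan,
            "formula": "",
            "class": "",
        },
        index=pd.Index(fids, name="id"),
    )
    samples = sample_ids if sample_ids is not None else [f"S{i:03d}" for i in range(n)]
    inten = pd.DataFrame(X, index=pd.Index(samples, name="sample"), columns=fids)
    return FeatureMatrix(feats, inten)


@pytest.fixture(scope="session")
def marker_study():
    """Two-variety study with 50 planted 3x markers, n = 40 per class.

    The preset exercised by the discrimination stage: 150-metabolite
    library, default noise, a 1.3x batch effect, full preprocessing
    chain. Returns dict with the raw and scaled matrices, design and
    ground truth.
    """
    lib = make_library(11, 150)
    design = make_design(12, n_per_variety=40,
                         varieties=("Chardonnay", "PinotNoir"))
    markers = make_markers(lib, 13, n_markers=50, fold=3.0)
    di, lc, truth = emit_peaklists(
        lib, design, NoiseSpec(), 14, markers=markers,
        batch_effects={"B1": 1.0, "B2": 1.3},
    )
    fm = presence_filter(align_samples(di, 0.5, 3.0, metadata=design),
                         min_samples=4)
    imputed = impute_zeros(fm)
    scaled = transform_scale(batch_correct(imputed, batch_key="batch"))
    return {
        "library": lib,
        "design": design,
        "markers": markers,
        "truth": truth,
        "di": di,
        "lc": lc,
        "features": fm,
        "imputed": imputed,
        "scaled": scaled,
    }
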