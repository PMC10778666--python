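"""Ground-truthed synthetic peak lists emulating a grape-juice
metabolomics study.

The generator builds a metabolite library over the CHNOS van Krevelen
envelope (with CH2 and glycosyl homologous series and a sugar
"pollutant" eluting at many retention times), lays out a sample design
(variety / region / vintage / batch / preparation), and emits per-sample
peak lists for two virtual platforms:

* direct infusion — one peak per detected (metabolite, adduct), sub-ppm
  mass error, signal-to-noise column;
* LC — one peak per isomer retention time, few-ppm mass error, RT
  jitter.

Intensities are log-normal, modulated by class-marker fold changes and
multiplicative batch offsets; detection dropout is a logistic function
of log-intensity (a statistical proxy for ionization competition).
Every emitted peak traces back to one (metabolite, adduct, isomer,
sample) tuple, and everything is reproducible from the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assign import AssignmentConfig
from .chem import Adduct, ElementalComposition, chemical_class, ion_mz, ppm_error
from .align import PeakList

__all__ = [
    "NoiseSpec",
    "Metabolite",
    "GroundTruth",
    "make_library",
    "make_design",
    "make_markers",
    "emit_peaklists",
    "truth_report",
    "make_varpart_dataset",
]

_F = ElementalComposition.from_formula


@dataclass(frozen=True)
class NoiseSpec:
    """Per-platform noise model.

    Mass error is multiplicative Gaussian (ppm sd); DI is an order of
    magnitude more accurate than LC, so the study's alignment windows
    (0.5 / 2 / 5 ppm) are neither trivially loose nor unachievable.
    Dropout probability decays logistically with log10 intensity.
    """

    di_ppm_sd: float = 0.1
    lc_ppm_sd: float = 1.0
    rt_jitter_s: float = 2.0
    intensity_cv: float = 0.3
    dropout_max: float = 0.3
    dropout_midpoint_log10: float = 3.5
    dropout_steepness: float = 1.5
    snr_noise_floor: float = 50.0

    def dropout_probability(self, intensity: float) -> float:
        x = math.log10(max(intensity, 1e-12))
        return self.dropout_max / (
            1.0 + math.exp(self.dropout_steepness * (x - self.dropout_midpoint_log10))
        )


@dataclass(frozen=True)
class Metabolite:
    """One library entry: a neutral composition observed at one or more
    retention times (isomers), emitted as one or more adduct ions."""

    mid: str
    composition: ElementalComposition
    rts_s: tuple[float, ...]
    adducts: tuple[Adduct, ...]
    base_intensity: float
    origin: str = "random"  # "random" | "series" | "pollutant"

    @property
    def n_isomers(self) -> int:
        return len(self.rts_s)


@dataclass
class GroundTruth:
    """Everything needed to score pipeline outputs against the truth."""

    library: list[Metabolite]
    design: pd.DataFrame
    markers: pd.DataFrame  # columns: mid, factor, level, fold
    noise: NoiseSpec
    emitted: pd.DataFrame  # one row per emitted peak (both platforms)
    seed: int

    def library_table(self) -> pd.DataFrame:
        rows = []
        for m in self.library:
            for ad in m.adducts:
                rows.append(
                    {
                        "mid": m.mid,
                        "formula": m.composition.formula(),
                        "class": chemical_class(m.composition),
                        "adduct": ad.label,
                        "ion_mz": ion_mz(m.composition, ad),
                        "n_isomers": m.n_isomers,
                        "origin": m.origin,
                    }
                )
        return pd.DataFrame(rows)

    def ion_mzs(self) -> np.ndarray:
        return np.sort(self.library_table()["ion_mz"].to_numpy())


# --------------------------------------------------------------------------
# Library
# --------------------------------------------------------------------------

_DEFAULT_CLASS_MIX = {"CHO": 0.70, "CHNO": 0.15, "CHOS": 0.10, "CHNOS": 0.05}

#: (base formula, step formula, number of extra members)
_DEFAULT_SERIES = (
    ("C6H12O6", "C6H10O5", 2),     # glucose + glycosyl steps
    ("C10H12O5", "CH2", 3),        # alkylation series
    ("C15H20O10", "C6H10O5", 1),   # glycoside series
)

_RT_RANGE_S = (45.0, 360.0)
_MIN_RT_GAP_S = 25.0
_MIN_ION_SEPARATION_PPM = 3.0


def _sample_composition(rng: np.random.Generator, cls: str,
                        config: AssignmentConfig) -> ElementalComposition | None:
    c = int(rng.integers(6, 36))
    hc = rng.uniform(0.7, 2.1)
    oc = rng.uniform(0.15, 1.05)
    h = max(int(round(c * hc)), 1)
    o = max(int(round(c * oc)), 1)
    n = int(rng.integers(1, 4)) if "N" in cls else 0
    s = int(rng.integers(1, 3)) if "S" in cls else 0
    try:
        comp = ElementalComposition(C=c, H=h, N=n, O=o, S=s)
    except ValueError:
        return None
    if not config.is_plausible(comp):
        return None
    lo, hi = config.mass_range
    mz = ion_mz(comp, Adduct.DEPROTONATED)
    if not lo <= mz <= hi:
        return None
    return comp


def _separated(mz: float, taken: list[float], min_ppm: float) -> bool:
    return all(abs(ppm_error(max(mz, t), min(mz, t))) > min_ppm for t in taken)


def _draw_rts(rng: np.random.Generator, n: int) -> tuple[float, ...]:
    lo, hi = _RT_RANGE_S
    for _ in range(200):
        rts = np.sort(rng.uniform(lo, hi, size=n))
        if n == 1 or np.diff(rts).min() > _MIN_RT_GAP_S:
            return tuple(float(r) for r in rts)
    # fall back to an even grid
    return tuple(float(r) for r in np.linspace(lo, hi, n))


def make_library(
    seed: int,
    n_compositions: int = 150,
    class_mix: dict[str, float] | None = None,
    series_spec=_DEFAULT_SERIES,
    pollutant_rts: int = 13,
    config: AssignmentConfig | None = None,
) -> list[Metabolite]:
    """Sample a ground-truth metabolite library.

    Compositions are drawn inside the assignment element bounds and the
    van Krevelen envelope, in the requested chemical-class proportions,
    and rejected unless every emitted adduct ion is separated from every
    other library ion by > 3 ppm (so that within-platform alignment has
    an unambiguous truth). Homologous series and the many-RT sugar
    pollutant (a glucose chloride adduct, emulating sugar elution
    throughout the chromatographic time frame) are added on top.
    """
    if n_compositions < 1:
        raise ValueError("need at least one composition")
    mix = dict(class_mix or _DEFAULT_CLASS_MIX)
    total = sum(mix.values())
    if total <= 0 or any(v < 0 for v in mix.values()):
        raise ValueError(f"infeasible class mix: {mix}")
    for k in mix:
        mix[k] /= total
    unknown = set(mix) - {"CHO", "CHNO", "CHOS", "CHNOS"}
    if unknown:
        raise ValueError(f"infeasible class mix, unknown classes: {unknown}")

    config = config or AssignmentConfig()
    rng = np.random.default_rng(seed)
    library: list[Metabolite] = []
    taken_mz: list[float] = []
    counter = 0

    def push(comp, rts, adducts, base, origin) -> bool:
        nonlocal counter
        ions = [ion_mz(comp, ad) for ad in adducts]
        for mz in ions:
            if not _separated(mz, taken_mz, _MIN_ION_SEPARATION_PPM):
                return False
        taken_mz.extend(ions)
        library.append(
            Metabolite(f"M{counter:04d}", comp, rts, tuple(adducts), base, origin)
        )
        counter += 1
        return True

    # pollutant: glucose chloride adduct at many RTs, very intense
    glucose = _F("C6H12O6")
    push(
        glucose,
        tuple(float(r) for r in np.linspace(60.0, 344.0, pollutant_rts)),
        (Adduct.CHLORIDE,),
        5e6,
        "pollutant",
    )

    # homologous series
    for base_formula, step_formula, n_steps in series_spec:
        comp = _F(base_formula)
        step = _F(step_formula)
        for k in range(n_steps + 1):
            if ion_mz(comp, Adduct.DEPROTONATED) <= config.mass_range[1]:
                push(
                    comp,
                    _draw_rts(rng, 1),
                    (Adduct.DEPROTONATED,),
                    float(np.exp(rng.normal(np.log(1e5), 0.8))),
                    "series",
                )
            comp = comp.add(step)

    classes = list(mix)
    probs = np.array([mix[c] for c in classes])
    guard = 0
    while len(library) < n_compositions and guard < 200 * n_compositions:
        guard += 1
        cls = classes[rng.choice(len(classes), p=probs)]
        comp = _sample_composition(rng, cls, config)
        if comp is None:
            continue
        n_isomers = 1 + int(rng.geometric(0.7) - 1)  # mostly 1, tail to 3-4
        n_isomers = min(n_isomers, 4)
        adducts: list[Adduct] = [Adduct.DEPROTONATED]
        if rng.random() < 0.10:
            adducts.append(Adduct.CHLORIDE)
        if rng.random() < 0.08 and Adduct.DEPROTONATED_DEHYDRATED.is_possible(comp):
            adducts.append(Adduct.DEPROTONATED_DEHYDRATED)
        base = float(np.exp(rng.normal(np.log(1e5), 1.0)))
        push(comp, _draw_rts(rng, n_isomers), tuple(adducts), base, "random")
    if len(library) < n_compositions:
        raise RuntimeError("could not place the requested library size")
    return library


def make_design(
    seed: int,
    n_per_variety: int = 20,
    varieties=("Chardonnay", "PinotNoir", "Meunier", "Aligote"),
    regions=("Burgundy", "Languedoc", "Champagne", "UcoValley"),
    vintages=(2019, 2020, 2021),
    n_batches: int = 2,
    preparation: str = "SPE",
) -> pd.DataFrame:
    """Sample design table: variety balanced, region/vintage drawn at
    random, batches interleaved."""
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for variety in varieties:
        for _ in range(n_per_variety):
            rows.append(
                {
                    "variety": variety,
                    "region": regions[rng.integers(len(regions))],
                    "vintage": int(vintages[rng.integers(len(vintages))]),
                    "batch": f"B{k % n_batches + 1}",
                    "preparation": preparation,
                }
            )
            k += 1
    design = pd.DataFrame(rows, index=pd.Index(
        [f"S{j:03d}" for j in range(len(rows))], name="sample"))
    return design


def make_markers(
    library: list[Metabolite],
    seed: int,
    n_markers: int = 50,
    factor: str = "variety",
    level: str = "Chardonnay",
    fold: float = 3.0,
) -> pd.DataFrame:
    """Pick random single-isomer [M−H]− metabolites as class markers:
    samples of ``level`` get ``fold`` × the base intensity."""
    rng = np.random.default_rng(seed)
    eligible = [m.mid for m in library
                if m.origin == "random" and m.n_isomers == 1]
    if len(eligible) < n_markers:
        raise ValueError("library too small for the requested marker count")
    chosen = rng.choice(eligible, size=n_markers, replace=False)
    return pd.DataFrame(
        {"mid": sorted(chosen), "factor": factor, "level": level, "fold": fold}
    )


# --------------------------------------------------------------------------
# Emission
# --------------------------------------------------------------------------


def emit_peaklists(
    library: list[Metabolite],
    design: pd.DataFrame,
    noise: NoiseSpec | None = None,
    seed: int = 0,
    markers: pd.DataFrame | None = None,
    batch_effects: dict[str, float] | None = None,
) -> tuple[list[PeakList], list[PeakList], GroundTruth]:
    """Emit per-sample DI and LC peak lists plus the traceable truth.

    For every sample and every detected (metabolite, adduct): one DI
    peak whose m/z carries multiplicative Gaussian error (``di_ppm_sd``)
    and whose intensity is the sum over isomers; and one LC peak per
    isomer with its own mass error (``lc_ppm_sd``), RT jitter and an
    intensity share fixed per metabolite. Marker fold changes multiply
    the intensity for samples of the marked level; batch effects
    multiply all intensities of a batch. With zero noise and zero
    dropout the emitted m/z equal the theoretical ion m/z exactly.
    """
    if design.empty:
        raise ValueError("design table is empty")
    noise = noise or NoiseSpec()
    rng = np.random.default_rng(seed)
    batch_effects = batch_effects or {}
    marker_map: dict[str, tuple[str, str, float]] = {}
    if markers is not None:
        for _, row in markers.iterrows():
            marker_map[row["mid"]] = (row["factor"], str(row["level"]),
                                      float(row["fold"]))

    sigma_ln = math.sqrt(math.log(1.0 + noise.intensity_cv**2))
    # per-metabolite isomer intensity shares (fixed across samples)
    shares = {
        m.mid: (
            np.full(m.n_isomers, 1.0 / m.n_isomers)
            if m.n_isomers == 1
            else rng.dirichlet(np.full(m.n_isomers, 5.0))
        )
        for m in library
    }

    di_lists: list[PeakList] = []
    lc_lists: list[PeakList] = []
    trace_rows = []
    for sample_id, meta in design.iterrows():
        di_rows = []
        lc_rows = []
        batch_mult = float(batch_effects.get(str(meta.get("batch")), 1.0))
        for m in library:
            fold = 1.0
            if m.mid in marker_map:
                factor, level, f = marker_map[m.mid]
                if str(meta.get(factor)) == level:
                    fold = f
            for adduct in m.adducts:
                expected = m.base_intensity * fold * batch_mult
                intensity = expected * float(
                    np.exp(rng.normal(-0.5 * sigma_ln**2, sigma_ln))
                )
                if rng.random() < noise.dropout_probability(intensity):
                    continue
                theo = ion_mz(m.composition, adduct)
                # DI: isomers coelute into one peak
                mz_di = theo * (1.0 + rng.normal(0.0, noise.di_ppm_sd) * 1e-6)
                di_rows.append(
                    (mz_di, intensity, intensity / noise.snr_noise_floor)
                )
                trace_rows.append(
                    {"sample": sample_id, "mid": m.mid, "adduct": adduct.label,
                     "platform": "DI", "isomer": -1, "mz": mz_di,
                     "intensity": intensity}
                )
                for iso, (rt, share) in enumerate(zip(m.rts_s, shares[m.mid])):
                    mz_lc = theo * (1.0 + rng.normal(0.0, noise.lc_ppm_sd) * 1e-6)
                    rt_obs = rt + rng.normal(0.0, noise.rt_jitter_s)
                    lc_rows.append((mz_lc, rt_obs, intensity * share))
                    trace_rows.append(
                        {"sample": sample_id, "mid": m.mid,
                         "adduct": adduct.label, "platform": "LC",
                         "isomer": iso, "mz": mz_lc,
                         "intensity": intensity * share}
                    )
        di_lists.append(
            PeakList(str(sample_id), pd.DataFrame(
                di_rows, columns=["mz", "intensity", "snr"]))
        )
        lc_lists.append(
            PeakList(str(sample_id), pd.DataFrame(
                lc_rows, columns=["mz", "rt_s", "intensity"]))
        )
    truth = GroundTruth(
        library=library,
        design=design.copy(),
        markers=markers.copy() if markers is not None else pd.DataFrame(
            columns=["mid", "factor", "level", "fold"]),
        noise=noise,
        emitted=pd.DataFrame(trace_rows),
        seed=seed,
    )
    return di_lists, lc_lists, truth


# --------------------------------------------------------------------------
# Scoring
# --------------------------------------------------------------------------


def truth_report(
    truth: GroundTruth,
    feature_matrix,
    assignments=None,
    vip: pd.Series | None = None,
    match_ppm: float = 0.5,
) -> dict:
    """Score pipeline outputs against the generator's truth.

    Metrics (all in [0, 1]):

    * ``alignment_recall`` — emitted ions recovered as at least one
      feature within ``match_ppm`` of the true ion m/z;
    * ``alignment_precision`` — features tracing back to a true ion;
    * ``alignment_split_rate`` — true ions matched by more than one
      feature (0 is the clean outcome);
    * ``assignment_accuracy`` — assigned features whose neutral formula
      and adduct equal the truth (when ``assignments`` given);
    * ``marker_recovery`` — planted markers found in the top-k VIP ranks
      (k = number of planted markers; when ``vip`` given).

    Rejects output whose sample set does not match the generating
    design (a mismatched-dataset guard).
    """
    out_samples = list(feature_matrix.intensities.index)
    if set(out_samples) - set(truth.design.index.astype(str)):
        raise ValueError("feature matrix samples do not match the design "
                         "(mismatched datasets)")
    lib = truth.library_table()
    emitted_keys = set(
        truth.emitted.loc[truth.emitted["platform"] == "DI", ["mid", "adduct"]]
        .itertuples(index=False, name=None)
    )
    lib = lib[[(m, a) in emitted_keys
               for m, a in zip(lib["mid"], lib["adduct"])]]
    feats = feature_matrix.features
    fmz = feats["mz"].to_numpy()
    report: dict = {}
    hits_per_ion = []
    matched_features = np.zeros(len(fmz), dtype=bool)
    for mz in lib["ion_mz"]:
        d_ppm = np.abs(fmz - mz) / mz * 1e6
        hit = d_ppm <= match_ppm
        hits_per_ion.append(int(hit.sum()))
        matched_features |= hit
    hits = np.array(hits_per_ion)
    report["alignment_recall"] = float((hits >= 1).mean()) if len(hits) else 1.0
    report["alignment_split_rate"] = float((hits > 1).mean()) if len(hits) else 0.0
    report["alignment_precision"] = (
        float(matched_features.mean()) if len(fmz) else 1.0
    )

    if assignments is not None:
        truth_by_mz = {
            (row["mid"], row["adduct"]): (row["formula"], row["ion_mz"])
            for _, row in lib.iterrows()
        }
        correct = 0
        scored = 0
        for cand in assignments:
            d = [
                (abs(cand.observed_mz - imz) / imz * 1e6, formula)
                for (formula, imz) in (
                    (f, i) for (f, i) in truth_by_mz.values()
                )
            ]
            d.sort()
            if not d or d[0][0] > match_ppm:
                continue  # peak does not correspond to a planted ion
            scored += 1
            if cand.neutral.formula() == d[0][1]:
                correct += 1
        report["assignment_accuracy"] = correct / scored if scored else 1.0

    if vip is not None and len(truth.markers):
        marker_mids = set(truth.markers["mid"])
        marker_mzs = lib.loc[lib["mid"].isin(marker_mids), "ion_mz"].to_numpy()
        k = len(marker_mids)
        top = vip.sort_values(ascending=False).head(k).index
        top_mz = feats.loc[top, "mz"].to_numpy()
        found = 0
        for mz in marker_mzs:
            if np.any(np.abs(top_mz - mz) / mz * 1e6 <= match_ppm):
                found += 1
        report["marker_recovery"] = found / k if k else 1.0
    return report


def make_varpart_dataset(
    seed: int,
    n_samples: int = 100,
    n_features: int = 50,
    variety_frac: float = 0.16,
    region_frac: float = 0.10,
    n_regions: int = 4,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Gaussian response with calibrated factor variance shares.

    Variety is a balanced two-level factor contributing
    ``variety_frac`` of each feature's variance, region an independent
    ``n_regions``-level factor contributing ``region_frac``; the rest is
    white noise. Used to exercise RDA variance partitioning against a
    known decomposition.
    """
    rng = np.random.default_rng(seed)
    variety = np.array(["Chardonnay", "PinotNoir"])[
        np.arange(n_samples) % 2
    ]
    region_labels = np.array([f"R{k}" for k in range(n_regions)])
    region = region_labels[rng.integers(n_regions, size=n_samples)]
    v_sign = np.where(variety == "Chardonnay", 1.0, -1.0)
    v_load = np.sqrt(variety_frac) * np.ones(n_features)
    r_eff = rng.normal(0.0, 1.0, size=(n_regions, n_features))
    r_eff -= r_eff.mean(axis=0)
    r_eff *= np.sqrt(region_frac) / max(r_eff.std(axis=0).mean(), 1e-12)
    noise_sd = math.sqrt(max(1.0 - variety_frac - region_frac, 0.0))
    Y = (
        np.outer(v_sign, v_load)
        + r_eff[np.searchsorted(region_labels, region)]
        + rng.normal(0.0, noise_sd, size=(n_samples, n_features))
    )
    factors = pd.DataFrame({"variety": variety, "region": region})
    return Y, factors
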