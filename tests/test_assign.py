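"""Formula assignment: brute-force oracle, enumeration, network
propagation."""

import itertools

import numpy as np
import pytest

from grapemet.assign import (
    AssignmentConfig,
    DEFAULT_EDGES,
    MassDifferenceNetwork,
    assign_by_network,
    assignment_summary,
    enumerate_formulas,
)
from grapemet.chem import Adduct, ElementalComposition, ion_mz, monoisotopic_mass
from grapemet.constants import ELECTRON_MASS, MONOISOTOPIC_MASS

F = ElementalComposition.from_formula

REDUCED_BOUNDS = {"C": (1, 25), "H": (1, 40), "N": (0, 3), "O": (0, 15),
                  "S": (0, 2)}


def brute_force_candidates(mz, config):
    """Independent oracle: plain nested loops over every element-count
    tuple in the bounds, with plausibility recomputed inline.

    Written first and kept here as the reference the production
    enumerator must equal exactly.
    """
    m = MONOISOTOPIC_MASS
    out = set()
    b = config.bounds
    for adduct in config.adducts:
        target = mz - adduct.mass_delta - (
            ELECTRON_MASS if config.include_electron else 0.0
        )
        for c, n, o, s in itertools.product(
            range(b["C"][0], b["C"][1] + 1),
            range(b["N"][0], b["N"][1] + 1),
            range(b["O"][0], b["O"][1] + 1),
            range(b["S"][0], b["S"][1] + 1),
        ):
            base = c * m["C"] + n * m["N"] + o * m["O"] + s * m["S"]
            if base > target + 1:
                continue
            for h in range(b["H"][0], b["H"][1] + 1):
                mass = base + h * m["H"]
                if abs(mz - (mass + adduct.mass_delta
                             + (ELECTRON_MASS if config.include_electron
                                else 0.0))) / mz * 1e6 > config.tolerance_ppm:
                    continue
                # plausibility, recomputed from scratch
                r = c - h / 2 + n / 2 + 1
                if not config.rdbe_range[0] <= r <= config.rdbe_range[1]:
                    continue
                if not config.hc_range[0] <= h / c <= config.hc_range[1]:
                    continue
                if o / c > config.oc_max:
                    continue
                # adduct feasibility on the neutral
                if adduct is Adduct.DEPROTONATED and h < 1:
                    continue
                if adduct is Adduct.DEPROTONATED_DEHYDRATED and (h < 3 or o < 1):
                    continue
                counts = {"C": c, "H": h, "N": n, "O": o, "S": s}
                formula = "".join(
                    f"{e}{counts[e]}" if counts[e] > 1 else e
                    for e in ("C", "H", "N", "O", "S") if counts[e]
                )
                out.add((formula, adduct.label))
    return out


def test_enumeration_equals_brute_force_oracle():
    """The production enumerator returns exactly the oracle's set on
    random masses under reduced bounds."""
    rng = np.random.default_rng(2024)
    config = AssignmentConfig(bounds=dict(REDUCED_BOUNDS))
    masses = list(rng.uniform(92, 450, size=15))
    # include masses guaranteed to hit: real ion m/z values, some nudged
    for formula, adduct in [
        ("C6H12O6", Adduct.CHLORIDE),
        ("C6H12O6", Adduct.DEPROTONATED),
        ("C11H12N2O2", Adduct.DEPROTONATED),
        ("C9H14O4S", Adduct.DEPROTONATED),
        ("C12H22O11", Adduct.DEPROTONATED),
    ]:
        mz = ion_mz(F(formula), adduct)
        masses += [mz, mz * (1 + 0.3e-6), mz * (1 - 0.4e-6)]
    for mz in masses:
        got = {
            (c.neutral.formula(), c.adduct.label)
            for c in enumerate_formulas(mz, config)
        }
        assert got == brute_force_candidates(mz, config), f"mz={mz}"


def test_glucose_chloride_is_first_candidate():
    config = AssignmentConfig(adducts=(Adduct.CHLORIDE,))
    cands = enumerate_formulas(215.03279, config)
    assert cands, "expected at least one candidate"
    assert cands[0].neutral.formula() == "C6H12O6"
    assert cands[0].adduct is Adduct.CHLORIDE


def test_tryptophan_assignment():
    config = AssignmentConfig(adducts=(Adduct.DEPROTONATED,))
    cands = enumerate_formulas(203.08257, config)
    assert [c.neutral.formula() for c in cands] == ["C11H12N2O2"]
    assert cands[0].status == "ok"  # unambiguous
    assert abs(cands[0].error_ppm) < 0.5


def test_mass_below_range_rejected():
    with pytest.raises(ValueError, match="mass range"):
        enumerate_formulas(12.0, AssignmentConfig())


def test_monotone_in_tolerance_and_bounds():
    """Enlarging the window or the bounds never loses a candidate."""
    mz = ion_mz(F("C10H16O8"), Adduct.DEPROTONATED) * (1 + 0.2e-6)
    small = AssignmentConfig(tolerance_ppm=0.5, bounds=dict(REDUCED_BOUNDS))
    wide_tol = AssignmentConfig(tolerance_ppm=2.0, bounds=dict(REDUCED_BOUNDS))
    wide_bounds = AssignmentConfig(
        tolerance_ppm=0.5,
        bounds={"C": (1, 40), "H": (1, 80), "N": (0, 6), "O": (0, 30),
                "S": (0, 3)},
    )
    key = lambda cands: {(c.neutral.formula(), c.adduct.label) for c in cands}
    base = key(enumerate_formulas(mz, small))
    assert base <= key(enumerate_formulas(mz, wide_tol))
    assert base <= key(enumerate_formulas(mz, wide_bounds))


def test_candidate_order_deterministic():
    mz = 400.124
    config = AssignmentConfig(tolerance_ppm=5.0, bounds=dict(REDUCED_BOUNDS))
    a = enumerate_formulas(mz, config)
    b = enumerate_formulas(mz, config)
    assert [(c.neutral.formula(), c.adduct.label) for c in a] == [
        (c.neutral.formula(), c.adduct.label) for c in b
    ]
    errs = [abs(c.error_ppm) for c in a]
    assert errs == sorted(errs)


# -- network ---------------------------------------------------------------


def test_network_glycosyl_propagation():
    """Glucose seed plus one glycosyl edge annotates the disaccharide."""
    config = AssignmentConfig(adducts=(Adduct.DEPROTONATED,))
    peaks = [
        ion_mz(F("C6H12O6"), Adduct.DEPROTONATED),
        ion_mz(F("C12H22O11"), Adduct.DEPROTONATED),
    ]
    assert peaks[1] == pytest.approx(341.108936, abs=2e-6)
    out = assign_by_network(peaks, MassDifferenceNetwork.default(), config)
    got = {round(a.observed_mz, 5): a.neutral.formula() for a in out}
    assert got[round(peaks[0], 5)] == "C6H12O6"
    assert got[round(peaks[1], 5)] == "C12H22O11"


def test_network_isolated_seed_only():
    config = AssignmentConfig(adducts=(Adduct.DEPROTONATED,))
    seed_mz = ion_mz(F("C6H12O6"), Adduct.DEPROTONATED)
    out = assign_by_network([seed_mz, 800.5], MassDifferenceNetwork.default(),
                            config)
    assert len(out) == 1 and out[0].neutral.formula() == "C6H12O6"


def test_inconsistent_seed_rejected():
    config = AssignmentConfig()
    net = MassDifferenceNetwork.default()
    net.seeds[0] = (net.seeds[0][0] + 0.01, net.seeds[0][1], net.seeds[0][2])
    with pytest.raises(ValueError, match="inconsistent seed"):
        assign_by_network([200.0], net, config)


def test_network_subset_of_enumeration_and_order_invariant():
    """Every network assignment is reachable by enumeration at the same
    tolerance, and the result ignores peak-list order."""
    rng = np.random.default_rng(5)
    config = AssignmentConfig(adducts=(Adduct.DEPROTONATED,))
    chain = [F("C6H12O6")]
    for step in ("C6H10O5", "CH2", "O", "C2H2O"):
        chain.append(chain[-1].add(F(step)))
    peaks = [ion_mz(c, Adduct.DEPROTONATED) * (1 + rng.normal(0, 0.1) * 1e-6)
             for c in chain]
    net = MassDifferenceNetwork.default()
    out = assign_by_network(peaks, net, config)
    assert len(out) == len(peaks)
    for cand in out:
        enum = {
            c.neutral.formula()
            for c in enumerate_formulas(cand.observed_mz, config)
        }
        assert cand.neutral.formula() in enum
    shuffled = list(peaks)
    rng.shuffle(shuffled)
    out2 = assign_by_network(shuffled, net, config)
    assert {(round(a.observed_mz, 6), a.neutral.formula()) for a in out} == {
        (round(a.observed_mz, 6), a.neutral.formula()) for a in out2
    }


def test_edge_library_masses_consistent():
    for formula, _name in DEFAULT_EDGES:
        comp = F(formula)
        assert monoisotopic_mass(comp) > 0


def test_assignment_summary():
    assert assignment_summary([]) == {
        "n_assigned": 0, "n_peaks": 0, "assigned_fraction": 0.0,
        "by_class": {}, "by_adduct": {},
    }
    config = AssignmentConfig(adducts=(Adduct.DEPROTONATED,))
    cands = enumerate_formulas(203.08257, config) + enumerate_formulas(
        ion_mz(F("C6H12O6"), Adduct.DEPROTONATED), config
    )
    s = assignment_summary(cands, n_peaks=3)
    assert s["n_assigned"] == len(cands)
    assert s["by_class"].get("CHNO", 0) >= 1
    assert s["by_class"].get("CHO", 0) >= 1
    assert 0 < s["assigned_fraction"] <= 1
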