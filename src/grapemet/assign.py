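"""Elemental-composition assignment for negative-mode mass peaks.

Two complementary assigners operate within a ppm tolerance window:

* :func:`enumerate_formulas` — exhaustive decomposition of one m/z over a
  bounded C/H/N/O/S lattice, the reference method;
* :func:`assign_by_network` — propagation of compositions from a few
  trusted seed ions along a library of exact biochemical mass differences
  (CH2 homologation, glycosylation, amino-acid residues, ...), which is
  how ultra-high-resolution peak lists are annotated in practice: the
  network visits only observed peaks and inherits chemistry from its
  neighbours instead of re-enumerating the lattice at every mass.

Both return :class:`CandidateAssignment` records; every network assignment
is guaranteed to lie within the enumeration tolerance of its own m/z, so
the network result is always a subset of what enumeration would accept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import yaml

from .chem import (
    Adduct,
    ElementalComposition,
    chemical_class,
    ion_mz,
    monoisotopic_mass,
    ppm_error,
    rdbe,
    van_krevelen,
)
from .constants import ELECTRON_MASS, MONOISOTOPIC_MASS

__all__ = [
    "AssignmentConfig",
    "CandidateAssignment",
    "MassDifferenceNetwork",
    "enumerate_formulas",
    "assign_by_network",
    "assignment_summary",
    "write_assignment_table",
    "DEFAULT_SEEDS",
    "DEFAULT_EDGES",
]

_DEFAULT_BOUNDS = {
    "C": (1, 70),
    "H": (1, 130),
    "N": (0, 10),
    "O": (0, 45),
    "S": (0, 4),
}


@dataclass(frozen=True)
class AssignmentConfig:
    """Tolerance, search bounds and plausibility filters for assignment.

    Defaults follow ultra-high-resolution practice for plant extracts:
    a 0.5 ppm window, a 92–1000 Da mass range, and generous van Krevelen
    / RDBE envelopes that admit every plotted metabolite class with
    headroom.
    """

    tolerance_ppm: float = 0.5
    bounds: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(_DEFAULT_BOUNDS)
    )
    adducts: tuple[Adduct, ...] = (
        Adduct.DEPROTONATED,
        Adduct.DEPROTONATED_DEHYDRATED,
        Adduct.CHLORIDE,
    )
    rdbe_range: tuple[float, float] = (0.0, 40.0)
    hc_range: tuple[float, float] = (0.2, 3.1)
    oc_max: float = 1.5
    mass_range: tuple[float, float] = (92.0, 1000.0)
    include_electron: bool = True

    def __post_init__(self) -> None:
        if self.tolerance_ppm <= 0:
            raise ValueError("tolerance must be positive")
        lo, hi = self.mass_range
        if lo <= 0 or hi <= lo:
            raise ValueError("mass range must be positive and ordered")
        for e, (bmin, bmax) in self.bounds.items():
            if bmin < 0 or bmax < bmin:
                raise ValueError(f"bad bounds for {e}: {bmin}..{bmax}")

    def is_plausible(self, neutral: ElementalComposition) -> bool:
        """RDBE / van Krevelen / element-bound plausibility filter."""
        for e, (bmin, bmax) in self.bounds.items():
            if not bmin <= neutral.get(e) <= bmax:
                return False
        if neutral.get("C") == 0:
            return False
        r = rdbe(neutral)
        if not self.rdbe_range[0] <= r <= self.rdbe_range[1]:
            return False
        oc, hc = van_krevelen(neutral)
        if not self.hc_range[0] <= hc <= self.hc_range[1]:
            return False
        if oc > self.oc_max:
            return False
        return True

    @classmethod
    def from_yaml(cls, path) -> "AssignmentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bounds" in raw:
            raw["bounds"] = {e: tuple(v) for e, v in raw["bounds"].items()}
        if "adducts" in raw:
            raw["adducts"] = tuple(Adduct.from_label(a) for a in raw["adducts"])
        for key in ("rdbe_range", "hc_range", "mass_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        raw = {
            "tolerance_ppm": self.tolerance_ppm,
            "bounds": {e: list(v) for e, v in self.bounds.items()},
            "adducts": [a.label for a in self.adducts],
            "rdbe_range": list(self.rdbe_range),
            "hc_range": list(self.hc_range),
            "oc_max": self.oc_max,
            "mass_range": list(self.mass_range),
            "include_electron": self.include_electron,
        }
        with open(path, "w") as fh:
            yaml.safe_dump(raw, fh, sort_keys=False)


@dataclass(frozen=True)
class CandidateAssignment:
    """One (neutral composition, adduct) explanation of an observed m/z.

    ``error_ppm`` follows the convention (observed − theoretical) /
    observed × 1e6. The annotation reported to users is always the
    NEUTRAL formula plus the adduct tag — never the bare ion
    stoichiometry, which is ambiguous across adducts.
    """

    observed_mz: float
    neutral: ElementalComposition
    adduct: Adduct
    error_ppm: float
    provenance: str = "enumeration"  # or "network"
    status: str = "ok"  # or "conflict" / "ambiguous"

    @property
    def chemical_class(self) -> str:
        return chemical_class(self.neutral)

    @property
    def theoretical_mz(self) -> float:
        return ion_mz(self.neutral, self.adduct)


def _heteroatoms(comp: ElementalComposition) -> int:
    return comp.get("N") + comp.get("O") + comp.get("S")


def _sort_key(cand: CandidateAssignment):
    return (abs(cand.error_ppm), _heteroatoms(cand.neutral), cand.neutral.formula())


def enumerate_formulas(
    mz: float, config: AssignmentConfig | None = None
) -> list[CandidateAssignment]:
    """All bounded-lattice (composition, adduct) pairs matching ``mz``.

    Returns the exact set of neutral CHNOS compositions whose anion m/z
    under any configured adduct lies within ``config.tolerance_ppm`` of
    the observed value and which pass the plausibility filters, sorted by
    |ppm error|, then by heteroatom count, then by formula string. An
    empty list means "unassigned peak" and is a valid outcome.

    The search is organised per adduct: the implied neutral target mass
    is scanned over the (S, N, O, C) sub-lattice vectorised with numpy,
    and the hydrogen count is solved from the mass remainder — only a
    handful of H values can fall inside a sub-ppm window, so the lattice
    never needs to be enumerated over H explicitly.
    """
    config = config or AssignmentConfig()
    lo, hi = config.mass_range
    if not lo <= mz <= hi:
        raise ValueError(f"m/z {mz} outside configured mass range {lo}–{hi} Da")

    tol_da = config.tolerance_ppm * 1e-6 * mz
    m = MONOISOTOPIC_MASS
    c_lo, c_hi = config.bounds.get("C", (1, 70))
    h_lo, h_hi = config.bounds.get("H", (1, 130))
    n_lo, n_hi = config.bounds.get("N", (0, 10))
    o_lo, o_hi = config.bounds.get("O", (0, 45))
    s_lo, s_hi = config.bounds.get("S", (0, 4))

    out: list[CandidateAssignment] = []
    for adduct in config.adducts:
        target = mz - adduct.mass_delta
        if config.include_electron:
            target -= ELECTRON_MASS
        # lattice over S, N, O, C; H solved from the remainder
        s = np.arange(s_lo, s_hi + 1)
        n = np.arange(n_lo, n_hi + 1)
        o = np.arange(o_lo, o_hi + 1)
        c = np.arange(c_lo, c_hi + 1)
        S, N, O, C = np.meshgrid(s, n, o, c, indexing="ij")
        base = S * m["S"] + N * m["N"] + O * m["O"] + C * m["C"]
        remainder = target - base
        h0 = np.rint(remainder / m["H"]).astype(np.int64)
        for dh in (-1, 0, 1):
            H = h0 + dh
            ok = (H >= h_lo) & (H <= h_hi)
            ok &= np.abs(remainder - H * m["H"]) <= tol_da
            if not ok.any():
                continue
            for i_s, i_n, i_o, i_c in np.argwhere(ok):
                neutral = ElementalComposition(
                    C=int(C[i_s, i_n, i_o, i_c]),
                    H=int(H[i_s, i_n, i_o, i_c]),
                    N=int(N[i_s, i_n, i_o, i_c]),
                    O=int(O[i_s, i_n, i_o, i_c]),
                    S=int(S[i_s, i_n, i_o, i_c]),
                )
                if not adduct.is_possible(neutral):
                    continue
                if not config.is_plausible(neutral):
                    continue
                theo = ion_mz(neutral, adduct, include_electron=config.include_electron)
                err = ppm_error(mz, theo)
                if abs(err) <= config.tolerance_ppm:
                    out.append(
                        CandidateAssignment(mz, neutral, adduct, err, "enumeration")
                    )
    # de-duplicate (an identical (neutral, adduct) cannot arise twice, but
    # the ±1 hydrogen probes can in principle revisit a cell)
    seen: set[tuple[ElementalComposition, Adduct]] = set()
    unique = []
    for cand in sorted(out, key=_sort_key):
        key = (cand.neutral, cand.adduct)
        if key not in seen:
            seen.add(key)
            unique.append(cand)
    if len(unique) > 1:
        unique = [replace(cand, status="ambiguous") for cand in unique]
    return unique


# --------------------------------------------------------------------------
# Mass-difference network
# --------------------------------------------------------------------------

_F = ElementalComposition.from_formula

#: Default seed ions: ubiquitous grape-juice metabolites observed as
#: [M−H]− (sugars, organic acids, tryptophan).
DEFAULT_SEEDS: tuple[tuple[str, str], ...] = (
    ("C6H12O6", "glucose"),
    ("C6H12O6", "fructose"),
    ("C4H6O6", "tartaric acid"),
    ("C4H6O5", "malic acid"),
    ("C11H12N2O2", "tryptophan"),
)

#: Biochemical mass differences used for propagation: homologation,
#: oxidation states, hydration, amination, sulfonation, acetylation,
#: glycosylation, and the proteinogenic amino-acid residues.
DEFAULT_EDGES: tuple[tuple[str, str], ...] = (
    ("H2", "hydrogenation"),
    ("CH2", "methylene homologation"),
    ("O", "oxidation"),
    ("CO", "carbonyl"),
    ("CO2", "carboxylation"),
    ("H2O", "hydration"),
    ("NH", "imination"),
    ("NH3", "amination"),
    ("S", "sulfur"),
    ("SO3", "sulfonation"),
    ("C2H2O", "acetylation"),
    ("C6H10O5", "glycosylation"),
    # amino-acid residues (condensation deltas)
    ("C2H3NO", "Gly residue"),
    ("C3H5NO", "Ala residue"),
    ("C3H5NO2", "Ser residue"),
    ("C5H7NO", "Pro residue"),
    ("C5H9NO", "Val residue"),
    ("C4H7NO2", "Thr residue"),
    ("C3H5NOS", "Cys residue"),
    ("C6H11NO", "Leu/Ile residue"),
    ("C4H6N2O2", "Asn residue"),
    ("C4H5NO3", "Asp residue"),
    ("C5H8N2O2", "Gln residue"),
    ("C6H12N2O", "Lys residue"),
    ("C5H7NO3", "Glu residue"),
    ("C5H9NOS", "Met residue"),
    ("C6H7N3O", "His residue"),
    ("C9H9NO", "Phe residue"),
    ("C6H12N4O", "Arg residue"),
    ("C9H9NO2", "Tyr residue"),
    ("C11H10N2O", "Trp residue"),
)


@dataclass
class MassDifferenceNetwork:
    """Seeds plus an exact-mass edge library for composition propagation.

    Seeds are (m/z, neutral composition, adduct) triples that anchor the
    network; every edge's composition delta and mass delta are mutually
    consistent through the monoisotopic mass table by construction.
    """

    seeds: list[tuple[float, ElementalComposition, Adduct]]
    edges: list[tuple[str, ElementalComposition, float]]

    @classmethod
    def default(
        cls,
        adduct: Adduct = Adduct.DEPROTONATED,
        *,
        extra_seeds: Iterable[tuple[ElementalComposition, Adduct]] = (),
    ) -> "MassDifferenceNetwork":
        seeds = [
            (ion_mz(_F(f), adduct), _F(f), adduct) for f, _name in DEFAULT_SEEDS
        ]
        for comp, ad in extra_seeds:
            seeds.append((ion_mz(comp, ad), comp, ad))
        edges = [
            (name, _F(f), monoisotopic_mass(_F(f))) for f, name in DEFAULT_EDGES
        ]
        return cls(seeds=seeds, edges=edges)


def assign_by_network(
    peaks: Sequence[float],
    network: MassDifferenceNetwork,
    config: AssignmentConfig | None = None,
) -> list[CandidateAssignment]:
    """Propagate compositions from seeds along matched mass differences.

    Peaks are matched to seeds (within tolerance of the seed ion m/z) and
    then visited breadth-first: an unassigned peak whose mass difference
    to an assigned neighbour matches an edge delta — within the tolerance
    expressed in ppm of the heavier of the two masses — inherits the
    neighbour's composition plus/minus the edge's composition delta,
    provided the result passes the plausibility filters and reproduces
    the peak's own m/z within tolerance. Peaks reachable by several paths
    must agree on a single composition; disagreeing peaks are returned
    flagged ``"conflict"``. Re-running on a permuted peak list yields
    identical assignments (the frontier is processed in m/z order).
    """
    config = config or AssignmentConfig()
    tol = config.tolerance_ppm
    order = sorted(range(len(peaks)), key=lambda i: peaks[i])
    mzs = [float(peaks[i]) for i in order]

    # validate seeds, attach to matching peaks
    assigned: dict[int, tuple[ElementalComposition, Adduct]] = {}
    conflict: set[int] = set()
    for seed_mz, comp, adduct in network.seeds:
        theo = ion_mz(comp, adduct, include_electron=config.include_electron)
        if abs(ppm_error(seed_mz, theo)) > tol:
            raise ValueError(
                f"inconsistent seed: m/z {seed_mz} vs {comp.formula()} "
                f"{adduct.label} (theoretical {theo:.6f})"
            )
    if not network.seeds:
        raise ValueError("network requires at least one seed")

    frontier: list[int] = []
    for i, mz in enumerate(mzs):
        for seed_mz, comp, adduct in network.seeds:
            if abs(ppm_error(mz, ion_mz(comp, adduct,
                                        include_electron=config.include_electron))) <= tol:
                if i in assigned and assigned[i][0] != comp:
                    conflict.add(i)
                elif i not in assigned:
                    assigned[i] = (comp, adduct)
                    frontier.append(i)

    def try_set(j: int, comp: ElementalComposition, adduct: Adduct) -> bool:
        theo = ion_mz(comp, adduct, include_electron=config.include_electron)
        if abs(ppm_error(mzs[j], theo)) > tol:
            return False
        if not config.is_plausible(comp):
            return False
        if j in assigned:
            if assigned[j][0] != comp:
                conflict.add(j)
            return False
        assigned[j] = (comp, adduct)
        return True

    # BFS over the implicit graph; edges probed against every yet-unassigned
    # peak (peak lists are small enough that the O(frontier × peaks × edges)
    # scan is the clear, deterministic choice).
    while frontier:
        frontier.sort(key=lambda i: mzs[i])
        next_frontier: list[int] = []
        for i in list(frontier):
            comp_i, adduct_i = assigned[i]
            for j in range(len(mzs)):
                if j == i:
                    continue
                diff = mzs[j] - mzs[i]
                heavier = max(mzs[i], mzs[j])
                for _name, delta_comp, delta_mass in network.edges:
                    if abs(abs(diff) - delta_mass) > tol * 1e-6 * heavier:
                        continue
                    try:
                        cand = (
                            comp_i.add(delta_comp)
                            if diff > 0
                            else comp_i.subtract(delta_comp)
                        )
                    except ValueError:
                        continue
                    if try_set(j, cand, adduct_i):
                        next_frontier.append(j)
        frontier = next_frontier

    out: list[CandidateAssignment] = []
    for i in sorted(assigned, key=lambda i: mzs[i]):
        comp, adduct = assigned[i]
        theo = ion_mz(comp, adduct, include_electron=config.include_electron)
        out.append(
            CandidateAssignment(
                mzs[i],
                comp,
                adduct,
                ppm_error(mzs[i], theo),
                provenance="network",
                status="conflict" if i in conflict else "ok",
            )
        )
    return out


def assignment_summary(
    assignments: Sequence[CandidateAssignment], n_peaks: int | None = None
) -> dict:
    """Counts per chemical class and per adduct, plus assigned fraction.

    ``n_peaks`` is the number of peaks submitted for assignment; when
    omitted, the number of distinct observed m/z values is used.
    """
    by_class: dict[str, int] = {}
    by_adduct: dict[str, int] = {}
    mz_seen = set()
    for cand in assignments:
        by_class[cand.chemical_class] = by_class.get(cand.chemical_class, 0) + 1
        by_adduct[cand.adduct.label] = by_adduct.get(cand.adduct.label, 0) + 1
        mz_seen.add(cand.observed_mz)
    total = n_peaks if n_peaks is not None else len(mz_seen)
    return {
        "n_assigned": len(assignments),
        "n_peaks": total,
        "assigned_fraction": (len(mz_seen) / total) if total else 0.0,
        "by_class": by_class,
        "by_adduct": by_adduct,
    }


def write_assignment_table(
    assignments: Sequence[CandidateAssignment], path, sep: str = "\t"
) -> None:
    """Write assignments as delimited text (one row per candidate)."""
    cols = ["mz", "formula", "adduct", "error_ppm", "class", "o_to_c", "h_to_c",
            "provenance", "status"]
    with open(path, "w") as fh:
        fh.write(sep.join(cols) + "\n")
        for cand in assignments:
            oc, hc = van_krevelen(cand.neutral)
            fh.write(
                sep.join(
                    [
                        f"{cand.observed_mz:.6f}",
                        cand.neutral.formula(),
                        cand.adduct.label,
                        f"{cand.error_ppm:.4f}",
                        cand.chemical_class,
                        f"{oc:.4f}",
                        f"{hc:.4f}",
                        cand.provenance,
                        cand.status,
                    ]
                )
                + "\n"
            )
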