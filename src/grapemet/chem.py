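"""Exact-mass chemistry for negative-mode metabolomics annotation.

The unit of annotation is an :class:`ElementalComposition` — integer atom
counts over C, H, N, O, S (Cl only enters through chloride adducts, never
as part of a neutral metabolite). Ions are singly charged anions of the
three species relevant to ESI(−) grape-juice work: [M−H]−, [M−H−H2O]− and
[M+Cl]−. The anion m/z includes the mass of the acquired electron; this is
what reproduces published FT-ICR peak positions to the fifth decimal (the
chloride adduct of glucose computes to 215.03279 Da with the electron,
215.03224 without — a 2.5 ppm discrepancy an ultra-high-resolution
instrument resolves easily).
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass
from typing import Iterator, Mapping

from .constants import ELECTRON_MASS, MONOISOTOPIC_MASS, SUPPORTED_ELEMENTS

__all__ = [
    "ElementalComposition",
    "Adduct",
    "monoisotopic_mass",
    "ion_mz",
    "neutral_mass_from_mz",
    "ppm_error",
    "chemical_class",
    "van_krevelen",
    "rdbe",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")

# Hill order for CH-containing formulas: C, H, then other elements
# alphabetically.
_HILL_ORDER = ("C", "H", "Cl", "N", "O", "S")


class ElementalComposition(Mapping[str, int]):
    """Immutable bag of atom counts over C, H, N, O, S (and Cl for ions).

    Construct from keyword counts or parse from a Hill-order formula
    string::

        ElementalComposition(C=6, H=12, O=6)
        ElementalComposition.from_formula("C6H12O6")

    Zero counts are dropped; at least one atom is required.
    """

    __slots__ = ("_counts", "_hash")

    def __init__(self, **counts: int) -> None:
        clean: dict[str, int] = {}
        for element, n in counts.items():
            if element not in SUPPORTED_ELEMENTS:
                raise ValueError(f"unknown element symbol: {element!r}")
            if not isinstance(n, (int,)) or isinstance(n, bool):
                raise TypeError(f"count for {element} must be an int, got {n!r}")
            if n < 0:
                raise ValueError(f"negative count for {element}: {n}")
            if n:
                clean[element] = n
        if not clean:
            raise ValueError("composition must contain at least one atom")
        # canonical storage order = Hill order
        self._counts = {e: clean[e] for e in _HILL_ORDER if e in clean}
        self._hash = hash(tuple(self._counts.items()))

    @classmethod
    def from_formula(cls, formula: str) -> "ElementalComposition":
        counts: dict[str, int] = {}
        pos = 0
        for match in _FORMULA_TOKEN.finditer(formula):
            if match.start() != pos:
                raise ValueError(f"cannot parse formula {formula!r}")
            if not match.group(0):
                break
            element, digits = match.groups()
            counts[element] = counts.get(element, 0) + (int(digits) if digits else 1)
            pos = match.end()
        if pos != len(formula) or not counts:
            raise ValueError(f"cannot parse formula {formula!r}")
        return cls(**counts)

    # Mapping protocol -----------------------------------------------------
    def __getitem__(self, element: str) -> int:
        return self._counts[element]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def get(self, element: str, default: int = 0) -> int:  # type: ignore[override]
        return self._counts.get(element, default)

    def __hash__(self) -> int:
        return self._hash

    def __eq__(self, other: object) -> bool:
        if isinstance(other, ElementalComposition):
            return self._counts == other._counts
        return NotImplemented

    def __repr__(self) -> str:
        return f"ElementalComposition({self.formula()!r})"

    # Arithmetic -----------------------------------------------------------
    def add(self, other: "ElementalComposition") -> "ElementalComposition":
        counts = dict(self._counts)
        for e, n in other.items():
            counts[e] = counts.get(e, 0) + n
        return ElementalComposition(**counts)

    def subtract(self, other: "ElementalComposition") -> "ElementalComposition":
        """Element-wise difference; raises if any count would go negative."""
        counts = dict(self._counts)
        for e, n in other.items():
            counts[e] = counts.get(e, 0) - n
            if counts[e] < 0:
                raise ValueError(
                    f"cannot remove {other.formula()} from {self.formula()}"
                )
        return ElementalComposition(**{e: n for e, n in counts.items() if n})

    def formula(self) -> str:
        """Hill-order formula string, e.g. ``C6H12O6``."""
        parts = []
        for e, n in self._counts.items():
            parts.append(e if n == 1 else f"{e}{n}")
        return "".join(parts)


class Adduct(enum.Enum):
    """Singly charged negative-mode ion species.

    Each member carries the mass delta (Da) applied to the neutral mass
    *before* the electron correction, and the atoms the neutral must
    possess for the ion to be chemically possible.
    """

    DEPROTONATED = ("[M-H]-", {"H": -1})
    DEPROTONATED_DEHYDRATED = ("[M-H-H2O]-", {"H": -3, "O": -1})
    CHLORIDE = ("[M+Cl]-", {"Cl": +1})

    def __init__(self, label: str, delta_atoms: dict[str, int]) -> None:
        self.label = label
        self.delta_atoms = delta_atoms
        self.mass_delta = sum(
            n * MONOISOTOPIC_MASS[e] for e, n in delta_atoms.items()
        )

    @classmethod
    def from_label(cls, label: str) -> "Adduct":
        for member in cls:
            if member.label == label or member.name.lower() == label.lower():
                return member
        raise ValueError(f"unknown adduct: {label!r}")

    def is_possible(self, neutral: ElementalComposition) -> bool:
        """Whether the neutral has the atoms this adduct removes."""
        for e, n in self.delta_atoms.items():
            if n < 0 and neutral.get(e) < -n:
                return False
        return True

    def apply(self, neutral: ElementalComposition) -> ElementalComposition:
        """Ion stoichiometry (without the charge-carrying electron)."""
        if not self.is_possible(neutral):
            raise ValueError(
                f"adduct {self.label} impossible for {neutral.formula()}: "
                "neutral lacks the atoms the adduct removes"
            )
        counts = {e: neutral.get(e) for e in neutral}
        for e, n in self.delta_atoms.items():
            counts[e] = counts.get(e, 0) + n
        return ElementalComposition(**{e: n for e, n in counts.items() if n})


def monoisotopic_mass(composition: ElementalComposition) -> float:
    """Neutral monoisotopic mass in Da: sum of count × atomic mass."""
    return sum(n * MONOISOTOPIC_MASS[e] for e, n in composition.items())


def ion_mz(
    composition: ElementalComposition,
    adduct: Adduct,
    *,
    include_electron: bool = True,
) -> float:
    """m/z of the singly charged anion of ``composition`` under ``adduct``.

    m/z = M + Δadduct + mₑ for charge −1. ``include_electron=False`` drops
    the electron-mass term (a documented toggle; the default reproduces
    printed ultra-high-resolution peak positions).

    Raises ``ValueError`` when the adduct is chemically impossible for the
    composition (e.g. dehydration of an oxygen-free neutral).
    """
    if not adduct.is_possible(composition):
        raise ValueError(
            f"adduct {adduct.label} impossible for {composition.formula()}: "
            "neutral lacks the atoms the adduct removes"
        )
    mz = monoisotopic_mass(composition) + adduct.mass_delta
    if include_electron:
        mz += ELECTRON_MASS
    return mz


def neutral_mass_from_mz(
    mz: float, adduct: Adduct, *, include_electron: bool = True
) -> float:
    """Invert :func:`ion_mz`: neutral monoisotopic mass implied by an
    observed anion m/z. Exact to machine precision by construction."""
    mass = mz - adduct.mass_delta
    if include_electron:
        mass -= ELECTRON_MASS
    return mass


def ppm_error(mz1: float, mz2: float) -> float:
    """Signed relative mass difference: (m/z₁ − m/z₂) / m/z₁ × 10⁶."""
    if mz1 <= 0:
        raise ValueError(f"reference m/z must be positive, got {mz1}")
    return (mz1 - mz2) / mz1 * 1e6


def chemical_class(composition: ElementalComposition) -> str:
    """Compound class from heteroatom content: CHO / CHNO / CHOS / CHNOS.

    Compositions lacking any of C, H or O fall outside the four classes
    and are labelled ``"unclassified"`` rather than dropped.
    """
    if not (composition.get("C") and composition.get("H") and composition.get("O")):
        return "unclassified"
    has_n = composition.get("N") > 0
    has_s = composition.get("S") > 0
    if has_n and has_s:
        return "CHNOS"
    if has_n:
        return "CHNO"
    if has_s:
        return "CHOS"
    return "CHO"


CHEMICAL_CLASSES = ("CHO", "CHNO", "CHOS", "CHNOS")


def van_krevelen(composition: ElementalComposition) -> tuple[float, float]:
    """(O/C, H/C) atomic ratios — the van Krevelen coordinates."""
    c = composition.get("C")
    if c == 0:
        raise ValueError("van Krevelen ratios undefined for zero carbon")
    return composition.get("O") / c, composition.get("H") / c


def rdbe(composition: ElementalComposition) -> float:
    """Rings plus double-bond equivalents: C − H/2 + N/2 + 1.

    O and S are divalent and do not enter. May be half-integer for
    radical-like stoichiometries; negative values flag impossible
    formulas.
    """
    return (
        composition.get("C")
        - composition.get("H") / 2
        + composition.get("N") / 2
        + 1
    )


def export_constants_table() -> str:
    """Plain-text dump of the frozen mass table (element<TAB>mass)."""
    lines = [f"{e}\t{m:.10f}" for e, m in MONOISOTOPIC_MASS.items()]
    lines.append(f"e-\t{ELECTRON_MASS:.12f}")
    return "\n".join(lines) + "\n"
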