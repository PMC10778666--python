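"""Monoisotopic mass constants.

Single source of truth for every m/z computed in the package. Values are
CODATA-2018 / IUPAC-2021 monoisotopic atomic masses of the principal
isotopes (1H, 12C, 14N, 16O, 32S, 35Cl), in unified atomic mass units (Da),
truncated only at the precision of the source tables. 12C defines the scale
and is exactly 12 by definition.
"""

from __future__ import annotations

from types import MappingProxyType

#: Monoisotopic atomic masses in Da (principal isotope of each element).
MONOISOTOPIC_MASS = MappingProxyType(
    {
        "H": 1.00782503207,
        "C": 12.0,
        "N": 14.0030740048,
        "O": 15.9949146196,
        "S": 31.9720707300,
        "Cl": 34.96885268,
    }
)

#: Electron rest mass in Da (CODATA). A singly charged anion carries one
#: extra electron; its m/z therefore exceeds the neutral-fragment mass sum
#: by this amount.
ELECTRON_MASS = 0.000548579909

#: Mass of a proton in Da, as removed by deprotonation: one H atom minus
#: one electron.
PROTON_MASS = MONOISOTOPIC_MASS["H"] - ELECTRON_MASS

SUPPORTED_ELEMENTS = tuple(MONOISOTOPIC_MASS)
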