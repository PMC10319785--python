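"""Adduct ion types and their fixed encodings.

Electrospray ionization most commonly yields protonated [M+H]+, sodiated
[M+Na]+ and deprotonated [M-H]- ions; these three are the supported adduct
set.  Each adduct carries a fixed one-hot code (appended to the pooled
graph representation before the dense head) and the monoisotopic mass
shift used to compute m/z from the neutral molecular mass.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import UnknownAdductError

# proton / sodium-minus-electron monoisotopic mass shifts in Da
_PROTON = 1.00728
_SODIUM = 22.98922


@dataclass(frozen=True)
class AdductType:
    label: str
    code: tuple[int, int, int]
    mass_shift: float
    charge: int

    @property
    def onehot(self) -> np.ndarray:
        return np.asarray(self.code, dtype=float)


M_PLUS_H = AdductType("[M+H]+", (1, 0, 0), +_PROTON, +1)
M_PLUS_NA = AdductType("[M+Na]+", (0, 1, 0), +_SODIUM, +1)
M_MINUS_H = AdductType("[M-H]-", (0, 0, 1), -_PROTON, -1)

SUPPORTED_ADDUCTS: dict[str, AdductType] = {
    a.label: a for a in (M_PLUS_H, M_PLUS_NA, M_MINUS_H)
}

# tolerated spelling variants seen in public CCS tables (unicode minus, spaces)
_ALIASES = {
    "[M+H]+": "[M+H]+",
    "[M + H]+": "[M+H]+",
    "[M+Na]+": "[M+Na]+",
    "[M + Na]+": "[M+Na]+",
    "[M-H]-": "[M-H]-",
    "[M−H]−": "[M-H]-",
    "[M−H]-": "[M-H]-",
    "[M-H]−": "[M-H]-",
}


def normalize_adduct(label: str) -> str | None:
    """Return the canonical label, or None if the adduct is unsupported."""
    return _ALIASES.get(label.strip())


def get_adduct(label: str) -> AdductType:
    canonical = normalize_adduct(label)
    if canonical is None:
        raise UnknownAdductError(f"unsupported adduct {label!r}; "
                                 f"supported: {sorted(SUPPORTED_ADDUCTS)}")
    return SUPPORTED_ADDUCTS[canonical]


def adduct_mz(neutral_mass: float, adduct: AdductType | str) -> float:
    """m/z of a singly charged adduct ion of a molecule of given neutral mass."""
    if isinstance(adduct, str):
        adduct = get_adduct(adduct)
    return neutral_mass + adduct.mass_shift
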