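"""Exact-mass and mass-defect arithmetic for fluorinated-compound screening.

Everything downstream — carbon-normalized mass-defect filtering, Kendrick
homologue detection, fragment matching, suspect screening — reduces to
monoisotopic-mass bookkeeping on small molecular formulas.  This module is
the single source of truth for atomic masses (IUPAC 2021 monoisotopic
values), isotope abundances, and the handful of derived quantities:

* mass defect, MD = m - round(m), wrapped to (-0.5, +0.5].  The nearest-
  integer convention matters: saturated hydrocarbons above ~C45 accumulate
  an MD beyond +0.5 Da, which under this convention wraps to negative
  values and lands near the perfluoroalkyl region of an MD plot — exactly
  the ambiguity the carbon-normalized m/C axis resolves.
* Kendrick mass defect for an arbitrary repeating unit (CF2, CF2O, CH2...):
  KM = m * nominal(RU)/exact(RU), KMD = round(KM) - KM.  Members of a
  homologous series share a KMD up to measurement error.
* adduct m/z for the three singly charged species used in suspect
  screening: [M-H]-, [M+H]+ (proton mass, electron-correct) and [M]+
  (electron loss).
* aggregated (nominal-mass) theoretical isotope patterns by per-element
  binomial/multinomial convolution — enough to predict the M+1 ratio that
  drives carbon-number estimation, not fine structure.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np

__all__ = [
    "ATOMIC_MASSES",
    "PROTON_MASS",
    "ELECTRON_MASS",
    "C13_C12_DELTA",
    "ElementCounts",
    "RepeatingUnit",
    "AdductSpec",
    "IsotopePattern",
    "ADDUCTS",
    "parse_formula",
    "format_formula",
    "monoisotopic_mass",
    "mass_defect",
    "kendrick_mass",
    "kendrick_mass_defect",
    "adduct_mz",
    "isotope_pattern",
    "CF2",
    "CF2O",
    "CH2",
]

# Monoisotopic masses of the most abundant isotope, IUPAC 2021 (Da).
ATOMIC_MASSES: Dict[str, float] = {
    "H": 1.007825032,
    "C": 12.000000000,
    "N": 14.003074004,
    "O": 15.994914620,
    "F": 18.998403163,
    "Na": 22.989769282,
    "P": 30.973761998,
    "S": 31.972071174,
    "Cl": 34.968852682,
    "K": 38.963706486,
    "Br": 78.918337601,
    "I": 126.904471853,
}

# Integer (nominal) masses of the same isotopes.
NOMINAL_MASSES: Dict[str, int] = {
    "H": 1, "C": 12, "N": 14, "O": 16, "F": 19, "Na": 23,
    "P": 31, "S": 32, "Cl": 35, "K": 39, "Br": 79, "I": 127,
}

# Isotope abundance distributions over nominal-mass offsets 0, +1, +2, ...
# relative to the most abundant isotope (IUPAC representative values).
ISOTOPE_ABUNDANCES: Dict[str, Tuple[float, ...]] = {
    "H": (0.999885, 0.000115),
    "C": (0.9893, 0.0107),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "F": (1.0,),
    "Na": (1.0,),
    "P": (1.0,),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
    "Cl": (0.7576, 0.0, 0.2424),
    "K": (0.932581, 0.000117, 0.067302),
    "Br": (0.5069, 0.0, 0.4931),
    "I": (1.0,),
}

PROTON_MASS = 1.007276467  # Da
ELECTRON_MASS = 0.000548580  # Da
C13_C12_DELTA = 1.0033548  # Da, spacing of the M+1 isotopologue trace

# Per-carbon M+1/M abundance factor conventionally used to estimate carbon
# numbers from the ratio of the M+1 to the monoisotopic trace.
M1_PER_CARBON = 0.011145


class FormulaError(ValueError):
    """Malformed or unsupported molecular formula."""


ElementCounts = Dict[str, int]

_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(text: str) -> ElementCounts:
    """Parse a Hill-style molecular formula like ``"C8HF15O2"``.

    No isotope labels, charges, or grouping parentheses; unknown element
    symbols raise :class:`FormulaError` naming the offending token.
    """
    if not isinstance(text, str) or not text.strip():
        raise FormulaError("empty formula")
    s = text.strip()
    counts: ElementCounts = {}
    pos = 0
    while pos < len(s):
        m = _TOKEN.match(s, pos)
        if not m or not m.group(1):
            raise FormulaError(f"cannot parse formula {text!r} at {s[pos:]!r}")
        sym, num = m.group(1), m.group(2)
        if sym not in ATOMIC_MASSES:
            raise FormulaError(f"unknown element {sym!r} in formula {text!r}")
        counts[sym] = counts.get(sym, 0) + (int(num) if num else 1)
        pos = m.end()
    if not counts or all(v == 0 for v in counts.values()):
        raise FormulaError(f"formula {text!r} has no atoms")
    return counts


def format_formula(counts: ElementCounts) -> str:
    """Hill-order string (C, H, then alphabetical) for an element-count map."""
    parts = []
    keys = list(counts)
    order = [k for k in ("C", "H") if k in keys and counts[k] > 0]
    order += sorted(k for k in keys if k not in ("C", "H") and counts[k] > 0)
    for k in order:
        n = counts[k]
        parts.append(k if n == 1 else f"{k}{n}")
    return "".join(parts)


def monoisotopic_mass(f: ElementCounts | str) -> float:
    """Monoisotopic (most-abundant-isotope) mass of a formula, in Da."""
    if isinstance(f, str):
        f = parse_formula(f)
    try:
        return float(sum(ATOMIC_MASSES[el] * n for el, n in f.items()))
    except KeyError as e:  # pragma: no cover - guarded by parse_formula
        raise FormulaError(f"unknown element {e.args[0]!r}") from None


def nominal_mass(f: ElementCounts | str) -> int:
    """Integer nominal mass (sum of most-abundant-isotope nucleon counts)."""
    if isinstance(f, str):
        f = parse_formula(f)
    return int(sum(NOMINAL_MASSES[el] * n for el, n in f.items()))


def combine(a: ElementCounts, b: ElementCounts, sign: int = 1) -> ElementCounts:
    """Element-wise a + sign*b; raises FormulaError if any count goes negative."""
    out = dict(a)
    for el, n in b.items():
        out[el] = out.get(el, 0) + sign * n
        if out[el] < 0:
            raise FormulaError(
                f"subtraction yields negative {el} count "
                f"({format_formula(a)} - {format_formula(b)})"
            )
    return {el: n for el, n in out.items() if n > 0}


def mass_defect(m: float) -> float:
    """Mass defect under the nearest-integer convention, in (-0.5, +0.5].

    MD = m - round(m).  High-carbon hydrocarbons whose conventional MD
    exceeds +0.5 Da wrap to negative values here; the m/C axis is what
    separates them from genuinely fluorine-dominated species.
    """
    if m <= 0:
        raise ValueError("mass must be positive")
    md = m - np.floor(m + 0.5)
    # np.floor(m + .5) rounds half up, giving the (-0.5, +0.5] window
    return float(md)


@dataclass(frozen=True)
class RepeatingUnit:
    """A homologue repeating unit, e.g. CF2 (49.99681 Da, nominal 50)."""

    formula: "ElementCounts"
    exact_mass: float = field(default=0.0)
    nominal_mass: int = field(default=0)
    label: str = ""

    def __post_init__(self):
        if not self.exact_mass:
            object.__setattr__(self, "exact_mass", monoisotopic_mass(self.formula))
        if not self.nominal_mass:
            object.__setattr__(self, "nominal_mass", nominal_mass(self.formula))
        if not self.label:
            object.__setattr__(self, "label", format_formula(self.formula))

    @classmethod
    def from_formula(cls, text: str) -> "RepeatingUnit":
        return cls(formula=parse_formula(text))


CF2 = RepeatingUnit.from_formula("CF2")
CF2O = RepeatingUnit.from_formula("CF2O")
CH2 = RepeatingUnit.from_formula("CH2")


def kendrick_mass(m: float, ru: RepeatingUnit) -> float:
    """Kendrick mass: m rescaled so the repeating unit is integer-valued."""
    if m <= 0:
        raise ValueError("mass must be positive")
    return m * ru.nominal_mass / ru.exact_mass


def kendrick_mass_defect(m: float, ru: RepeatingUnit) -> float:
    """KMD = round(KM) - KM; equal within a homologous series of `ru`.

    Sign convention: CH2-type series get small positive KMD.  Grouping
    logic depends only on within-series equality, not on the sign.
    """
    km = kendrick_mass(m, ru)
    return float(np.floor(km + 0.5) - km)


@dataclass(frozen=True)
class AdductSpec:
    """A singly charged ionization adduct: label, mass delta, charge sign."""

    label: str
    mass_delta: float
    charge: int  # +1 or -1


ADDUCTS: Dict[str, AdductSpec] = {
    "[M-H]-": AdductSpec("[M-H]-", -PROTON_MASS, -1),
    "[M+H]+": AdductSpec("[M+H]+", +PROTON_MASS, +1),
    "[M]+": AdductSpec("[M]+", -ELECTRON_MASS, +1),
}

# tolerate unicode minus signs in user-supplied labels
_ADDUCT_ALIASES = {
    "[M−H]−": "[M-H]-", "[M-H]−": "[M-H]-", "[M−H]-": "[M-H]-",
    "[M+H]⁺": "[M+H]+", "[M]⁺": "[M]+",
}


def get_adduct(label: str | AdductSpec) -> AdductSpec:
    if isinstance(label, AdductSpec):
        return label
    key = _ADDUCT_ALIASES.get(label, label)
    try:
        return ADDUCTS[key]
    except KeyError:
        raise ValueError(
            f"unknown adduct {label!r}; supported: {sorted(ADDUCTS)}"
        ) from None


def adduct_mz(neutral_mass: float, adduct: str | AdductSpec) -> float:
    """m/z of a singly charged adduct of a neutral monoisotopic mass."""
    if neutral_mass <= 0:
        raise ValueError("neutral mass must be positive")
    return neutral_mass + get_adduct(adduct).mass_delta


IsotopePattern = List[Tuple[float, float]]


def _element_envelope(el: str, n: int, n_peaks: int) -> np.ndarray:
    """Abundance envelope over nominal offsets for n atoms of one element.

    Exponentiation by squaring of the single-atom distribution; arrays are
    truncated to n_peaks offsets at each step (trailing mass loss is
    irrelevant at the M+2/M+3 level used here).
    """
    base = np.asarray(ISOTOPE_ABUNDANCES[el], dtype=float)
    result = np.array([1.0])
    power = base
    k = n
    while k:
        if k & 1:
            result = np.convolve(result, power)[:n_peaks]
        k >>= 1
        if k:
            power = np.convolve(power, power)[:n_peaks]
    return result


def isotope_pattern(f: ElementCounts | str, n_peaks: int = 3) -> IsotopePattern:
    """Aggregated nominal-mass isotopologue envelope of a formula.

    Returns up to ``n_peaks`` (m/z, relative abundance) pairs; the base
    peak has abundance 1 and peak k sits at monoisotopic mass + k x
    1.0033548 Da (the 13C spacing; an adequate stand-in for the aggregated
    isotopologue centroid at small k).  Peaks with relative abundance
    below 1e-9 are dropped.
    """
    if isinstance(f, str):
        f = parse_formula(f)
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    env = np.array([1.0])
    for el, n in f.items():
        if n > 0:
            env = np.convolve(env, _element_envelope(el, n, n_peaks))[:n_peaks]
    env = env / env.max()
    m0 = monoisotopic_mass(f)
    out = [
        (m0 + k * C13_C12_DELTA, float(a))
        for k, a in enumerate(env)
        if a > 1e-9
    ]
    return out
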