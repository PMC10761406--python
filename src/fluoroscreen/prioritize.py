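"""PFAS evidence engine.

Four independent evidence channels are computed per feature and
accumulated as flags rather than hard deletions (the audit trail matters
when cutoffs are tuned iteratively):

1. carbon-normalized mass-defect position (MD/C vs m/C) and the
   associated two-sided cutoff filter.  Fluorine-dominated molecules sit
   at high mass-per-carbon (m/C ~ 40-55) with MD/C near or below zero;
   hydrocarbon matrix sits near m/C ~ 14 with clearly positive MD/C.
2. Kendrick mass-defect homologous-series membership for a repeating
   unit such as CF2 or CF2O.
3. MS2 evidence: diagnostic-fragment matches, fragment mass-difference
   matches (all pairwise gaps within a spectrum), and formula
   propagation from annotated fragments across listed mass differences.
4. adduct-aware suspect screening by accurate mass.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from . import chem
from .chem import (
    ElementCounts,
    RepeatingUnit,
    adduct_mz,
    combine,
    format_formula,
    get_adduct,
    mass_defect,
    monoisotopic_mass,
    parse_formula,
)
from .features import Feature
from .msio import Spectrum

__all__ = [
    "HomologousSeries",
    "DiagnosticFragment",
    "MassDifference",
    "SuspectEntry",
    "MS2Annotation",
    "compute_mdc_mc",
    "filter_mdc_mc",
    "detect_homologous_series",
    "match_diagnostic_fragments",
    "match_fragment_differences",
    "propagate_formulas",
    "suspect_screen",
    "builtin_diagnostic_fragments",
    "builtin_mass_differences",
    "read_suspect_csv",
    "read_fragment_csv",
    "read_difference_csv",
]


# ---------------------------------------------------------------------------
# evidence channel 1: MD/C - m/C

def compute_mdc_mc(features: Sequence[Feature]) -> Sequence[Feature]:
    """Populate md, mdc (= MD / carbon) and m_over_c (= m/z / carbon).

    Features without a carbon estimate keep empty columns and a
    ``no_carbon_estimate`` flag; they cannot participate in the
    carbon-normalized filter.
    """
    for f in features:
        f.md = mass_defect(f.mz)
        if f.carbon_est and f.carbon_est > 0:
            f.mdc = f.md / f.carbon_est
            f.m_over_c = f.mz / f.carbon_est
        else:
            f.mdc = None
            f.m_over_c = None
            f.flags.add("no_carbon_estimate")
    return features


def filter_mdc_mc(
    features: Sequence[Feature],
    mc_min: Optional[float] = 30.0,
    mdc_max: Optional[float] = 0.003,
) -> List[Feature]:
    """Keep features with m/C above ``mc_min`` and MD/C below ``mdc_max``.

    Either cutoff may be None (disabled).  Non-passing features are
    flagged, not deleted; the returned list is the passing subset.
    """
    passed: List[Feature] = []
    for f in features:
        ok = f.m_over_c is not None
        if ok and mc_min is not None:
            ok = f.m_over_c > mc_min
        if ok and mdc_max is not None:
            ok = f.mdc < mdc_max
        if ok:
            f.flags.add("mdc_mc_pass")
            passed.append(f)
        else:
            f.flags.discard("mdc_mc_pass")
    return passed


# ---------------------------------------------------------------------------
# evidence channel 2: KMD homologous series

@dataclass
class HomologousSeries:
    """Features sharing a Kendrick mass defect for one repeating unit."""

    hs_id: int
    repeating_unit: RepeatingUnit
    member_feature_indices: List[int]
    kmd_centroid: float


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def detect_homologous_series(
    features: Sequence[Feature],
    ru: RepeatingUnit = chem.CF2,
    mass_tol: float = 0.002,
    min_members: int = 3,
    first_hs_id: int = 1,
) -> List[HomologousSeries]:
    """Group features into homologous series of a repeating unit.

    Two features are linked when their m/z difference is within
    ``mass_tol`` of a nonzero integer multiple of the unit's exact mass;
    connected components with at least ``min_members`` members become
    series (so a chain A-B-C qualifies even if A and C were only linked
    through B — bridging features can merge series).  Retention time is
    deliberately not used; RT-shift verification is a downstream visual
    check.  Membership is also recorded on each feature's ``hs_ids``.
    """
    n = len(features)
    mzs = np.array([f.mz for f in features])
    order = np.argsort(mzs)
    uf = _UnionFind(n)
    for a in range(n):
        i = order[a]
        for b in range(a + 1, n):
            j = order[b]
            diff = mzs[j] - mzs[i]
            k = round(diff / ru.exact_mass)
            if k < 1:
                continue
            if abs(diff - k * ru.exact_mass) <= mass_tol:
                uf.union(i, j)
    groups: Dict[int, List[int]] = {}
    for i in range(n):
        groups.setdefault(uf.find(i), []).append(i)
    series: List[HomologousSeries] = []
    hs_id = first_hs_id
    for root in sorted(groups):
        members = sorted(groups[root], key=lambda i: mzs[i])
        if len(members) < min_members:
            continue
        kmds = [chem.kendrick_mass_defect(mzs[i], ru) for i in members]
        series.append(
            HomologousSeries(
                hs_id=hs_id,
                repeating_unit=ru,
                member_feature_indices=members,
                kmd_centroid=float(np.mean(kmds)),
            )
        )
        for i in members:
            features[i].hs_ids.append(hs_id)
        hs_id += 1
    return series


# ---------------------------------------------------------------------------
# evidence channel 3: MS2 fragments

@dataclass(frozen=True)
class DiagnosticFragment:
    """A literature diagnostic fragment ion: label, optional formula, m/z."""

    label: str
    mz: float
    polarity: str  # "negative" | "positive"
    formula: Optional[ElementCounts] = None


@dataclass(frozen=True)
class MassDifference:
    """A characteristic fragment mass gap (e.g. CF2, HF)."""

    label: str
    formula: ElementCounts
    delta: float

    @classmethod
    def from_formula(cls, text: str, label: Optional[str] = None) -> "MassDifference":
        f = parse_formula(text)
        return cls(label=label or format_formula(f), formula=f,
                   delta=monoisotopic_mass(f))


@dataclass
class MS2Annotation:
    """Annotation of one MS2 peak, from the fragment list or propagated."""

    fragment_mz: float
    label: str
    formula: Optional[ElementCounts]
    source: str  # "df_list" | "propagated"
    partner_mz: Optional[float] = None


def _fragment_anion_mz(formula: str) -> float:
    """m/z of the [X]- anion of a fragment composition X (add one electron)."""
    return monoisotopic_mass(formula) + chem.ELECTRON_MASS


def _fragment_cation_mz(formula: str) -> float:
    return monoisotopic_mass(formula) - chem.ELECTRON_MASS


def builtin_diagnostic_fragments(polarity: str = "negative") -> List[DiagnosticFragment]:
    """A starter list of well-known PFAS diagnostic fragments.

    Negative mode: the perfluoroalkyl anion series CnF(2n+1)- for n=1..10,
    common oxygen/sulfur/phosphorus head-group ions, and a few
    fluorotelomer markers.  Positive mode: CnF(2n-1)+ fluorocarbon ions.
    All masses are computed from formulas, never hard-coded.
    """
    frags: List[DiagnosticFragment] = []
    if polarity == "negative":
        for n in range(1, 11):
            f = f"C{n}F{2 * n + 1}"
            frags.append(DiagnosticFragment(
                label=f"{format_formula(parse_formula(f))}-",
                mz=_fragment_anion_mz(f), polarity="negative",
                formula=parse_formula(f)))
        for f in ["F", "SO3", "FSO3", "PO3", "PO2F2", "C2F5O",
                  "C3F7O", "CF3SO3", "C2F3O2", "C3F5O2", "C2HF2O2",
                  "C2H4FSO3", "CHF2", "C2F4H"]:
            frags.append(DiagnosticFragment(
                label=f"{format_formula(parse_formula(f))}-",
                mz=_fragment_anion_mz(f), polarity="negative",
                formula=parse_formula(f)))
    elif polarity == "positive":
        for n in range(1, 9):
            f = f"C{n}F{2 * n - 1}"
            frags.append(DiagnosticFragment(
                label=f"{format_formula(parse_formula(f))}+",
                mz=_fragment_cation_mz(f), polarity="positive",
                formula=parse_formula(f)))
        for f in ["CHF2", "C2H2F3", "C3H2F5", "C5H2F9"]:
            frags.append(DiagnosticFragment(
                label=f"{format_formula(parse_formula(f))}+",
                mz=_fragment_cation_mz(f), polarity="positive",
                formula=parse_formula(f)))
    else:
        raise ValueError(f"unknown polarity {polarity!r}")
    return frags


def builtin_mass_differences() -> List[MassDifference]:
    """Characteristic PFAS fragment mass differences (masses computed)."""
    out = [MassDifference.from_formula(t) for t in
           ["CF2", "C2F4", "HF", "CF2O", "C2F4O", "C10H3F17"]]
    hf_co2 = combine(parse_formula("HF"), parse_formula("CO2"))
    out.append(MassDifference(label="HF+CO2", formula=hf_co2,
                              delta=monoisotopic_mass(hf_co2)))
    return out


def match_diagnostic_fragments(
    spec: Spectrum,
    dfs: Sequence[DiagnosticFragment],
    tol: float = 0.002,
    noise: float = 2000.0,
    min_hits: int = 1,
) -> Tuple[List[Tuple[float, DiagnosticFragment]], bool]:
    """Match MS2 peaks above the noise threshold against a fragment list.

    Returns (hits, flagged): hits are (peak m/z, fragment) pairs; the
    spectrum is flagged when the hit count reaches ``min_hits``.  The
    fragment list must match the spectrum polarity.
    """
    pols = {d.polarity for d in dfs}
    if pols and pols != {spec.polarity}:
        raise ValueError(
            f"fragment-list polarity {sorted(pols)} does not match "
            f"spectrum polarity {spec.polarity!r}"
        )
    mask = spec.intensity >= noise
    peaks = spec.mz[mask]
    hits: List[Tuple[float, DiagnosticFragment]] = []
    if peaks.size:
        df_mz = np.array([d.mz for d in dfs])
        for p in peaks:
            for j in np.flatnonzero(np.abs(df_mz - p) <= tol):
                hits.append((float(p), dfs[j]))
    return hits, len(hits) >= min_hits


def match_fragment_differences(
    spec: Spectrum,
    diffs: Sequence[MassDifference],
    tol: float = 0.002,
    noise: float = 2000.0,
) -> List[Tuple[float, float, MassDifference]]:
    """Match all pairwise fragment gaps against listed mass differences.

    All C(n,2) gaps among peaks above the noise threshold are formed by
    broadcasting; returns (lower peak, upper peak, difference) triples.
    """
    peaks = spec.mz[spec.intensity >= noise]
    out: List[Tuple[float, float, MassDifference]] = []
    if peaks.size < 2:
        return out
    gaps = peaks[None, :] - peaks[:, None]  # gaps[i, j] = p_j - p_i
    iu, ju = np.triu_indices(peaks.size, k=1)
    gap_vals = gaps[iu, ju]
    for d in diffs:
        for k in np.flatnonzero(np.abs(gap_vals - d.delta) <= tol):
            out.append((float(peaks[iu[k]]), float(peaks[ju[k]]), d))
    out.sort(key=lambda t: (t[0], t[1], t[2].label))
    return out


def propagate_formulas(
    spec: Spectrum,
    annotations: Sequence[MS2Annotation],
    diffs: Sequence[MassDifference],
    tol: float = 0.002,
    noise: float = 2000.0,
) -> List[MS2Annotation]:
    """Extend fragment annotations across listed mass differences.

    An unannotated peak lying at (annotated m/z +- delta) within ``tol``
    inherits the annotated formula with the difference composition added
    or subtracted element-wise; subtractions that would need a negative
    element count are rejected.  Iterates to a fixed point (bounded by
    the number of peaks).  Propagated annotations carry
    ``source='propagated'`` and the partner peak's m/z.
    """
    peaks = spec.mz[spec.intensity >= noise]
    anns: List[MS2Annotation] = list(annotations)
    annotated_mz = {round(a.fragment_mz, 6) for a in anns}
    frontier = [a for a in anns if a.formula]
    for _ in range(len(peaks) + 1):
        new: List[MS2Annotation] = []
        for a in frontier:
            if not a.formula:
                continue
            for d in diffs:
                for sign in (+1, -1):
                    target = a.fragment_mz + sign * d.delta
                    for p in peaks[np.abs(peaks - target) <= tol]:
                        key = round(float(p), 6)
                        if key in annotated_mz:
                            continue
                        try:
                            f = combine(a.formula, d.formula, sign)
                        except chem.FormulaError:
                            continue
                        if not f:
                            continue
                        new.append(MS2Annotation(
                            fragment_mz=float(p),
                            label=format_formula(f),
                            formula=f,
                            source="propagated",
                            partner_mz=a.fragment_mz,
                        ))
                        annotated_mz.add(key)
        if not new:
            break
        anns.extend(new)
        frontier = new
    return anns


# ---------------------------------------------------------------------------
# evidence channel 4: suspect screening

@dataclass
class SuspectEntry:
    """One suspect-list compound (neutral species)."""

    name: str
    formula: Optional[ElementCounts]
    exact_mass: float
    smiles: str = ""


@dataclass(frozen=True)
class SuspectHit:
    feature_index: int
    suspect: SuspectEntry
    adduct_label: str
    error_mda: float


def suspect_screen(
    features: Sequence[Feature],
    suspects: Sequence[SuspectEntry],
    adducts: Iterable[str] = ("[M-H]-",),
    tol: float = 0.004,
    polarity: Optional[str] = None,
) -> List[SuspectHit]:
    """Accurate-mass suspect screening for the chosen adducts.

    Every (feature, suspect, adduct) match within ``tol`` Da is reported;
    a feature may hit several suspects and vice versa.  Matched features
    get the ``suspect_hit`` flag and suspect names in ``extras``.
    """
    specs = [get_adduct(a) for a in adducts]
    if polarity is not None:
        want = -1 if polarity == "negative" else +1
        bad = [a.label for a in specs if a.charge != want]
        if bad:
            raise ValueError(
                f"adducts {bad} are inconsistent with {polarity} polarity"
            )
    mzs = np.array([f.mz for f in features])
    hits: List[SuspectHit] = []
    for s in suspects:
        for a in specs:
            target = adduct_mz(s.exact_mass, a)
            for i in np.flatnonzero(np.abs(mzs - target) <= tol):
                hits.append(SuspectHit(
                    feature_index=int(i), suspect=s, adduct_label=a.label,
                    error_mda=float((mzs[i] - target) * 1000.0),
                ))
                features[i].flags.add("suspect_hit")
                names = features[i].extras.setdefault("suspect_names", [])
                if s.name not in names:
                    names.append(s.name)
    return hits


# ---------------------------------------------------------------------------
# list file I/O

def read_suspect_csv(path: str | Path) -> List[SuspectEntry]:
    """Read a suspect list CSV: name, smiles, formula, exact_mass.

    The exact mass is recomputed from the formula on load; a mismatch
    above 1 mDa triggers a warning (corrupt-list guard), and the stated
    exact_mass is kept.
    """
    df = pd.read_csv(path)
    required = {"name", "formula", "exact_mass"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"suspect list missing column(s): {sorted(missing)}")
    out: List[SuspectEntry] = []
    for i, rec in df.iterrows():
        formula = None
        if isinstance(rec["formula"], str) and rec["formula"].strip():
            formula = parse_formula(rec["formula"])
        exact = float(rec["exact_mass"])
        if formula is not None:
            calc = monoisotopic_mass(formula)
            if abs(calc - exact) > 0.001:
                warnings.warn(
                    f"suspect {rec['name']!r}: stated exact mass {exact:.5f} "
                    f"deviates from formula mass {calc:.5f} by "
                    f"{abs(calc - exact) * 1000:.2f} mDa", stacklevel=2)
        out.append(SuspectEntry(
            name=str(rec["name"]), formula=formula, exact_mass=exact,
            smiles=str(rec.get("smiles", "") or ""),
        ))
    return out


def read_fragment_csv(path: str | Path) -> List[DiagnosticFragment]:
    """Read a diagnostic-fragment list CSV: label, formula_or_mz, polarity.

    ``formula_or_mz`` is either a molecular formula (ion m/z computed,
    electron-corrected for the stated polarity) or a numeric m/z.
    """
    df = pd.read_csv(path)
    required = {"label", "formula_or_mz", "polarity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fragment list missing column(s): {sorted(missing)}")
    out: List[DiagnosticFragment] = []
    for _, rec in df.iterrows():
        raw = str(rec["formula_or_mz"]).strip()
        pol = str(rec["polarity"]).strip().lower()
        if pol not in ("negative", "positive"):
            raise ValueError(f"fragment polarity must be negative/positive, got {pol!r}")
        try:
            mz = float(raw)
            formula = None
        except ValueError:
            formula = parse_formula(raw)
            mz = (_fragment_anion_mz(raw) if pol == "negative"
                  else _fragment_cation_mz(raw))
        out.append(DiagnosticFragment(
            label=str(rec["label"]), mz=mz, polarity=pol, formula=formula))
    return out


def read_difference_csv(path: str | Path) -> List[MassDifference]:
    """Read a mass-difference list CSV: label, formula."""
    df = pd.read_csv(path)
    missing = {"label", "formula"} - set(df.columns)
    if missing:
        raise ValueError(f"difference list missing column(s): {sorted(missing)}")
    return [
        MassDifference.from_formula(str(rec["formula"]), label=str(rec["label"]))
        for _, rec in df.iterrows()
    ]
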