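"""Extracted ion chromatograms and coelution-correlation grouping.

In-source fragments and adducts of one compound share its exact elution
profile, so the squared Pearson correlation of their EICs over a narrow
retention-time window around the apex is ~1 regardless of their relative
abundances.  Correlating a seed feature's EIC against every coeluting
feature therefore groups an ion family (e.g. [M-H]-, [M-HF-H]-, [M+Cl]-,
[M+Ac]-) without knowing any mass difference in advance.

Extraction width convention: ``width`` is the half-window, i.e. centroids
within mz +- width are summed (a "5 mDa" extraction covers a 10 mDa span).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from . import chem
from .features import Feature
from .msio import Run

__all__ = [
    "EIC",
    "CorrelationGroup",
    "extract_eic",
    "extract_series_eics",
    "correlate_coeluting",
    "label_mass_delta",
]


@dataclass
class EIC:
    """Intensity vs retention time at a fixed m/z window."""

    rt: np.ndarray  # minutes, the run's MS1 scan grid in range
    intensity: np.ndarray
    target_mz: float
    width: float  # half-window, Da

    @property
    def apex_rt(self) -> float:
        return float(self.rt[int(np.argmax(self.intensity))])

    @property
    def apex_intensity(self) -> float:
        return float(self.intensity.max(initial=0.0))


@dataclass
class CorrelationGroup:
    """Features whose EICs coelute with a seed above an r^2 threshold."""

    seed_mz: float
    members: List[Tuple[float, float, float]]  # (mz, r_squared, delta_to_seed)
    rt_window: float  # seconds
    r2_threshold: float


def extract_eic(
    run: Run,
    mz: float,
    width: float = 0.005,
    rt_range: Optional[Tuple[float, float]] = None,
) -> EIC:
    """Extract an ion chromatogram: per MS1 scan, the summed intensity of
    centroids within mz +- width; zero where none fall in the window."""
    if width <= 0:
        raise ValueError("extraction width must be positive")
    ms1 = run.ms1()
    if rt_range is not None:
        lo, hi = rt_range
        if hi < lo:
            raise ValueError("empty RT range")
        ms1 = [s for s in ms1 if lo <= s.rt <= hi]
        if not ms1:
            raise ValueError(f"no MS1 scans in RT range {rt_range}")
    rts = np.array([s.rt for s in ms1])
    inten = np.zeros(len(ms1))
    for i, s in enumerate(ms1):
        a = np.searchsorted(s.mz, mz - width)
        b = np.searchsorted(s.mz, mz + width)
        if b > a:
            inten[i] = s.intensity[a:b].sum()
    return EIC(rt=rts, intensity=inten, target_mz=mz, width=width)


def extract_series_eics(
    run: Run,
    base_mz: float,
    ru: chem.RepeatingUnit = chem.CF2,
    n: int = 3,
    width: float = 0.005,
    rt_range: Optional[Tuple[float, float]] = None,
) -> List[EIC]:
    """EICs at base_mz + k x unit mass for k = 0..n-1 (homologue ladder
    extrapolation, used to verify RT shifts of a suspected series)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return [
        extract_eic(run, base_mz + k * ru.exact_mass, width, rt_range)
        for k in range(n)
    ]


def _r_squared(a: np.ndarray, b: np.ndarray) -> Optional[float]:
    """Squared Pearson correlation; None when undefined (fewer than 5
    jointly nonzero grid points, or zero variance)."""
    nonzero = (a > 0) | (b > 0)
    if nonzero.sum() < 5:
        return None
    if a.std() == 0 or b.std() == 0:
        return None
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def correlate_coeluting(
    run: Run,
    features: Sequence[Feature],
    seed_mz: float,
    rt_window: float = 25.0,
    r2_threshold: float = 0.95,
    width: float = 0.005,
) -> CorrelationGroup:
    """Group features whose EICs correlate with a seed feature's EIC.

    The seed must exist among ``features`` within 2 mDa of ``seed_mz``.
    Every feature with apex RT within ``rt_window`` seconds of the seed
    apex is correlated on the shared MS1 scan grid over seed apex +-
    window; members with r^2 >= threshold are kept, each with its mass
    difference to the seed.
    """
    mzs = np.array([f.mz for f in features])
    if mzs.size == 0:
        raise ValueError("no features supplied")
    d = np.abs(mzs - seed_mz)
    si = int(np.argmin(d))
    if d[si] > 0.002:
        raise ValueError(
            f"no feature within 2 mDa of m/z {seed_mz}; nearest is "
            f"{mzs[si]:.5f} ({d[si] * 1000:.1f} mDa away)"
        )
    seed = features[si]
    win_min = rt_window / 60.0
    rt_range = (seed.rt - win_min, seed.rt + win_min)
    seed_eic = extract_eic(run, seed.mz, width, rt_range)
    members: List[Tuple[float, float, float]] = []
    for f in features:
        if abs(f.rt - seed.rt) > win_min:
            continue
        if f is seed:
            members.append((f.mz, 1.0, 0.0))
            continue
        eic = extract_eic(run, f.mz, width, rt_range)
        r2 = _r_squared(seed_eic.intensity, eic.intensity)
        if r2 is not None and r2 >= r2_threshold:
            members.append((f.mz, r2, f.mz - seed.mz))
    members.sort(key=lambda t: t[0])
    return CorrelationGroup(
        seed_mz=seed.mz, members=members,
        rt_window=rt_window, r2_threshold=r2_threshold,
    )


# small adduct/loss lookup for labelling mass deltas within a group
_DELTA_LABELS: List[Tuple[str, float]] = [
    ("-HF", -chem.monoisotopic_mass("HF")),
    ("+HF", +chem.monoisotopic_mass("HF")),
    ("-CO2", -chem.monoisotopic_mass("CO2")),
    ("-HF-CO2", -chem.monoisotopic_mass("HF") - chem.monoisotopic_mass("CO2")),
    ("+Cl-H", chem.ATOMIC_MASSES["Cl"] - chem.ATOMIC_MASSES["H"]),
    ("+Br-H", chem.ATOMIC_MASSES["Br"] - chem.ATOMIC_MASSES["H"]),
    ("+Ac-H", chem.monoisotopic_mass("C2H4O2") - chem.ATOMIC_MASSES["H"]),
    ("+CF2", chem.CF2.exact_mass),
    ("-CF2", -chem.CF2.exact_mass),
]


def label_mass_delta(delta: float, tol: float = 0.003) -> Optional[str]:
    """Suggest an adduct/loss label for a mass difference to the seed."""
    for label, d in _DELTA_LABELS:
        if abs(delta - d) <= tol:
            return label
    return None
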