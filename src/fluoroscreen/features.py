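"""MS1 feature detection, carbon-number estimation, MS2 alignment, blank correction.

The feature finder is a transparent greedy EIC tracer, not a port of any
existing metabolomics feature finder: feature finding is treated as a
swappable front end (external feature tables are accepted by the
pipeline), so the constraints are what matter — mass error in ppm, an MS1
intensity threshold, a chromatographic FWHM window, and at least two
coeluting isotopologue traces with a plausible M+1/M ratio.

Carbon numbers come from the M+1 isotopologue abundance: with a natural
13C fraction of ~1.1% per carbon, C ~= (I_M+1 / I_M) / 0.011145.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .chem import C13_C12_DELTA, M1_PER_CARBON
from .msio import ExternalFeatureRow, Run, Spectrum

__all__ = [
    "Feature",
    "FeatureFinderParams",
    "detect_features",
    "features_from_table",
    "estimate_carbon",
    "align_ms2",
    "blank_correct",
]


@dataclass
class Feature:
    """One MS1 chromatographic feature and its accumulated evidence."""

    mz: float  # intensity-weighted apex m/z of the monoisotopic trace
    rt: float  # apex retention time, minutes
    area: float  # trapezoidal EIC area, counts x min
    intensity_M: float  # apex intensity of the monoisotopic trace
    intensity_M1: float = 0.0  # apex intensity of the M+1 trace
    fwhm: float = float("nan")  # seconds
    n_isotope_traces: int = 1
    carbon_est: Optional[float] = None
    md: Optional[float] = None
    mdc: Optional[float] = None
    m_over_c: Optional[float] = None
    hs_ids: List[int] = field(default_factory=list)
    ms2_index: Optional[int] = None  # index into Run.spectra
    flags: Set[str] = field(default_factory=set)
    extras: Dict[str, object] = field(default_factory=dict)


@dataclass
class FeatureFinderParams:
    """Constraints for the greedy EIC tracer (defaults follow common
    QTOF screening practice: 10 ppm, 2000 counts, FWHM 1 s - 1 min,
    two isotopologue traces)."""

    mass_error_ppm: float = 10.0
    intensity_threshold: float = 2000.0
    min_fwhm: float = 1.0  # seconds
    max_fwhm: float = 1.0  # minutes
    min_isotope_traces: int = 2
    isotope_ratio_rel_tol: float = 0.5  # M+1/M within +-50% of expectation

    def __post_init__(self):
        if self.min_fwhm <= 0 or self.max_fwhm <= 0:
            raise ValueError("FWHM bounds must be positive")
        if self.min_fwhm >= self.max_fwhm * 60.0:
            raise ValueError("min_fwhm (s) must be below max_fwhm (min)")


def _interp_crossing(t0, y0, t1, y1, level):
    """RT where a linear segment crosses `level` (y0, y1 straddle it)."""
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def _fwhm_minutes(rts: np.ndarray, ints: np.ndarray, apex: int) -> float:
    """FWHM by linear interpolation; NaN if the trace never falls below
    half max on either side of the apex."""
    half = ints[apex] / 2.0
    left = right = None
    for i in range(apex, 0, -1):
        if ints[i - 1] < half <= ints[i]:
            left = _interp_crossing(rts[i - 1], ints[i - 1], rts[i], ints[i], half)
            break
    for i in range(apex, len(ints) - 1):
        if ints[i + 1] < half <= ints[i]:
            right = _interp_crossing(rts[i], ints[i], rts[i + 1], ints[i + 1], half)
            break
    if left is None or right is None:
        return float("nan")
    return right - left


class _ScanIndex:
    """Sorted per-scan centroid arrays with a claimed mask."""

    def __init__(self, ms1: Sequence[Spectrum]):
        self.rts = np.array([s.rt for s in ms1])
        self.mz = [s.mz for s in ms1]
        self.inten = [s.intensity for s in ms1]
        self.claimed = [np.zeros(s.mz.size, dtype=bool) for s in ms1]

    def nearest_unclaimed(self, scan: int, mz: float, tol: float) -> Optional[int]:
        arr = self.mz[scan]
        if arr.size == 0:
            return None
        lo = np.searchsorted(arr, mz - tol)
        hi = np.searchsorted(arr, mz + tol)
        best, best_d = None, tol
        for j in range(lo, hi):
            if self.claimed[scan][j]:
                continue
            d = abs(arr[j] - mz)
            if d <= best_d:
                best, best_d = j, d
        return best


def detect_features(run: Run, p: Optional[FeatureFinderParams] = None) -> List[Feature]:
    """Detect MS1 features by greedy EIC tracing.

    Seeds at the most intense unclaimed centroid above the intensity
    threshold, extends the trace scan-by-scan within the ppm tolerance,
    requires a local-maximum peak with FWHM inside the window and a
    coeluting M+1 trace at +1.0033548 Da whose apex ratio is plausible
    for an integer carbon count.  Returns features sorted by descending
    area.
    """
    p = p or FeatureFinderParams()
    ms1 = run.ms1()
    if len(ms1) < 3:
        raise ValueError("need at least 3 MS1 scans for feature detection")
    idx = _ScanIndex(ms1)

    seeds = []  # (intensity, scan, centroid)
    for si, (mzs, ints) in enumerate(zip(idx.mz, idx.inten)):
        for ci in np.flatnonzero(ints >= p.intensity_threshold):
            seeds.append((ints[ci], si, int(ci)))
    seeds.sort(key=lambda t: (-t[0], t[1], t[2]))

    features: List[Feature] = []
    n_scans = len(ms1)
    for seed_int, seed_scan, seed_ci in seeds:
        if idx.claimed[seed_scan][seed_ci]:
            continue
        seed_mz = idx.mz[seed_scan][seed_ci]
        tol = p.mass_error_ppm * 1e-6 * seed_mz
        trace: List[Tuple[int, int]] = [(seed_scan, seed_ci)]
        for direction in (-1, +1):
            scan = seed_scan + direction
            while 0 <= scan < n_scans:
                j = idx.nearest_unclaimed(scan, seed_mz, tol)
                if j is None:
                    break
                trace.append((scan, j))
                scan += direction
        trace.sort()
        t_rts = np.array([idx.rts[s] for s, _ in trace])
        t_int = np.array([idx.inten[s][j] for s, j in trace])
        t_mz = np.array([idx.mz[s][j] for s, j in trace])

        # claim the monoisotopic trace regardless of acceptance, so a
        # rejected trace is not re-seeded from a shoulder centroid
        for s, j in trace:
            idx.claimed[s][j] = True

        if len(trace) < 3:
            continue
        apex = int(np.argmax(t_int))
        if apex == 0 or apex == len(trace) - 1:
            continue  # no interior local maximum
        fwhm_min = _fwhm_minutes(t_rts, t_int, apex)
        if not np.isfinite(fwhm_min):
            continue
        if not (p.min_fwhm / 60.0 <= fwhm_min <= p.max_fwhm):
            continue

        # M+1 isotopologue trace
        m1_hits = 0
        m1_apex_int = 0.0
        m1_claim: List[Tuple[int, int]] = []
        for k, (s, j) in enumerate(trace):
            target = t_mz[k] + C13_C12_DELTA
            jj = idx.nearest_unclaimed(s, target, tol)
            if jj is not None:
                m1_hits += 1
                m1_claim.append((s, jj))
                if k == apex:
                    m1_apex_int = idx.inten[s][jj]
        n_traces = 1 + (1 if m1_hits >= 3 and m1_apex_int > 0 else 0)
        if n_traces < p.min_isotope_traces:
            continue

        apex_int = float(t_int[apex])
        if m1_apex_int > 0:
            ratio = m1_apex_int / apex_int
            c_est = ratio / M1_PER_CARBON
            n_c = max(1.0, round(c_est))
            expected = n_c * M1_PER_CARBON
            implausible = (
                c_est < 0.5
                or c_est > t_mz[apex] / 12.0
                or abs(ratio - expected) > p.isotope_ratio_rel_tol * expected
            )
            if implausible:
                continue

        for s, jj in m1_claim:
            idx.claimed[s][jj] = True

        apex_mz = float(np.average(t_mz, weights=t_int))
        area = float(np.trapezoid(t_int, t_rts))
        features.append(
            Feature(
                mz=apex_mz,
                rt=float(t_rts[apex]),
                area=area,
                intensity_M=apex_int,
                intensity_M1=float(m1_apex_int),
                fwhm=fwhm_min * 60.0,
                n_isotope_traces=n_traces,
            )
        )
    features.sort(key=lambda f: -f.area)
    return features


def features_from_table(rows: Sequence[ExternalFeatureRow]) -> List[Feature]:
    """Build features from an external feature table (apex intensities
    stand in for areas, as no raw chromatogram is available)."""
    return [
        Feature(
            mz=r.mz, rt=r.rt, area=r.intensity_M,
            intensity_M=r.intensity_M, intensity_M1=r.intensity_M1,
            n_isotope_traces=2 if r.intensity_M1 > 0 else 1,
            extras=dict(r.extras),
        )
        for r in rows
    ]


def estimate_carbon(f: Feature) -> Optional[float]:
    """Estimate the carbon number from the M+1/M ratio.

    C ~= (I_M+1 / I_M) / 0.011145.  Features without an M+1 intensity get
    no estimate and are flagged ``no_carbon_estimate`` (they are then
    excluded from carbon-normalized filtering).
    """
    if f.intensity_M <= 0:
        raise ValueError("feature has non-positive monoisotopic intensity")
    if f.intensity_M1 <= 0:
        f.carbon_est = None
        f.flags.add("no_carbon_estimate")
        return None
    f.carbon_est = (f.intensity_M1 / f.intensity_M) / M1_PER_CARBON
    return f.carbon_est


def align_ms2(
    features: Sequence[Feature],
    run: Run,
    mz_tol: float = 0.005,
    rt_tol: float = 0.2,
) -> Dict[int, int]:
    """Assign at most one MS2 spectrum to each feature.

    Each MS2 scan is matched to the nearest-m/z feature whose apex lies
    within ``mz_tol`` (Da) and ``rt_tol`` (min) of the precursor; among a
    feature's matched scans the one with the highest precursor intensity
    wins (ties: earlier scan).  Returns {feature index -> spectrum index}
    and stores the index on each feature.
    """
    candidates: Dict[int, List[Tuple[float, int]]] = {}
    for spec_idx, spec in enumerate(run.spectra):
        if spec.ms_level != 2:
            continue
        best_fi, best_d = None, mz_tol
        for fi, f in enumerate(features):
            d = abs(f.mz - spec.precursor_mz)
            if d <= best_d and abs(f.rt - spec.rt) <= rt_tol:
                best_fi, best_d = fi, d
        if best_fi is not None:
            prec_int = spec.precursor_intensity or 0.0
            candidates.setdefault(best_fi, []).append((prec_int, spec_idx))
    assignments: Dict[int, int] = {}
    for fi, lst in candidates.items():
        lst.sort(key=lambda t: (-t[0], t[1]))
        assignments[fi] = lst[0][1]
        features[fi].ms2_index = lst[0][1]
    return assignments


def blank_correct(
    sample: Sequence[Feature],
    blank: Sequence[Feature],
    mz_tol: float = 0.002,
    rt_tol: float = 0.1,
    fold: float = 5.0,
) -> List[Feature]:
    """Remove sample features explained by the blank.

    A sample feature is removed iff some blank feature matches within
    both tolerances and the sample area is less than ``fold`` times the
    blank area.  Removed features keep a ``blank_removed`` flag for the
    audit trail; the returned list holds the survivors.
    """
    if not blank:
        warnings.warn("empty blank feature list; blank correction skipped",
                      stacklevel=2)
        return list(sample)
    kept: List[Feature] = []
    for f in sample:
        removed = False
        for b in blank:
            if abs(f.mz - b.mz) <= mz_tol and abs(f.rt - b.rt) <= rt_tol:
                if f.area < fold * b.area:
                    removed = True
                    break
        if removed:
            f.flags.add("blank_removed")
        else:
            f.flags.discard("blank_removed")
            kept.append(f)
    return kept
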