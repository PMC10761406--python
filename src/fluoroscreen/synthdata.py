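"""Ground-truthed synthetic HRMS runs and feature tables.

The generator emulates the data regimes the screening pipeline must
handle, with every planted species carried as an explicit molecular
formula so that its exact m/z, isotope ratio, carbon number, m/C and
MD/C are all recomputable from first principles:

* hydrocarbon matrix features (CcHhOo, m/C between ~12.5 and 25) with
  Gaussian elution profiles and M/M+1 isotopologue traces;
* perfluoroalkyl homologous series (CF2-spaced ladders, e.g. PFCAs,
  PFSAs as [M-H]- ions) with a systematic per-homologue RT increment;
* shared blank contaminants (a fraction of the matrix reappearing in a
  paired blank run at equal abundance);
* ddMS2 scans for fluorinated species containing planted diagnostic
  fragments and CF2/HF fragment ladders, plus non-PFAS MS2 decoys;
* an in-source ion family (parent plus -HF / +Cl-H / +Ac-H satellites)
  sharing one elution profile, with coeluting and distant decoys.

The M+1/M ratio is planted as carbon_count x 0.011145, the per-carbon
convention the carbon estimator inverts, so ground-truth carbon numbers
are exactly recoverable on noise-free data.  Elution profiles are pure
Gaussians; tailing, chemical noise and electrospray response physics are
deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem
from .chem import (
    C13_C12_DELTA,
    M1_PER_CARBON,
    PROTON_MASS,
    combine,
    format_formula,
    monoisotopic_mass,
    parse_formula,
)
from .msio import Run, Spectrum, write_mzml

__all__ = [
    "SeriesSpec",
    "FamilySpec",
    "SynthConfig",
    "SynthResult",
    "generate_run",
    "generate_feature_csv",
    "preset_config",
]


@dataclass(frozen=True)
class SeriesSpec:
    """A planted homologous series: base formula extended by a repeating
    unit over a chain range, eluting with a fixed RT increment."""

    label: str
    base_formula: str  # formula of the shortest homologue (neutral)
    repeat_formula: str = "CF2"
    n_members: int = 7
    rt_start: float = 2.0  # minutes
    rt_step: float = 0.8  # minutes per homologue
    amplitude: float = 4e5
    adduct: str = "[M-H]-"


@dataclass(frozen=True)
class FamilySpec:
    """A planted in-source ion family sharing one elution profile."""

    parent_formula: str = "C16H9F26O4P"
    rt: float = 7.3
    amplitude: float = 6e5
    # satellite label -> (mass delta relative to the parent ion, rel. abundance)
    deltas: Tuple[Tuple[str, float, float], ...] = (
        ("-HF", -monoisotopic_mass("HF"), 0.55),
        ("+Cl-H", chem.ATOMIC_MASSES["Cl"] - chem.ATOMIC_MASSES["H"], 0.35),
        ("+Ac-H", monoisotopic_mass("C2H4O2") - chem.ATOMIC_MASSES["H"], 0.22),
    )


@dataclass
class SynthConfig:
    """Study conditions for one synthetic acquisition."""

    seed: int = 1
    # chromatography / acquisition
    rt_max: float = 10.0  # minutes
    scan_interval: float = 0.02  # minutes between MS1 scans
    peak_sigma: float = 0.03  # minutes (FWHM ~ 4.2 s)
    centroid_floor: float = 30.0  # counts; weaker signals emit no centroid
    polarity: str = "negative"
    # composition
    n_matrix_features: int = 60
    series: Tuple[SeriesSpec, ...] = ()
    family: Optional[FamilySpec] = None
    n_family_decoys: int = 0
    blank_overlap_fraction: float = 0.0
    amplitude_range: Tuple[float, float] = (1e4, 1e6)
    # noise model
    mz_jitter_ppm: float = 1.0
    intensity_noise_sd: float = 0.02
    # ddMS2
    ms2_for_fluorinated: bool = True
    ms2_df_formulas: Tuple[str, ...] = ("C2F5", "C3F7")
    ms2_ladder_len: int = 4
    ms2_noise_decoys: bool = True

    def noise_free(self) -> "SynthConfig":
        return replace(self, mz_jitter_ppm=0.0, intensity_noise_sd=0.0)


@dataclass
class _Species:
    sid: int
    kind: str  # matrix | pfas | family | decoy
    formula: str
    adduct: str
    mz: float
    rt: float
    amplitude: float
    carbon: int
    series_id: int = -1
    family_id: int = -1
    in_blank: bool = False
    has_ms2: bool = False
    ms2_peaks: Optional[List[Tuple[float, float]]] = None


@dataclass
class SynthResult:
    """A generated sample (and optional blank) with its ground truth."""

    run: Run
    blank_run: Optional[Run]
    truth: pd.DataFrame
    config: SynthConfig

    def write(self, outdir: str | Path, stem: str = "synthetic") -> Dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"mzml": write_mzml(self.run, outdir / f"{stem}.mzML")}
        if self.blank_run is not None:
            paths["blank_mzml"] = write_mzml(
                self.blank_run, outdir / f"{stem}_blank.mzML")
        truth_path = outdir / f"{stem}_truth.csv"
        self.truth.to_csv(truth_path, index=False, lineterminator="\n")
        paths["truth"] = truth_path
        return paths


def _min_separation_ok(mz: float, used: List[float], gap: float = 0.05) -> bool:
    """Keep planted ions >= `gap` Da away from existing M and M+1 traces."""
    if not used:
        return True
    u = np.asarray(used)
    for shift in (0.0, C13_C12_DELTA, -C13_C12_DELTA):
        if np.any(np.abs(mz - u + shift) < gap):
            return False
    return True


def _draw_matrix_formula(rng: np.random.Generator) -> Tuple[str, float]:
    """Random CcHhOo composition (humic-like matrix) with m/C in ~[12.5, 25]."""
    for _ in range(1000):
        c = int(rng.integers(8, 61))
        h = int(rng.integers(c, 2 * c + 3))
        o = int(rng.integers(0, int(0.8 * c) + 1))
        f = {"C": c, "H": h}
        if o:
            f["O"] = o
        mass = monoisotopic_mass(f)
        if 12.5 <= mass / c <= 25.0:
            return format_formula(f), mass
    raise RuntimeError("matrix formula sampling failed")  # pragma: no cover


def _hydrocarbon_ms2(rng: np.random.Generator, prec_mz: float) -> List[Tuple[float, float]]:
    """Non-PFAS MS2 decoy peaks: a CH2-spaced ladder below the precursor
    (gaps of 14.0157 Da; no CF2/HF gaps, no diagnostic-fragment masses)."""
    ch2 = chem.CH2.exact_mass
    base = prec_mz - float(rng.uniform(30.0, 60.0))
    n = int(rng.integers(3, 6))
    return [(base - k * ch2, float(rng.uniform(5e3, 5e4))) for k in range(n)]


def _fluorinated_ms2(
    cfg: SynthConfig, rng: np.random.Generator, prec_mz: float
) -> List[Tuple[float, float]]:
    """Planted PFAS MS2 content: diagnostic-fragment anions, a CF2-spaced
    fragment ladder hanging off the precursor, and one HF gap."""
    peaks: List[Tuple[float, float]] = []
    for f in cfg.ms2_df_formulas:
        peaks.append((monoisotopic_mass(f) + chem.ELECTRON_MASS,
                      float(rng.uniform(1e4, 8e4))))
    cf2 = chem.CF2.exact_mass
    for k in range(1, cfg.ms2_ladder_len + 1):
        peaks.append((prec_mz - k * cf2, float(rng.uniform(8e3, 5e4))))
    hf = monoisotopic_mass("HF")
    peaks.append((prec_mz - hf, float(rng.uniform(8e3, 5e4))))
    return peaks


def _plant_species(cfg: SynthConfig, rng: np.random.Generator) -> List[_Species]:
    species: List[_Species] = []
    used_mz: List[float] = []
    sid = 0
    lo, hi = cfg.amplitude_range

    def register(sp: _Species) -> None:
        nonlocal sid
        species.append(sp)
        used_mz.append(sp.mz)
        sid += 1

    # hydrocarbon matrix
    n_blank = int(round(cfg.blank_overlap_fraction * cfg.n_matrix_features))
    for i in range(cfg.n_matrix_features):
        while True:
            formula, mass = _draw_matrix_formula(rng)
            mz = mass - PROTON_MASS
            if _min_separation_ok(mz, used_mz):
                break
        rt = float(rng.uniform(0.8, cfg.rt_max - 0.8))
        amp = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        register(_Species(
            sid=sid, kind="matrix", formula=formula, adduct="[M-H]-",
            mz=mz, rt=rt, amplitude=amp,
            carbon=parse_formula(formula)["C"], in_blank=i < n_blank,
        ))

    # homologous series
    for s_idx, spec in enumerate(cfg.series):
        base = parse_formula(spec.base_formula)
        ru = parse_formula(spec.repeat_formula)
        for k in range(spec.n_members):
            f = dict(base)
            for _ in range(k):
                f = combine(f, ru)
            mz = chem.adduct_mz(monoisotopic_mass(f), spec.adduct)
            if not _min_separation_ok(mz, used_mz):
                raise ValueError(
                    f"series {spec.label} member {k} collides with a "
                    "planted m/z; adjust the configuration")
            rt = spec.rt_start + k * spec.rt_step
            if rt > cfg.rt_max - 0.5:
                raise ValueError(
                    f"series {spec.label} does not fit the RT range; "
                    "shorten it or extend rt_max")
            register(_Species(
                sid=sid, kind="pfas", formula=format_formula(f),
                adduct=spec.adduct, mz=mz, rt=rt, amplitude=spec.amplitude,
                carbon=f["C"], series_id=s_idx,
                has_ms2=cfg.ms2_for_fluorinated,
            ))

    # in-source family
    if cfg.family is not None:
        fam = cfg.family
        parent_f = parse_formula(fam.parent_formula)
        parent_mz = chem.adduct_mz(monoisotopic_mass(parent_f), "[M-H]-")
        members = [("[M-H]-", parent_mz, 1.0)]
        members += [(lab, parent_mz + d, rel) for lab, d, rel in fam.deltas]
        for lab, mz, rel in members:
            if not _min_separation_ok(mz, used_mz):
                raise ValueError("family ion collides with a planted m/z")
            register(_Species(
                sid=sid, kind="family", formula=fam.parent_formula,
                adduct=lab, mz=mz, rt=fam.rt, amplitude=fam.amplitude * rel,
                carbon=parent_f["C"], family_id=0,
                has_ms2=(lab == "[M-H]-") and cfg.ms2_for_fluorinated,
            ))
        # decoys: some coeluting near (but not with) the family, some far
        for i in range(cfg.n_family_decoys):
            while True:
                formula, mass = _draw_matrix_formula(rng)
                mz = mass - PROTON_MASS
                if _min_separation_ok(mz, used_mz):
                    break
            if i % 3 == 0:
                # inside the correlation RT window but apex-shifted
                off = float(rng.uniform(0.18, 0.38)) * (1 if i % 2 else -1)
                rt = fam.rt + off
            else:
                rt = float(rng.uniform(0.8, cfg.rt_max - 0.8))
                if abs(rt - fam.rt) < 0.6:
                    rt = fam.rt + 0.6 * np.sign(rt - fam.rt or 1.0)
            amp = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
            register(_Species(
                sid=sid, kind="decoy", formula=formula, adduct="[M-H]-",
                mz=mz, rt=rt, amplitude=amp,
                carbon=parse_formula(formula)["C"],
            ))

    # attach MS2 content
    for sp in species:
        if sp.has_ms2:
            sp.ms2_peaks = _fluorinated_ms2(cfg, rng, sp.mz)
    if cfg.ms2_noise_decoys:
        matrix = [sp for sp in species if sp.kind == "matrix"]
        for sp in matrix[: max(1, len(matrix) // 10)]:
            sp.has_ms2 = True
            sp.ms2_peaks = _hydrocarbon_ms2(rng, sp.mz)
    return species


def _build_scans(
    cfg: SynthConfig,
    rng: np.random.Generator,
    species: Sequence[_Species],
    with_ms2: bool,
) -> List[Spectrum]:
    grid = np.arange(0.0, cfg.rt_max + 1e-9, cfg.scan_interval)
    spectra: List[Spectrum] = []
    ms2_pending = {
        sp.sid: grid[np.argmin(np.abs(grid - sp.rt))]
        for sp in species if sp.has_ms2 and with_ms2
    }
    for t in grid:
        mzs: List[float] = []
        ints: List[float] = []
        for sp in species:
            inten = sp.amplitude * np.exp(
                -0.5 * ((t - sp.rt) / cfg.peak_sigma) ** 2)
            if inten < cfg.centroid_floor:
                continue
            ratio = sp.carbon * M1_PER_CARBON
            for mz0, i0 in ((sp.mz, inten), (sp.mz + C13_C12_DELTA, inten * ratio)):
                if i0 < cfg.centroid_floor:
                    continue
                jitter = (rng.normal(0.0, cfg.mz_jitter_ppm) * 1e-6 * mz0
                          if cfg.mz_jitter_ppm > 0 else 0.0)
                scale = (1.0 + rng.normal(0.0, cfg.intensity_noise_sd)
                         if cfg.intensity_noise_sd > 0 else 1.0)
                mzs.append(mz0 + jitter)
                ints.append(max(i0 * scale, 1.0))
        order = np.argsort(mzs) if mzs else []
        spectra.append(Spectrum(
            ms_level=1, rt=float(t),
            mz=np.array(mzs)[order] if len(mzs) else np.array([]),
            intensity=np.array(ints)[order] if len(ints) else np.array([]),
            polarity=cfg.polarity,
        ))
        # ddMS2 triggered right after the precursor's apex scan
        for sp in species:
            if sp.sid in ms2_pending and abs(t - ms2_pending[sp.sid]) < 1e-9:
                pk = sorted(sp.ms2_peaks or [])
                spectra.append(Spectrum(
                    ms_level=2, rt=float(t) + cfg.scan_interval / 4.0,
                    mz=np.array([p[0] for p in pk]),
                    intensity=np.array([p[1] for p in pk]),
                    polarity=cfg.polarity,
                    precursor_mz=sp.mz,
                    precursor_intensity=sp.amplitude,
                ))
                del ms2_pending[sp.sid]
    return spectra


def _truth_frame(species: Sequence[_Species]) -> pd.DataFrame:
    rows = []
    for sp in species:
        md = chem.mass_defect(sp.mz)
        rows.append({
            "species_id": sp.sid, "kind": sp.kind, "formula": sp.formula,
            "adduct": sp.adduct, "mz": sp.mz, "rt": sp.rt,
            "amplitude": sp.amplitude, "carbon": sp.carbon,
            "md": md, "mdc": md / sp.carbon, "m_over_c": sp.mz / sp.carbon,
            "series_id": sp.series_id, "family_id": sp.family_id,
            "in_blank": sp.in_blank, "has_ms2": sp.has_ms2,
        })
    return pd.DataFrame(rows)


def generate_run(cfg: SynthConfig) -> SynthResult:
    """Generate a synthetic centroided acquisition with ground truth.

    Returns the sample run, a paired blank run when
    ``blank_overlap_fraction > 0`` (containing the shared contaminants at
    their sample abundance), and a ground-truth table with one row per
    planted species.  Fixed seed => identical output.
    """
    rng = np.random.default_rng(cfg.seed)
    species = _plant_species(cfg, rng)
    sample = Run(
        spectra=_build_scans(cfg, rng, species, with_ms2=True),
        polarity=cfg.polarity, source="synthetic",
    )
    blank_run = None
    if cfg.blank_overlap_fraction > 0:
        blank_species = [sp for sp in species if sp.in_blank]
        blank_run = Run(
            spectra=_build_scans(cfg, rng, blank_species, with_ms2=False),
            polarity=cfg.polarity, source="synthetic_blank",
        )
    return SynthResult(run=sample, blank_run=blank_run,
                       truth=_truth_frame(species), config=cfg)


def generate_feature_csv(
    cfg: SynthConfig,
    n_matrix: Optional[int] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Tabular analogue of :func:`generate_run`: an external feature table
    (mz, rt, intensity_M, intensity_M1) plus its ground truth, with
    intensity_M1 = intensity_M x 0.011145 x C x (1 + noise)."""
    if n_matrix is not None:
        cfg = replace(cfg, n_matrix_features=n_matrix)
    rng = np.random.default_rng(cfg.seed)
    species = _plant_species(cfg, rng)
    rows = []
    for sp in species:
        noise = (rng.normal(0.0, cfg.intensity_noise_sd)
                 if cfg.intensity_noise_sd > 0 else 0.0)
        rows.append({
            "mz": sp.mz, "rt": sp.rt, "intensity_M": sp.amplitude,
            "intensity_M1": sp.amplitude * M1_PER_CARBON * sp.carbon * (1.0 + noise),
        })
    return pd.DataFrame(rows), _truth_frame(species)


PFCA_SERIES = SeriesSpec(
    label="PFCA", base_formula="C4HF7O2", n_members=7,
    rt_start=1.6, rt_step=0.75, amplitude=5e5)
PFSA_SERIES = SeriesSpec(
    label="PFSA", base_formula="C4HF9O3S", n_members=5,
    rt_start=2.4, rt_step=0.9, amplitude=3e5)


def preset_config(name: str, seed: int = 1) -> SynthConfig:
    """Named study conditions: matrix, series, family, or full."""
    if name == "matrix":
        return SynthConfig(seed=seed, n_matrix_features=60,
                           blank_overlap_fraction=0.3)
    if name == "series":
        return SynthConfig(seed=seed, n_matrix_features=40,
                           series=(PFCA_SERIES, PFSA_SERIES))
    if name == "family":
        return SynthConfig(seed=seed, n_matrix_features=20,
                           family=FamilySpec(), n_family_decoys=30)
    if name == "full":
        return SynthConfig(
            seed=seed, n_matrix_features=60,
            series=(PFCA_SERIES, PFSA_SERIES),
            family=FamilySpec(), n_family_decoys=30,
            blank_overlap_fraction=0.3,
        )
    raise ValueError(f"unknown preset {name!r}; use matrix/series/family/full")
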