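"""Three-stage screening pipeline: feature finding -> PFAS evidence -> report.

The pipeline is built for iterative use: every stage records its surviving
count, features are flagged rather than deleted, and the downstream
evidence channels (homologue detection, MS2 matching, suspect screening)
operate on the subset passing the carbon-normalized mass-defect filter so
that false positives in those channels stay manageable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import chem, features as feat, msio, prioritize as pri

logger = logging.getLogger("fluoroscreen")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "summarize",
           "features_to_frame", "load_config_file"]


@dataclass
class PipelineConfig:
    """All paths, tolerances and thresholds for one pipeline execution.

    Exactly one entry mode: either ``sample_mzml`` alone (internal feature
    finding) or ``feature_csv`` (external feature table) optionally with
    ``sample_mzml`` still supplying the MS2 scans.
    """

    sample_mzml: Optional[str] = None
    blank_mzml: Optional[str] = None
    feature_csv: Optional[str] = None
    suspect_csv: Optional[str] = None
    fragment_csv: Optional[str] = None
    difference_csv: Optional[str] = None

    polarity: str = "negative"
    adducts: Tuple[str, ...] = ("[M-H]-",)

    # feature finding
    mass_error_ppm: float = 10.0
    intensity_threshold: float = 2000.0
    min_fwhm: float = 1.0  # s
    max_fwhm: float = 1.0  # min
    min_isotope_traces: int = 2
    # MS2 alignment
    ms2_mz_tol: float = 0.005
    ms2_rt_tol: float = 0.2
    # blank correction
    blank_mz_tol: float = 0.002
    blank_rt_tol: float = 0.1
    blank_fold: float = 5.0
    # MD/C - m/C
    mc_min: Optional[float] = 30.0
    mdc_max: Optional[float] = 0.003
    # KMD homologous series
    kmd_unit: str = "CF2"
    kmd_tol: float = 0.002
    kmd_min_members: int = 3
    # MS2 matching
    frag_tol: float = 0.002
    ms2_noise: float = 2000.0
    min_df_hits: int = 1
    # suspect screening
    suspect_tol: float = 0.004

    def validate(self) -> None:
        if self.sample_mzml is None and self.feature_csv is None:
            raise ValueError(
                "provide a sample mzML, or an external feature CSV "
                "(optionally with an mzML for MS2 spectra)")


@dataclass
class PipelineResult:
    table: pd.DataFrame
    features: List[feat.Feature]
    series: List[pri.HomologousSeries]
    suspect_hits: List[pri.SuspectHit]
    stage_counts: Dict[str, int]
    config: PipelineConfig


def features_to_frame(features: Sequence[feat.Feature]) -> pd.DataFrame:
    """Flatten features and their evidence flags into the results table."""
    rows = []
    for i, f in enumerate(features):
        rows.append({
            "feature_id": i,
            "mz": f.mz, "rt": f.rt, "area": f.area,
            "intensity_M": f.intensity_M, "intensity_M1": f.intensity_M1,
            "carbon_est": f.carbon_est if f.carbon_est is not None else np.nan,
            "md": f.md if f.md is not None else np.nan,
            "mdc": f.mdc if f.mdc is not None else np.nan,
            "m_over_c": f.m_over_c if f.m_over_c is not None else np.nan,
            "mdc_mc_pass": "mdc_mc_pass" in f.flags,
            "hs_ids": ";".join(str(h) for h in f.hs_ids),
            "n_df_hits": int(f.extras.get("n_df_hits", 0)),
            "n_diff_hits": int(f.extras.get("n_diff_hits", 0)),
            "df_hit": "df_hit" in f.flags,
            "diff_hit": "diff_hit" in f.flags,
            "suspect_hit": "suspect_hit" in f.flags,
            "suspect_names": ";".join(f.extras.get("suspect_names", [])),
            "blank_removed": "blank_removed" in f.flags,
            "has_ms2": f.ms2_index is not None,
        })
    return pd.DataFrame(rows, columns=msio.RESULT_COLUMNS)


def run_pipeline(
    cfg: PipelineConfig,
    out_csv: Optional[str | Path] = None,
) -> PipelineResult:
    """Execute the full screening workflow and (optionally) write the
    results CSV.  Stage counts are logged and returned for the funnel
    report."""
    cfg.validate()
    counts: Dict[str, int] = {}
    run = msio.read_mzml(cfg.sample_mzml) if cfg.sample_mzml else None

    # stage 1: features
    if cfg.feature_csv:
        rows = msio.read_feature_csv(cfg.feature_csv)
        flist = feat.features_from_table(rows)
    else:
        params = feat.FeatureFinderParams(
            mass_error_ppm=cfg.mass_error_ppm,
            intensity_threshold=cfg.intensity_threshold,
            min_fwhm=cfg.min_fwhm, max_fwhm=cfg.max_fwhm,
            min_isotope_traces=cfg.min_isotope_traces,
        )
        flist = feat.detect_features(run, params)
    counts["features_detected"] = len(flist)
    logger.info("features detected: %d", len(flist))

    # stage 2: blank correction
    if cfg.blank_mzml:
        blank_run = msio.read_mzml(cfg.blank_mzml)
        params = feat.FeatureFinderParams(
            mass_error_ppm=cfg.mass_error_ppm,
            intensity_threshold=cfg.intensity_threshold,
            min_fwhm=cfg.min_fwhm, max_fwhm=cfg.max_fwhm,
            min_isotope_traces=cfg.min_isotope_traces,
        )
        blank_features = feat.detect_features(blank_run, params)
        kept = feat.blank_correct(
            flist, blank_features,
            mz_tol=cfg.blank_mz_tol, rt_tol=cfg.blank_rt_tol,
            fold=cfg.blank_fold)
    else:
        logger.warning("no blank provided; blank correction skipped")
        kept = list(flist)
    counts["after_blank_correction"] = len(kept)
    logger.info("after blank correction: %d", len(kept))

    # stage 3: carbon estimation + MD/C-m/C
    for f in kept:
        feat.estimate_carbon(f)
    pri.compute_mdc_mc(kept)
    passed = pri.filter_mdc_mc(kept, mc_min=cfg.mc_min, mdc_max=cfg.mdc_max)
    counts["after_mdc_mc"] = len(passed)
    logger.info("after MD/C-m/C filter: %d", len(passed))

    # stage 4: KMD homologous series on the prioritized subset
    ru = chem.RepeatingUnit.from_formula(cfg.kmd_unit)
    series = pri.detect_homologous_series(
        passed, ru, mass_tol=cfg.kmd_tol, min_members=cfg.kmd_min_members)
    counts["homologous_series"] = len(series)
    logger.info("homologous series (%s): %d", ru.label, len(series))

    # stage 5: MS2 evidence
    n_df_spectra = n_diff_spectra = 0
    if run is not None:
        feat.align_ms2(passed, run, mz_tol=cfg.ms2_mz_tol, rt_tol=cfg.ms2_rt_tol)
        dfs = (pri.read_fragment_csv(cfg.fragment_csv) if cfg.fragment_csv
               else pri.builtin_diagnostic_fragments(cfg.polarity))
        diffs = (pri.read_difference_csv(cfg.difference_csv)
                 if cfg.difference_csv else pri.builtin_mass_differences())
        for f in passed:
            if f.ms2_index is None:
                continue
            spec = run.spectra[f.ms2_index]
            hits, flagged = pri.match_diagnostic_fragments(
                spec, dfs, tol=cfg.frag_tol, noise=cfg.ms2_noise,
                min_hits=cfg.min_df_hits)
            f.extras["n_df_hits"] = len(hits)
            if flagged:
                f.flags.add("df_hit")
                n_df_spectra += 1
            dhits = pri.match_fragment_differences(
                spec, diffs, tol=cfg.frag_tol, noise=cfg.ms2_noise)
            f.extras["n_diff_hits"] = len(dhits)
            if dhits:
                f.flags.add("diff_hit")
                n_diff_spectra += 1
    counts["df_flagged_spectra"] = n_df_spectra
    counts["diff_flagged_spectra"] = n_diff_spectra

    # stage 6: suspect screening
    suspect_hits: List[pri.SuspectHit] = []
    if cfg.suspect_csv:
        suspects = pri.read_suspect_csv(cfg.suspect_csv)
        suspect_hits = pri.suspect_screen(
            passed, suspects, adducts=cfg.adducts, tol=cfg.suspect_tol,
            polarity=cfg.polarity)
    counts["suspect_hits"] = len(suspect_hits)

    table = features_to_frame(flist)
    if out_csv is not None:
        msio.write_results(table, out_csv)
    return PipelineResult(
        table=table, features=flist, series=series,
        suspect_hits=suspect_hits, stage_counts=counts, config=cfg,
    )


def summarize(result: PipelineResult) -> str:
    """Funnel report: per-stage counts and percentage of features retained."""
    c = result.stage_counts
    total = max(c.get("features_detected", 0), 1)
    lines = ["stage                      count   % of detected"]
    for key in ("features_detected", "after_blank_correction", "after_mdc_mc"):
        if key in c:
            lines.append(f"{key:<26} {c[key]:>5}   {100.0 * c[key] / total:6.1f}%")
    for key in ("homologous_series", "df_flagged_spectra",
                "diff_flagged_spectra", "suspect_hits"):
        if key in c:
            lines.append(f"{key:<26} {c[key]:>5}")
    return "\n".join(lines)


_BOOL = {"true": True, "false": False, "1": True, "0": False,
         "yes": True, "no": False}


def load_config_file(path: str | Path) -> PipelineConfig:
    """Read a flat ``key = value`` config file into a PipelineConfig.

    Lines starting with '#' are comments; 'none' clears a value;
    ``adducts`` takes a comma-separated list.
    """
    cfg = PipelineConfig()
    valid = {f.name: f for f in fields(PipelineConfig)}
    for ln, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{ln}: expected 'key = value'")
        key, _, val = line.partition("=")
        key, val = key.strip(), val.strip()
        if key not in valid:
            raise ValueError(f"{path}:{ln}: unknown config key {key!r}")
        if val.lower() == "none":
            setattr(cfg, key, None)
            continue
        current = getattr(cfg, key)
        if key == "adducts":
            setattr(cfg, key, tuple(a.strip() for a in val.split(",")))
        elif isinstance(current, bool):
            setattr(cfg, key, _BOOL[val.lower()])
        elif isinstance(current, int) and not isinstance(current, bool):
            setattr(cfg, key, int(val))
        elif isinstance(current, float) or current is None and key in (
                "mc_min", "mdc_max"):
            setattr(cfg, key, float(val))
        else:
            setattr(cfg, key, val)
    return cfg
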