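"""Shared fixtures: synthetic runs at known ground truth.

Session-scoped so the (cheap but not free) generation and feature
detection run once per suite.
"""

from __future__ import annotations

import numpy as np
import pytest

from fluoroscreen import features as feat
from fluoroscreen import synthdata
from fluoroscreen.msio import Run, Spectrum


def make_gaussian_run(
    species,
    rt_max: float = 4.0,
    dt: float = 0.02,
    sigma: float = 0.03,
    floor: float = 30.0,
    polarity: str = "negative",
    ms2=(),
) -> Run:
    """Hand-rolled run builder for unit tests.

    ``species`` is a list of dicts with keys mz, rt, amp and optional
    ``m1_ratio`` (M+1/M abundance; omit for no isotope trace).
    ``ms2`` is a list of dicts with keys rt, precursor_mz,
    precursor_intensity, peaks [(mz, intensity), ...].
    """
    spectra = []
    grid = np.arange(0.0, rt_max + 1e-9, dt)
    for t in grid:
        mzs, ints = [], []
        for sp in species:
            inten = sp["amp"] * np.exp(-0.5 * ((t - sp["rt"]) / sp.get("sigma", sigma)) ** 2)
            if inten < floor:
                continue
            mzs.append(sp["mz"])
            ints.append(inten)
            ratio = sp.get("m1_ratio", 0.0)
            if ratio > 0 and inten * ratio >= floor:
                mzs.append(sp["mz"] + 1.0033548)
                ints.append(inten * ratio)
        order = np.argsort(mzs) if mzs else []
        spectra.append(Spectrum(
            ms_level=1, rt=float(t),
            mz=np.asarray(mzs, dtype=float)[order] if mzs else np.array([]),
            intensity=np.asarray(ints, dtype=float)[order] if mzs else np.array([]),
            polarity=polarity,
        ))
    for m in ms2:
        peaks = sorted(m["peaks"])
        spectra.append(Spectrum(
            ms_level=2, rt=m["rt"],
            mz=np.array([p[0] for p in peaks]),
            intensity=np.array([p[1] for p in peaks]),
            polarity=polarity,
            precursor_mz=m["precursor_mz"],
            precursor_intensity=m.get("precursor_intensity", 1e4),
        ))
    return Run(spectra=spectra, polarity=polarity, source="unit-test")


@pytest.fixture(scope="session")
def full_noise_free():
    """Noise-free 'full' preset: matrix + 2 series + family + blank."""
    cfg = synthdata.preset_config("full", seed=11).noise_free()
    return synthdata.generate_run(cfg)


@pytest.fixture(scope="session")
def full_noise_free_features(full_noise_free):
    return feat.detect_features(full_noise_free.run)


@pytest.fixture(scope="session")
def family_noise_free():
    cfg = synthdata.preset_config("family", seed=5).noise_free()
    return synthdata.generate_run(cfg)


@pytest.fixture(scope="session")
def family_features(family_noise_free):
    return feat.detect_features(family_noise_free.run)


def match_feature(features, mz, rt, mz_tol=0.01, rt_tol=0.06):
    out = [f for f in features
           if abs(f.mz - mz) <= mz_tol and abs(f.rt - rt) <= rt_tol]
    return out
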