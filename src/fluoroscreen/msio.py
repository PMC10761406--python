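"""Reading and writing HRMS runs and feature tables.

mzML support is deliberately minimal and self-contained: the subset of the
PSI mzML 1.1 schema needed for centroided MS1/ddMS2 screening data
(spectrum list, ms level, scan start time, polarity, m/z and intensity
arrays with 32/64-bit float encoding and optional zlib compression, one
selected precursor ion per MS2 scan).  Written files are plain mzML that
conformant readers (e.g. Bioconductor mzR) parse; see the test suite for
the cross-reader check.

Retention times are minutes everywhere in this package; mzML files using
seconds are converted on read.
"""

from __future__ import annotations

import base64
import struct
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from lxml import etree

__all__ = [
    "Spectrum",
    "Run",
    "ExternalFeatureRow",
    "MzmlError",
    "read_mzml",
    "write_mzml",
    "read_feature_csv",
    "write_results",
]


class MzmlError(ValueError):
    """Unreadable or unsupported mzML content."""


@dataclass
class Spectrum:
    """One centroided scan (MS1 or MS2)."""

    ms_level: int
    rt: float  # minutes
    mz: np.ndarray  # ascending, Da
    intensity: np.ndarray  # counts, same length
    polarity: str = "negative"  # "negative" | "positive"
    precursor_mz: Optional[float] = None  # MS2 only
    precursor_intensity: Optional[float] = None

    def __post_init__(self):
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity arrays differ in length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            order = np.argsort(self.mz)
            self.mz = self.mz[order]
            self.intensity = self.intensity[order]
        if self.ms_level == 2 and self.precursor_mz is None:
            raise ValueError("MS2 spectrum requires a precursor m/z")


@dataclass
class Run:
    """An ordered acquisition of spectra from one file, single polarity."""

    spectra: List[Spectrum]
    polarity: str = "negative"
    source: str = ""

    def __post_init__(self):
        rts = [s.rt for s in self.spectra]
        if any(b < a - 1e-9 for a, b in zip(rts, rts[1:])):
            self.spectra = sorted(self.spectra, key=lambda s: s.rt)

    def ms1(self) -> List[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 1]

    def ms2(self) -> List[Spectrum]:
        return [s for s in self.spectra if s.ms_level == 2]


@dataclass
class ExternalFeatureRow:
    """One row of an externally produced feature table."""

    mz: float
    rt: float  # minutes
    intensity_M: float
    intensity_M1: float
    extras: Dict[str, object] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# mzML reading

_NS = "{http://psi.hupo.org/ms/mzml}"

_ACC_MS_LEVEL = "MS:1000511"
_ACC_CENTROID = "MS:1000127"
_ACC_PROFILE = "MS:1000128"
_ACC_NEG = "MS:1000129"
_ACC_POS = "MS:1000130"
_ACC_RT = "MS:1000016"
_ACC_PREC_MZ = "MS:1000744"
_ACC_PREC_INT = "MS:1000042"
_ACC_F64 = "MS:1000523"
_ACC_F32 = "MS:1000521"
_ACC_ZLIB = "MS:1000574"
_ACC_MZ_ARRAY = "MS:1000514"
_ACC_INT_ARRAY = "MS:1000515"


def _cv(elem) -> Dict[str, dict]:
    """accession -> cvParam attribute dict, over all descendants."""
    out = {}
    for cv in elem.iter(_NS + "cvParam", "cvParam"):
        out.setdefault(cv.get("accession"), dict(cv.attrib))
    return out


def _decode_array(bda) -> np.ndarray:
    cv = _cv(bda)
    binary = bda.find(_NS + "binary")
    if binary is None:
        binary = bda.find("binary")
    raw = base64.b64decode(binary.text or "")
    if _ACC_ZLIB in cv:
        raw = zlib.decompress(raw)
    dtype = "<f8" if _ACC_F64 in cv else "<f4"
    return np.frombuffer(raw, dtype=dtype).astype(float)


def _parse_spectrum(elem) -> Spectrum:
    cv = _cv(elem)
    if _ACC_PROFILE in cv and _ACC_CENTROID not in cv:
        raise MzmlError(
            "profile-mode spectrum encountered; centroid the file first"
        )
    ms_level = int(cv.get(_ACC_MS_LEVEL, {}).get("value", 1))
    polarity = "positive" if _ACC_POS in cv else "negative"
    rt_attr = cv.get(_ACC_RT, {})
    rt = float(rt_attr.get("value", "nan"))
    unit = (rt_attr.get("unitName") or "").lower()
    if unit.startswith("second"):
        rt /= 60.0
    mz = inten = np.array([])
    for bda in elem.iter(_NS + "binaryDataArray", "binaryDataArray"):
        acc = _cv(bda)
        if _ACC_MZ_ARRAY in acc:
            mz = _decode_array(bda)
        elif _ACC_INT_ARRAY in acc:
            inten = _decode_array(bda)
    prec_mz = prec_int = None
    if ms_level >= 2:
        for ion in elem.iter(_NS + "selectedIon", "selectedIon"):
            icv = _cv(ion)
            if _ACC_PREC_MZ in icv:
                prec_mz = float(icv[_ACC_PREC_MZ]["value"])
            if _ACC_PREC_INT in icv:
                prec_int = float(icv[_ACC_PREC_INT]["value"])
            break
        if prec_mz is None:
            raise MzmlError("MS2 spectrum without a selected precursor ion")
    return Spectrum(
        ms_level=ms_level, rt=rt, mz=mz, intensity=inten,
        polarity=polarity, precursor_mz=prec_mz, precursor_intensity=prec_int,
    )


def read_mzml(path: str | Path) -> Run:
    """Read a centroided single-polarity mzML file into a :class:`Run`.

    Raises :class:`MzmlError` for profile-mode spectra, mixed polarity,
    or files without spectra.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    spectra: List[Spectrum] = []
    try:
        context = etree.iterparse(
            str(path), events=("end",),
            tag=(_NS + "spectrum", "spectrum"),
        )
        for _, elem in context:
            spectra.append(_parse_spectrum(elem))
            elem.clear()
            while elem.getprevious() is not None:
                del elem.getparent()[0]
    except etree.XMLSyntaxError as e:
        raise MzmlError(f"cannot parse {path}: {e}") from None
    if not spectra:
        raise MzmlError(f"{path} contains no spectra")
    polarities = {s.polarity for s in spectra}
    if len(polarities) > 1:
        raise MzmlError(
            "mixed-polarity run; split the file into one polarity per run"
        )
    return Run(spectra=spectra, polarity=spectra[0].polarity, source=str(path))


# ---------------------------------------------------------------------------
# mzML writing

def _b64(arr: Sequence[float]) -> str:
    return base64.b64encode(
        np.asarray(arr, dtype="<f8").tobytes()
    ).decode("ascii")


def _spectrum_xml(i: int, s: Spectrum) -> str:
    pol = (
        ("MS:1000130", "positive scan")
        if s.polarity == "positive"
        else ("MS:1000129", "negative scan")
    )
    kind = (
        ("MS:1000579", "MS1 spectrum")
        if s.ms_level == 1
        else ("MS:1000580", "MSn spectrum")
    )
    p = [f'<spectrum index="{i}" id="scan={i + 1}" defaultArrayLength="{s.mz.size}">']
    p.append(f'<cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="{s.ms_level}"/>')
    p.append(f'<cvParam cvRef="MS" accession="{kind[0]}" name="{kind[1]}" value=""/>')
    p.append('<cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>')
    p.append(f'<cvParam cvRef="MS" accession="{pol[0]}" name="{pol[1]}" value=""/>')
    p.append(
        '<scanList count="1"><cvParam cvRef="MS" accession="MS:1000795" name="no combination" value=""/><scan>'
        f'<cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{s.rt:.6f}" '
        'unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/></scan></scanList>'
    )
    if s.ms_level == 2:
        p.append(
            '<precursorList count="1"><precursor><selectedIonList count="1"><selectedIon>'
            f'<cvParam cvRef="MS" accession="MS:1000744" name="selected ion m/z" value="{s.precursor_mz:.6f}" '
            'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
            f'<cvParam cvRef="MS" accession="MS:1000042" name="peak intensity" value="{(s.precursor_intensity or 0.0):.4f}" '
            'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
            '</selectedIon></selectedIonList><activation>'
            '<cvParam cvRef="MS" accession="MS:1000133" name="collision-induced dissociation" value=""/>'
            '</activation></precursor></precursorList>'
        )
    bmz, bint = _b64(s.mz), _b64(s.intensity)
    p.append('<binaryDataArrayList count="2">')
    p.append(
        f'<binaryDataArray encodedLength="{len(bmz)}">'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value="" '
        'unitCvRef="MS" unitAccession="MS:1000040" unitName="m/z"/>'
        f'<binary>{bmz}</binary></binaryDataArray>'
    )
    p.append(
        f'<binaryDataArray encodedLength="{len(bint)}">'
        '<cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>'
        '<cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value="" '
        'unitCvRef="MS" unitAccession="MS:1000131" unitName="number of detector counts"/>'
        f'<binary>{bint}</binary></binaryDataArray>'
    )
    p.append('</binaryDataArrayList></spectrum>')
    return "".join(p)


_MZML_HEADER = """<?xml version="1.0" encoding="utf-8"?>
<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">
<cvList count="2">
<cv id="MS" fullName="Proteomics Standards Initiative Mass Spectrometry Ontology" URI="https://raw.githubusercontent.com/HUPO-PSI/psi-ms-CV/master/psi-ms.obo"/>
<cv id="UO" fullName="Unit Ontology" URI="http://ontologies.berkeleybop.org/uo.obo"/>
</cvList>
<fileDescription><fileContent><cvParam cvRef="MS" accession="MS:1000579" name="MS1 spectrum" value=""/><cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/></fileContent></fileDescription>
<softwareList count="1"><software id="fluoroscreen" version="0.1"><cvParam cvRef="MS" accession="MS:1000799" name="custom unreleased software tool" value="fluoroscreen"/></software></softwareList>
<instrumentConfigurationList count="1"><instrumentConfiguration id="IC1"><cvParam cvRef="MS" accession="MS:1000031" name="instrument model" value=""/></instrumentConfiguration></instrumentConfigurationList>
<dataProcessingList count="1"><dataProcessing id="dp1"><processingMethod order="1" softwareRef="fluoroscreen"><cvParam cvRef="MS" accession="MS:1000544" name="Conversion to mzML" value=""/></processingMethod></dataProcessing></dataProcessingList>
"""


def write_mzml(run: Run, path: str | Path) -> Path:
    """Write a :class:`Run` as minimal, uncompressed, centroided mzML."""
    path = Path(path)
    chunks = [_MZML_HEADER]
    chunks.append('<run id="run1" defaultInstrumentConfigurationRef="IC1">\n')
    chunks.append(
        f'<spectrumList count="{len(run.spectra)}" defaultDataProcessingRef="dp1">\n'
    )
    for i, s in enumerate(run.spectra):
        chunks.append(_spectrum_xml(i, s))
        chunks.append("\n")
    chunks.append("</spectrumList>\n</run>\n</mzML>\n")
    path.write_text("".join(chunks))
    return path


# ---------------------------------------------------------------------------
# CSV feature tables and results

DEFAULT_FEATURE_COLUMNS = {
    "mz": "mz",
    "rt": "rt",
    "intensity_M": "intensity_M",
    "intensity_M1": "intensity_M1",
}


def read_feature_csv(
    path: str | Path,
    columns: Optional[Dict[str, str]] = None,
) -> List[ExternalFeatureRow]:
    """Read an external feature table (m/z, RT, M and M+1 intensities).

    ``columns`` maps the canonical names (mz, rt, intensity_M,
    intensity_M1) to the header names actually present.  Extra columns are
    carried through untouched in ``ExternalFeatureRow.extras``.
    """
    colmap = dict(DEFAULT_FEATURE_COLUMNS)
    if columns:
        colmap.update(columns)
    df = pd.read_csv(path)
    missing = [v for v in colmap.values() if v not in df.columns]
    if missing:
        raise ValueError(
            f"feature table {path} is missing required column(s): {missing}"
        )
    rows: List[ExternalFeatureRow] = []
    extra_cols = [c for c in df.columns if c not in colmap.values()]
    for i, rec in df.iterrows():
        vals = {}
        for canon, col in colmap.items():
            try:
                vals[canon] = float(rec[col])
            except (TypeError, ValueError):
                raise ValueError(
                    f"non-numeric value {rec[col]!r} in column {col!r}, row {i}"
                ) from None
        if vals["intensity_M1"] > vals["intensity_M"] * 1.2:
            import warnings

            warnings.warn(
                f"row {i}: M+1 intensity exceeds 1.2x M intensity "
                "(implausible isotope ratio)", stacklevel=2,
            )
        rows.append(
            ExternalFeatureRow(
                mz=vals["mz"], rt=vals["rt"],
                intensity_M=vals["intensity_M"],
                intensity_M1=vals["intensity_M1"],
                extras={c: rec[c] for c in extra_cols},
            )
        )
    return rows


RESULT_COLUMNS = [
    "feature_id", "mz", "rt", "area", "intensity_M", "intensity_M1",
    "carbon_est", "md", "mdc", "m_over_c", "mdc_mc_pass", "hs_ids",
    "n_df_hits", "n_diff_hits", "df_hit", "diff_hit",
    "suspect_hit", "suspect_names", "blank_removed", "has_ms2",
]


def write_results(table: pd.DataFrame, path: str | Path) -> Path:
    """Write a results table as CSV with a deterministic column order.

    Columns outside the canonical set are appended after it in their
    existing order; floats are written at full precision.
    """
    path = Path(path)
    cols = [c for c in RESULT_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table.loc[:, cols].to_csv(path, index=False, lineterminator="\n")
    return path
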