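"""Spectral containers, readers/writers and MS1 feature assembly.

Containers are deliberately small: centroided peak lists as numpy arrays, an
``Ms2Spectrum`` per data-dependent scan, and a ``Feature`` per MS1 consensus
ion (m/z, retention time, charge, intensity, optional isotope envelope and
linked MS2 scan).

Files are read with pyteomics (mzML and MGF).  Synthetic runs and exports are
written as MGF; mzML is read-only.  Feature assembly is a simplified
grid-free grouping (centroids within a ppm window and contiguous retention
time), not a re-implementation of chromatogram deconvolution: feature
finding is upstream plumbing here, not the method under study.
"""

from __future__ import annotations

import base64
import os
import struct
import zlib
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from lxml import etree
from pyteomics import mgf as _mgf

from .formula import monoisotopic_mass, REPORTED
from .library import default_library

__all__ = [
    "CentroidPeak",
    "Ms2Spectrum",
    "Ms1Scan",
    "Feature",
    "RawRun",
    "QCEntry",
    "QCReport",
    "read_spectra",
    "write_mgf",
    "infer_charge",
    "assemble_features",
    "attach_ms2",
    "qc_internal_standards",
    "features_to_table",
    "read_feature_table",
]

#: C13 - C12 mass difference, the isotope spacing unit.
ISOTOPE_SPACING = 1.003355
#: Tolerance on isotope spacing (Da) at ~70k resolution.
ISOTOPE_TOL = 0.01


@dataclass(frozen=True)
class CentroidPeak:
    mz: float
    intensity: float

    def __post_init__(self):
        if self.mz <= 0:
            raise ValueError("m/z must be positive")
        if self.intensity < 0:
            raise ValueError("intensity must be non-negative")


def _sorted_peak_arrays(mz, intensity):
    mz = np.asarray(mz, dtype=float)
    intensity = np.asarray(intensity, dtype=float)
    if mz.shape != intensity.shape:
        raise ValueError("m/z and intensity arrays differ in length")
    order = np.argsort(mz, kind="stable")
    return mz[order], intensity[order]


@dataclass
class Ms2Spectrum:
    """A centroided data-dependent MS2 scan."""

    precursor_mz: float
    rt: float
    mz: np.ndarray
    intensity: np.ndarray
    precursor_z: Optional[int] = None
    title: str = ""

    def __post_init__(self):
        if self.precursor_mz <= 0:
            raise ValueError("precursor m/z must be positive")
        self.mz, self.intensity = _sorted_peak_arrays(self.mz, self.intensity)

    @property
    def peaks(self) -> list[CentroidPeak]:
        return [CentroidPeak(m, i) for m, i in zip(self.mz, self.intensity)]

    def __len__(self) -> int:
        return len(self.mz)


@dataclass
class Ms1Scan:
    rt: float
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self):
        self.mz, self.intensity = _sorted_peak_arrays(self.mz, self.intensity)


@dataclass
class Feature:
    """An MS1 consensus ion with optional envelope and linked MS2 scan."""

    mz: float
    rt: float
    z: Optional[int]
    intensity: float
    envelope: Optional[np.ndarray] = None  # m/z of isotope peaks
    ms2: Optional[Ms2Spectrum] = None
    feature_id: str = ""
    charge_flag: str = ""  # "undetermined" when no consistent isotope spacing

    def __post_init__(self):
        if self.rt < 0:
            raise ValueError("retention time must be non-negative")


@dataclass
class RawRun:
    """Scans read from one acquisition, split by MS level."""

    ms1: list[Ms1Scan] = field(default_factory=list)
    ms2: list[Ms2Spectrum] = field(default_factory=list)


# ---------------------------------------------------------------------------
# readers / writers

def read_spectra(path, fmt: Optional[str] = None) -> RawRun:
    """Read centroided scans from an mzML or MGF file.

    Profile-mode mzML spectra are rejected with an explicit message.  MGF
    carries MS2 only; mzML may carry both levels.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.getsize(path) == 0:
        raise ValueError(f"empty file: {path}")
    if fmt is None:
        ext = os.path.splitext(str(path))[1].lower()
        fmt = {".mgf": "mgf", ".mzml": "mzml"}.get(ext)
        if fmt is None:
            raise ValueError(f"cannot infer format from extension of {path}")
    if fmt == "mgf":
        return _read_mgf(path)
    if fmt == "mzml":
        return _read_mzml(path)
    raise ValueError(f"unsupported format {fmt!r}")


def _read_mgf(path) -> RawRun:
    run = RawRun()
    # sequential reader: robust to duplicate or missing TITLE lines
    with _mgf.MGF(str(path)) as reader:
        for spec in reader:
            params = spec["params"]
            pep = params.get("pepmass", (0.0,))
            pmz = float(pep[0] if isinstance(pep, (tuple, list)) else pep)
            charge = params.get("charge")
            z = int(charge[0]) if charge else None
            rt = float(params.get("rtinseconds", 0.0)) / 60.0
            run.ms2.append(
                Ms2Spectrum(
                    precursor_mz=pmz,
                    rt=rt,
                    mz=spec["m/z array"],
                    intensity=spec["intensity array"],
                    precursor_z=z,
                    title=str(params.get("title", "")),
                )
            )
    if not run.ms2:
        raise ValueError(f"no spectra found in {path}")
    return run


# Minimal mzML reader for centroided MS1/MS2 scans.  Written in-package:
# mzML is plain XML with base64-encoded peak arrays, and only the handful of
# controlled-vocabulary terms used below matters for this pipeline.
_CV = {
    "ms_level": "MS:1000511",
    "centroid": "MS:1000127",
    "profile": "MS:1000128",
    "rt": "MS:1000016",
    "mz_array": "MS:1000514",
    "intensity_array": "MS:1000515",
    "f64": "MS:1000523",
    "f32": "MS:1000521",
    "zlib": "MS:1000574",
    "no_compression": "MS:1000576",
    "selected_mz": "MS:1000744",
    "charge": "MS:1000041",
}


def _cvparams(element) -> dict:
    out = {}
    for cv in element.iter("{*}cvParam"):
        out[cv.get("accession")] = cv
    return out


def _decode_binary_array(bda) -> np.ndarray:
    cvs = _cvparams(bda)
    node = bda.find("{*}binary")
    raw = base64.b64decode((node.text or "").strip()) if node is not None else b""
    if _CV["zlib"] in cvs:
        raw = zlib.decompress(raw)
    width, code = (4, "f") if _CV["f32"] in cvs else (8, "d")
    return np.array(struct.unpack(f"<{len(raw) // width}{code}", raw))


def _read_mzml(path) -> RawRun:
    run = RawRun()
    tree = etree.parse(str(path))
    for spec in tree.iter("{*}spectrum"):
        cvs = _cvparams(spec)
        if _CV["profile"] in cvs:
            raise ValueError(
                "profile-mode data are not supported; centroid before reading"
            )
        level = int(cvs[_CV["ms_level"]].get("value")) if _CV["ms_level"] in cvs else 1
        rt = 0.0
        if _CV["rt"] in cvs:
            cv = cvs[_CV["rt"]]
            rt = float(cv.get("value"))
            if (cv.get("unitName") or "").startswith("second"):
                rt /= 60.0
        mz = intensity = None
        for bda in spec.iter("{*}binaryDataArray"):
            arr_cvs = _cvparams(bda)
            if _CV["mz_array"] in arr_cvs:
                mz = _decode_binary_array(bda)
            elif _CV["intensity_array"] in arr_cvs:
                intensity = _decode_binary_array(bda)
        if mz is None or intensity is None:
            continue
        if level == 1:
            run.ms1.append(Ms1Scan(rt, mz, intensity))
        else:
            pmz, z = 0.0, None
            sel = spec.find(".//{*}selectedIon")
            if sel is not None:
                sel_cvs = _cvparams(sel)
                if _CV["selected_mz"] in sel_cvs:
                    pmz = float(sel_cvs[_CV["selected_mz"]].get("value"))
                if _CV["charge"] in sel_cvs:
                    z = int(sel_cvs[_CV["charge"]].get("value"))
            run.ms2.append(
                Ms2Spectrum(
                    precursor_mz=pmz,
                    rt=rt,
                    mz=mz,
                    intensity=intensity,
                    precursor_z=z,
                    title=str(spec.get("id", "")),
                )
            )
    if not run.ms1 and not run.ms2:
        raise ValueError(f"no spectra found in {path}")
    return run


def write_mgf(spectra: Iterable[Ms2Spectrum], path) -> None:
    """Write MS2 spectra as MGF (PEPMASS, CHARGE, RTINSECONDS, TITLE)."""
    records = []
    for s in spectra:
        params = {
            "pepmass": (round(s.precursor_mz, 6),),
            "rtinseconds": round(s.rt * 60.0, 3),
            "title": s.title,
        }
        if s.precursor_z:
            params["charge"] = [s.precursor_z]
        records.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    _mgf.write(records, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# charge inference and feature assembly

def infer_charge(envelope_mz: Sequence[float], tol: float = ISOTOPE_TOL) -> Optional[int]:
    """Charge from isotope spacing: z = round(1/median spacing).

    Returns None (undetermined) for fewer than two peaks or when the median
    spacing is not within ``tol`` of 1/z for any z in 1..3.  Ties toward the
    lower charge.
    """
    mzs = np.sort(np.asarray(envelope_mz, dtype=float))
    if mzs.size < 2:
        return None
    spacing = float(np.median(np.diff(mzs)))
    if spacing <= 0:
        return None
    for z in (1, 2, 3):  # ascending: ties break toward lower z
        if abs(spacing - ISOTOPE_SPACING / z) <= tol:
            return z
    return None


def assemble_features(
    ms1_scans: Sequence[Ms1Scan],
    mz_tol_ppm: float = 5.0,
    rt_gap: float = 0.1,
) -> list[Feature]:
    """Group MS1 centroids into features and fold in isotope envelopes.

    Centroids within ``mz_tol_ppm`` and contiguous in retention time (gaps
    <= ``rt_gap`` minutes) form one trace; the apex (max intensity) defines
    the feature.  Traces one isotope spacing above a stronger trace at the
    same retention time are folded into its envelope, and the charge is
    inferred from the spacing.  Features without a consistent envelope keep
    z = None and are flagged, not dropped.
    """
    pts = [
        (scan.rt, m, i)
        for scan in ms1_scans
        for m, i in zip(scan.mz, scan.intensity)
        if i > 0
    ]
    if not pts:
        return []
    pts.sort(key=lambda p: (p[1], p[0]))
    # split by m/z window
    traces: list[list[tuple[float, float, float]]] = []
    current = [pts[0]]
    for p in pts[1:]:
        if (p[1] - current[-1][1]) / current[-1][1] * 1e6 <= mz_tol_ppm:
            current.append(p)
        else:
            traces.append(current)
            current = [p]
    traces.append(current)
    # split traces at retention-time gaps
    split: list[list[tuple[float, float, float]]] = []
    for tr in traces:
        tr.sort(key=lambda p: p[0])
        cur = [tr[0]]
        for p in tr[1:]:
            if p[0] - cur[-1][0] <= rt_gap:
                cur.append(p)
            else:
                split.append(cur)
                cur = [p]
        split.append(cur)

    protos = []
    for tr in split:
        apex = max(tr, key=lambda p: p[2])
        w = np.array([p[2] for p in tr])
        mz = float(np.average([p[1] for p in tr], weights=w))
        protos.append({"mz": mz, "rt": apex[0], "intensity": apex[2]})
    protos.sort(key=lambda f: -f["intensity"])

    features: list[Feature] = []
    used = [False] * len(protos)
    by_mz = sorted(range(len(protos)), key=lambda i: protos[i]["mz"])
    mz_arr = np.array([protos[i]["mz"] for i in by_mz])
    for i, proto in enumerate(protos):
        if used[i]:
            continue
        used[i] = True
        env = [proto["mz"]]
        members: list[int] = []
        got_z = None
        for z in (1, 2, 3):
            cand_env = [proto["mz"]]
            cand_members = []
            for j_iso in (1, 2, 3):
                target = proto["mz"] + j_iso * ISOTOPE_SPACING / z
                lo = int(np.searchsorted(mz_arr, target - ISOTOPE_TOL))
                hi = int(np.searchsorted(mz_arr, target + ISOTOPE_TOL))
                best = None
                best_key = None
                for kk in range(lo, hi):
                    idx = by_mz[kk]
                    if used[idx]:
                        continue
                    cand = protos[idx]
                    if (
                        abs(cand["rt"] - proto["rt"]) <= rt_gap
                        and cand["intensity"] <= proto["intensity"] * 1.2
                    ):
                        key = (abs(cand["rt"] - proto["rt"]), abs(cand["mz"] - target))
                        if best is None or key < best_key:
                            best, best_key = idx, key
                if best is None:
                    break
                cand_env.append(protos[best]["mz"])
                cand_members.append(best)
            if len(cand_env) > len(env) or (len(cand_env) > 1 and got_z is None):
                env, members, got_z = cand_env, cand_members, z
        for idx in members:
            used[idx] = True
        z_inf = infer_charge(env) if len(env) >= 2 else None
        features.append(
            Feature(
                mz=proto["mz"],
                rt=proto["rt"],
                z=z_inf,
                intensity=proto["intensity"],
                envelope=np.array(env),
                charge_flag="" if z_inf else "undetermined",
            )
        )
    features.sort(key=lambda f: (f.rt, f.mz))
    for i, f in enumerate(features):
        if not f.feature_id:
            f.feature_id = f"F{i + 1:04d}"
    return features


def attach_ms2(
    features: Sequence[Feature],
    ms2_spectra: Sequence[Ms2Spectrum],
    mz_tol: float = 0.02,
    rt_tol: float = 0.2,
) -> list[Feature]:
    """Attach each MS2 scan to the nearest feature within the tolerances."""
    out = [replace(f) for f in features]
    for spec in ms2_spectra:
        best, best_d = None, None
        for f in out:
            d_mz = abs(f.mz - spec.precursor_mz)
            d_rt = abs(f.rt - spec.rt)
            if d_mz <= mz_tol and d_rt <= rt_tol:
                key = (d_mz, d_rt)
                if best_d is None or key < best_d:
                    best, best_d = f, key
        if best is not None and best.ms2 is None:
            best.ms2 = spec
    return out


# ---------------------------------------------------------------------------
# QC against internal standards

@dataclass(frozen=True)
class QCEntry:
    name: str
    expected_mz: float
    found: bool
    observed_mz: Optional[float] = None
    delta_ppm: Optional[float] = None
    rt: Optional[float] = None


@dataclass(frozen=True)
class QCReport:
    entries: tuple

    @property
    def passed(self) -> bool:
        return all(e.found for e in self.entries)


def qc_internal_standards(
    features: Sequence[Feature], tol_ppm: float = 5.0
) -> QCReport:
    """Check the spiked internal standards' [M+H]+ ions at <= tol_ppm.

    Absence or an out-of-tolerance mass is reported, never raised; the
    measured offset is included either way when a nearby ion exists.
    """
    lib = default_library()
    entries = []
    for std in lib.internal_standards:
        expected = monoisotopic_mass(std["formula"]) + REPORTED["H"]
        best = None
        for f in features:
            dppm = (f.mz - expected) / expected * 1e6
            if abs(dppm) <= 3 * tol_ppm and (f.z in (None, 1)):
                if best is None or abs(dppm) < abs(best[1]):
                    best = (f, dppm)
        if best is None:
            entries.append(QCEntry(std["name"], expected, False))
        else:
            f, dppm = best
            entries.append(
                QCEntry(
                    std["name"],
                    expected,
                    found=abs(dppm) <= tol_ppm,
                    observed_mz=f.mz,
                    delta_ppm=dppm,
                    rt=f.rt,
                )
            )
    return QCReport(tuple(entries))


# ---------------------------------------------------------------------------
# feature tables

def features_to_table(features: Sequence[Feature]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [f.feature_id for f in features],
            "mz": [round(f.mz, 4) for f in features],
            "rt": [round(f.rt, 2) for f in features],
            "z": [f.z if f.z is not None else "" for f in features],
            "intensity": [f.intensity for f in features],
            "has_ms2": [f.ms2 is not None for f in features],
        }
    )


def read_feature_table(path) -> list[Feature]:
    df = pd.read_csv(path, sep="\t")
    feats = []
    for _, row in df.iterrows():
        z = row.get("z")
        z = None if pd.isna(z) or z == "" else int(z)
        feats.append(
            Feature(
                mz=float(row["mz"]),
                rt=float(row["rt"]),
                z=z,
                intensity=float(row["intensity"]),
                feature_id=str(row["feature_id"]),
            )
        )
    return feats
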