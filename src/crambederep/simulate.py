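"""Labelled synthetic LC-MS/MS runs with the structure the annotator assumes.

The generator is the forward model of the fragmentation rules: for each
planted compound it emits a precursor ion at the theoretical m/z of its
protonated form (with optional mass jitter), an isotope envelope with 1/z
spacing, and an MS2 spectrum whose peaks are the sub-family's diagnostic
ions under a family intensity profile — the C-family C-diagnostic dication
dominates its spectra while the retro-Diels-Alder pair appears at clearly
lower intensity, and vice versa for the B family.  Decoy peaks are drawn
uniformly over m/z 60..precursor but rejected inside tolerance windows
around true diagnostic ions, so the planted truth stays well defined; an
adversarial mode deliberately places decoys inside those windows instead.

Every random draw goes through one seeded generator, so a fixed seed yields
byte-identical runs, and the manifest records the planted ground truth for
scoring.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .formula import REPORTED, Formula, monoisotopic_mass, parse_formula
from .library import CrambescidinEntry, ScaffoldLibrary, SeriesParams, default_library
from .reference import SERIES_FAMILIES, load_reference
from .spectra import ISOTOPE_SPACING, Feature, Ms1Scan, Ms2Spectrum, write_mgf

__all__ = [
    "PlantedCompound",
    "GeneratorConfig",
    "SyntheticRun",
    "generate_spectrum",
    "generate_run",
    "extractlike_manifest",
    "evaluate_run",
]

#: Relative-intensity ranges (percent of base peak before rescaling) per
#: fragment role and family.  Qualitative reported intensity statements
#: ("intense", "significantly lower") encoded as ratio bounds.
_PROFILE_AB = {
    "ch2n2_loss": (40, 80),
    "alkyl_loss": (30, 70),
    "guanidinoalkyl": (50, 100),
    "guanidinoalkyl_dehydrated": (10, 30),
    "ester_core": (5, 20),
    "ester_ring": (5, 15),
    "a3_core": (10, 30),
    "ch2n2_loss_1plus": (2, 8),
}
_PROFILE_B = {
    "rda_upper": (70, 100),
    "rda_lower": (40, 80),
    "rda_upper_ch2n2": (20, 50),
    "spiroaminal": (15, 40),
    "guanidinoalkyl": (30, 70),
    "guanidinoalkyl_dehydrated": (5, 20),
}
_PROFILE_C = {
    "c_diagnostic": (60, 100),
    "guanidinoalkyl": (30, 70),
    "guanidinoalkyl_dehydrated": (5, 20),
}
#: B-type ions leaking into C-family spectra, at clearly lower intensity.
_C_LEAK_RANGE = (5, 25)
_PROFILES = {
    "A": _PROFILE_AB,
    "didehydroA": _PROFILE_AB,
    "A3": _PROFILE_AB,
    "B": _PROFILE_B,
    "B3": _PROFILE_B,
    "C": _PROFILE_C,
    "C3": _PROFILE_C,
}
_MARKER_RANGES = {"core_264": (40, 100), "core_dehydrated_246": (30, 80), "pyrrolinium_70": (20, 60)}
#: Characteristic fragments planted for the spiked standards (plumbing only).
_STANDARD_FRAGMENTS = {
    "yohimbine": [(144.0807, 60.0), (212.1274, 40.0)],
    "reserpine": [(195.0642, 55.0), (397.2098, 35.0)],
}
_GUANIDINIUM_MZ = 60.0561  # [CH6N3]+


@dataclass(frozen=True)
class PlantedCompound:
    """Ground truth for one planted feature."""

    name: str
    rt: float
    z: int
    params: Optional[SeriesParams] = None
    entry: Optional[CrambescidinEntry] = None
    standard: bool = False
    base_intensity: Optional[float] = None

    def formula(self, library: Optional[ScaffoldLibrary] = None) -> Formula:
        lib = library or default_library()
        if self.params is not None:
            return lib.series_formula(self.params)
        if self.entry is not None:
            return self.entry.formula
        for std in lib.internal_standards:
            if std["name"] == self.name:
                return std["formula"]
        raise ValueError(f"no formula source for {self.name}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic-run generator.

    ``mass_jitter_ppm`` bounds the mass error: each m/z gets a Gaussian ppm
    offset with sigma = bound/3, truncated at ±bound (a calibrated-Orbitrap
    error model).  ``decoys_per_spectrum`` adds uniform noise peaks that
    avoid (default) or target (adversarial) the true-ion windows.
    """

    seed: int = 0
    mass_jitter_ppm: float = 0.0
    decoys_per_spectrum: int = 0
    isotope_peaks: int = 3
    include_standards: bool = True
    adversarial_decoys: bool = False
    residual_precursor: float = 30.0  # percent of MS2 base peak

    def __post_init__(self):
        if self.mass_jitter_ppm < 0:
            raise ValueError("jitter must be non-negative")
        if self.isotope_peaks < 1:
            raise ValueError("need at least the monoisotopic peak")


@dataclass
class SyntheticRun:
    features: list[Feature]
    spectra: list[Ms2Spectrum]
    compounds: list[PlantedCompound]
    manifest: pd.DataFrame
    overlap_warnings: list[str] = field(default_factory=list)

    def ms1_scans(self, n_scans: int = 3, rt_step: float = 0.05) -> list[Ms1Scan]:
        """Re-render features as MS1 scans (a short trace around each apex)."""
        shape = np.array([0.6, 1.0, 0.7] + [0.5] * max(0, n_scans - 3))[:n_scans]
        bins: dict[float, list[tuple[float, float]]] = {}
        for f in self.features:
            env = f.envelope if f.envelope is not None else np.array([f.mz])
            env_int = f.intensity * _envelope_profile(len(env), 30)
            for s in range(n_scans):
                rt = round(f.rt + (s - n_scans // 2) * rt_step, 4)
                for m, i in zip(env, env_int):
                    bins.setdefault(rt, []).append((m, i * shape[s]))
        return [
            Ms1Scan(rt, np.array([p[0] for p in pts]), np.array([p[1] for p in pts]))
            for rt, pts in sorted(bins.items())
        ]

    def write(self, directory) -> None:
        import os

        os.makedirs(directory, exist_ok=True)
        write_mgf(self.spectra, os.path.join(directory, "run.mgf"))
        from .spectra import features_to_table

        features_to_table(self.features).to_csv(
            os.path.join(directory, "features.tsv"), sep="\t", index=False
        )
        self.manifest.to_csv(
            os.path.join(directory, "manifest.tsv"), sep="\t", index=False
        )


def _envelope_profile(n_peaks: int, n_carbon: int) -> np.ndarray:
    """Poisson-shaped isotope intensity pattern for a given carbon count."""
    lam = 0.0107 * n_carbon
    ks = np.arange(n_peaks)
    pmf = np.exp(-lam) * lam**ks / np.array([math.factorial(int(k)) for k in ks])
    return pmf / pmf[0]


def _jitter(mz: float, bound_ppm: float, rng: np.random.Generator) -> float:
    if bound_ppm <= 0:
        return mz
    ppm = float(np.clip(rng.normal(0.0, bound_ppm / 3.0), -bound_ppm, bound_ppm))
    return mz * (1.0 + ppm * 1e-6)


def _true_ions(compound: PlantedCompound, lib: ScaffoldLibrary, rng) -> list[tuple[float, float]]:
    """(theoretical m/z, relative intensity) pairs of the planted MS2 ions."""
    out: list[tuple[float, float]] = []
    if compound.params is not None:
        fam = compound.params.subfamily
        profile = _PROFILES[fam]
        for frag in lib.diagnostic_fragments(compound.params):
            lo, hi = profile.get(frag.role, (5, 15))
            out.append((frag.mz, float(rng.uniform(lo, hi))))
        if fam in ("C", "C3"):
            partner = SeriesParams(
                "B" if fam == "C" else "B3", compound.params.m, compound.params.n
            )
            for frag in lib.diagnostic_fragments(partner):
                if frag.role in ("rda_upper", "rda_lower", "rda_upper_ch2n2", "spiroaminal"):
                    out.append((frag.mz, float(rng.uniform(*_C_LEAK_RANGE))))
    elif compound.entry is not None:
        if compound.entry.kind == "crambescidin":
            for marker in lib.crambescidin_markers:
                lo, hi = _MARKER_RANGES.get(marker.role, (20, 60))
                out.append((marker.mz, float(rng.uniform(lo, hi))))
        else:
            out.append((_GUANIDINIUM_MZ, float(rng.uniform(30, 80))))
    elif compound.standard:
        out.extend(_STANDARD_FRAGMENTS.get(compound.name, []))
    return out


def generate_spectrum(
    compound: PlantedCompound,
    cfg: GeneratorConfig,
    rng: Optional[np.random.Generator] = None,
    library: Optional[ScaffoldLibrary] = None,
    feature_id: str = "",
) -> tuple[Feature, Ms2Spectrum]:
    """One planted compound -> (MS1 feature with envelope, MS2 spectrum)."""
    lib = library or default_library()
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    formula = compound.formula(lib)
    mass = monoisotopic_mass(formula)
    z = compound.z
    mz_theor = (mass + z * REPORTED["H"]) / z
    pmz = _jitter(mz_theor, cfg.mass_jitter_ppm, rng)

    peaks = _true_ions(compound, lib, rng)
    is_crambescidin = compound.entry is not None and compound.entry.kind == "crambescidin"
    if (z > 1 and compound.params is not None) or is_crambescidin:
        # HCD spectra of multiply charged precursors retain a residual
        # precursor peak; it also anchors shifted matches in networking
        peaks.append((mz_theor, cfg.residual_precursor))
    true_mzs = [p[0] for p in peaks]
    mzs = [_jitter(m, cfg.mass_jitter_ppm, rng) for m in true_mzs]
    ints = [p[1] for p in peaks]

    for dm, di in _decoys(cfg, rng, true_mzs, pmz):
        mzs.append(dm)
        ints.append(di)

    ints = np.asarray(ints, dtype=float)
    if ints.size and ints.max() > 0:
        ints = ints * (100.0 / ints.max())
    spectrum = Ms2Spectrum(
        precursor_mz=pmz,
        rt=compound.rt,
        mz=np.asarray(mzs),
        intensity=ints,
        precursor_z=z,
        title=feature_id or compound.name,
    )
    intensity = compound.base_intensity or float(rng.lognormal(mean=13.0, sigma=1.0))
    envelope = pmz + np.arange(cfg.isotope_peaks) * (ISOTOPE_SPACING / z)
    feature = Feature(
        mz=pmz,
        rt=compound.rt,
        z=z,
        intensity=intensity,
        envelope=envelope,
        ms2=spectrum,
        feature_id=feature_id or compound.name,
    )
    return feature, spectrum


def _decoys(cfg, rng, true_mzs, precursor_mz):
    if cfg.decoys_per_spectrum <= 0:
        return []
    lo, hi = 60.0, max(61.0, precursor_mz)
    out = []
    windows = [(m - _window(m), m + _window(m)) for m in true_mzs]
    for _ in range(cfg.decoys_per_spectrum):
        if cfg.adversarial_decoys and true_mzs and rng.uniform() < 0.5:
            target = true_mzs[int(rng.integers(len(true_mzs)))]
            mz = target + float(rng.uniform(-0.0015, 0.0015))
        else:
            for _try in range(100):
                mz = float(rng.uniform(lo, hi))
                if not any(a <= mz <= b for a, b in windows):
                    break
        out.append((mz, float(rng.uniform(1, 30))))
    return out


def _window(mz: float) -> float:
    # match the annotator's fragment tolerance: 5 ppm with a 2 mDa floor,
    # doubled for margin so jittered decoys cannot collide with true ions
    return 2 * max(0.002, 5e-6 * mz)


def generate_run(
    manifest: Sequence[PlantedCompound],
    cfg: GeneratorConfig,
    library: Optional[ScaffoldLibrary] = None,
) -> SyntheticRun:
    """Generate a full labelled run from a list of planted compounds.

    Co-eluting compounds of near-identical precursor m/z are allowed (they
    are the isobar stress case) but collected as warnings.
    """
    if not manifest:
        raise ValueError("manifest is empty")
    lib = library or default_library()
    rng = np.random.default_rng(cfg.seed)
    compounds = [c for c in manifest if not c.standard or cfg.include_standards]
    features, spectra, rows = [], [], []
    for i, c in enumerate(compounds):
        fid = f"P{i + 1:03d}"
        feat, spec = generate_spectrum(c, cfg, rng, lib, feature_id=fid)
        features.append(feat)
        spectra.append(spec)
        p = c.params
        rows.append(
            {
                "feature_id": fid,
                "name": c.name,
                "rt": c.rt,
                "z": c.z,
                "mz": round(feat.mz, 6),
                "formula": str(c.formula(lib)),
                "family": p.subfamily if p else ("standard" if c.standard else c.entry.kind),
                "m": p.m if p else "",
                "n": (p.n if p.n is not None else "") if p else "",
                "seed": cfg.seed,
            }
        )
    overlaps = []
    by_key = sorted(zip(features, compounds), key=lambda fc: fc[0].mz)
    for (f1, c1), (f2, c2) in zip(by_key, by_key[1:]):
        if abs(f1.mz - f2.mz) <= 0.02 and abs(f1.rt - f2.rt) <= 0.2:
            msg = f"co-eluting near-isobars: {c1.name} / {c2.name}"
            overlaps.append(msg)
            warnings.warn(msg, stacklevel=2)
    return SyntheticRun(features, spectra, compounds, pd.DataFrame(rows), overlaps)


def extractlike_manifest(
    include_standards: bool = True,
    library: Optional[ScaffoldLibrary] = None,
) -> list[PlantedCompound]:
    """The extract-like manifest: every reference-table compound.

    39 crambescins, 8 crambescidins, small guanidines and (optionally) the
    two internal standards, each at its reported retention time and charge.
    """
    lib = library or default_library()
    ref = load_reference()
    by_formula = {str(e.formula): e for e in lib.closed_list}
    by_name = {e.name: e for e in lib.closed_list}
    out = []
    for _, row in ref.iterrows():
        fam = row["family"]
        if fam == "internal_standard":
            if include_standards:
                out.append(
                    PlantedCompound(
                        name=row["identification"], rt=row["rt"], z=int(row["z"]), standard=True
                    )
                )
            continue
        if fam in SERIES_FAMILIES:
            n = None if pd.isna(row["n"]) else int(row["n"])
            params = SeriesParams(fam, int(row["m"]), n)
            out.append(
                PlantedCompound(
                    name=row["identification"], rt=row["rt"], z=int(row["z"]), params=params
                )
            )
            continue
        ident = row["identification"]
        entry = by_name.get(ident.split(" or ")[0]) or by_formula.get(
            str(parse_formula(row["formula"]))
        )
        if entry is None:
            raise ValueError(f"no closed-list entry for reference row {row['idx']}")
        out.append(
            PlantedCompound(name=ident, rt=row["rt"], z=int(row["z"]), entry=entry)
        )
    return out


def evaluate_run(
    run: SyntheticRun,
    library: Optional[ScaffoldLibrary] = None,
    precursor_tol: float = 5.0,
    fragment_tol: float = 5.0,
) -> dict:
    """Score annotation of a labelled run against its planted truth.

    Returns counts of parametric crambescins recovered rank-1 with the
    correct (subfamily, m, n), and B/C-discrimination outcomes over the
    planted B and C compounds.
    """
    from .dereplicate import annotate_feature

    lib = library or default_library()
    stats = {"series_total": 0, "series_correct": 0, "bc_total": 0, "bc_correct": 0}
    for feat, truth in zip(run.features, run.compounds):
        if truth.params is None:
            continue
        stats["series_total"] += 1
        anns = annotate_feature(feat, lib, precursor_tol, fragment_tol)
        top = anns[0] if anns else None
        ok = top is not None and top.params == truth.params and "bc_undetermined" not in top.flags
        if ok:
            stats["series_correct"] += 1
        if truth.params.subfamily in ("B", "C", "B3", "C3"):
            stats["bc_total"] += 1
            if (
                top is not None
                and top.params is not None
                and top.params.subfamily == truth.params.subfamily
                and "bc_undetermined" not in top.flags
            ):
                stats["bc_correct"] += 1
    return stats
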