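"""Annotation of MS1 features against the guanidine-alkaloid library.

The procedure mirrors how these extracts are dereplicated by hand:

1. the observed m/z and charge give a neutral mass (``Mw = m/z*z - z*M_H``);
2. every library candidate within the precursor tolerance (default ±5 ppm)
   is enumerated — parametric crambescin homologues and the closed
   crambescidin list;
3. candidates are scored by their matched diagnostic MS2 ions, weighted by
   how family-discriminating each ion is; mass error breaks ties.  A
   candidate with no fragment evidence is kept but flagged ``formula_only``;
4. crambescin B and C homologues of the same formula are true isobars and
   are never merged: the relative intensity of the doubly charged
   C-diagnostic ion versus the retro-Diels-Alder pair decides between them
   (the monocyclic C core, with two conjugated double bonds, undergoes the
   retro-Diels-Alder cleavage less readily than the spiro B core);
5. crambescidins additionally require at least two of the three marker ions
   (guanidine core 264.17, its dehydration product 246.16, and the
   pyrrolinium ion 70.0657);
6. A3 isomer pairs sharing a formula are labelled cis (earlier eluting) and
   trans (later) by expected relative polarity.

Fragment matches use a ppm tolerance referenced to the full cation mass,
with a 0.002 Da absolute floor below m/z 400 (printed fragment values are
rounded to 4 decimals, which alone is ~4 ppm at m/z 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import pandas as pd

from .formula import (
    monoisotopic_mass,
    neutral_mass_from_mz,
    round_half_away,
)
from .formula import REPORTED
from .library import (
    CrambescidinEntry,
    FragmentIon,
    ScaffoldLibrary,
    SeriesParams,
    default_library,
)
from .spectra import Feature, Ms2Spectrum

__all__ = [
    "MatchedFragment",
    "Annotation",
    "annotate_feature",
    "annotate_run",
    "discriminate_B_vs_C",
    "annotate_crambescidin",
    "label_isomer_pairs",
    "build_report",
    "fragment_matches",
]

#: Absolute tolerance floor (Da) for fragment matching below this m/z.
FLOOR_DA = 0.002
FLOOR_BELOW_MZ = 400.0


def fragment_matches(
    mz_obs: float, mz_theor: float, z: int, tol_ppm: float = 5.0
) -> bool:
    """Fragment match: ppm on the full cation mass, with an absolute floor."""
    d = mz_obs - mz_theor
    if abs(1e6 * d / (z * mz_theor)) <= tol_ppm:
        return True
    return mz_theor < FLOOR_BELOW_MZ and abs(d) <= FLOOR_DA


@dataclass(frozen=True)
class MatchedFragment:
    mz_obs: float
    intensity: float
    role: str
    mz_theor: float
    z: int
    delta_ppm: float
    weight: float


@dataclass
class Annotation:
    """A ranked identification for one feature."""

    feature: Feature
    name: str
    formula: object  # Formula
    mw_exp: float
    mw_theor: float
    delta_ppm: float
    params: Optional[SeriesParams] = None
    entry: Optional[CrambescidinEntry] = None
    matched: tuple = ()
    score: float = 0.0
    n_rules: int = 0
    rank: int = 0
    flags: tuple = ()
    evidence: dict = field(default_factory=dict)

    @property
    def formula_only(self) -> bool:
        return "formula_only" in self.flags


def _match_spectrum(
    spectrum: Optional[Ms2Spectrum],
    fragments: Sequence[FragmentIon],
    tol_ppm: float,
) -> list[MatchedFragment]:
    if spectrum is None or len(spectrum) == 0:
        return []
    out = []
    for frag in fragments:
        best = None
        for mz, inten in zip(spectrum.mz, spectrum.intensity):
            if fragment_matches(mz, frag.mz, frag.ion.z, tol_ppm):
                if best is None or inten > best[1]:
                    best = (mz, inten)
        if best is not None:
            dppm = 1e6 * (best[0] - frag.mz) / (frag.ion.z * frag.mz)
            out.append(
                MatchedFragment(
                    best[0], best[1], frag.role, frag.mz, frag.ion.z, dppm, frag.weight
                )
            )
    return out


def _sort_key(a: Annotation):
    p = a.params
    return (
        -a.score,
        abs(a.delta_ppm),
        a.n_rules - len(a.matched),
        p.subfamily if p else "~" + a.name,
        p.m if p else 0,
        (p.n or 0) if p else 0,
    )


def annotate_feature(
    feature: Feature,
    library: Optional[ScaffoldLibrary] = None,
    precursor_tol: float = 5.0,
    fragment_tol: float = 5.0,
    bc_theta: float = 0.5,
) -> list[Annotation]:
    """Rank library candidates for one feature.

    Returns annotations in deterministic order: fragment score (weighted),
    then |precursor ppm|, then fewer unmatched rules.  Same-formula B/C
    pairs are reordered by the intensity discriminator when a spectrum is
    available; when neither diagnostic is present both are renamed
    "... B or C ..." and flagged.
    """
    lib = library or default_library()
    if feature.z is None:
        return []
    mw_exp = neutral_mass_from_mz(feature.mz, feature.z)
    anns: list[Annotation] = []

    for params, formula, dppm in lib.enumerate_candidates(mw_exp, precursor_tol):
        frags = lib.diagnostic_fragments(params)
        matched = _match_spectrum(feature.ms2, frags, fragment_tol)
        score = sum(m.weight for m in matched)
        flags = () if matched else ("formula_only",)
        anns.append(
            Annotation(
                feature=feature,
                name=lib.compound_name(params, formula),
                formula=formula,
                mw_exp=mw_exp,
                mw_theor=monoisotopic_mass(formula),
                delta_ppm=dppm,
                params=params,
                matched=tuple(matched),
                score=score,
                n_rules=len(frags),
                flags=flags,
            )
        )

    for entry, dppm in lib.enumerate_closed(mw_exp, precursor_tol):
        anns.append(_annotate_closed(feature, entry, mw_exp, dppm, lib, fragment_tol))

    anns.sort(key=_sort_key)
    anns = _resolve_bc(feature, anns, lib, fragment_tol, bc_theta)
    for i, a in enumerate(anns):
        a.rank = i + 1
    return anns


def _annotate_closed(feature, entry, mw_exp, dppm, lib, fragment_tol) -> Annotation:
    flags: tuple = ()
    score = 0.0
    matched: tuple = ()
    name = entry.name
    n_rules = 0
    if entry.kind == "crambescidin":
        n_rules = len(lib.crambescidin_markers)
        hits = _match_spectrum(feature.ms2, lib.crambescidin_markers, fragment_tol)
        matched = tuple(hits)
        score = float(len(hits))
        if len(hits) < 2:
            flags = ("formula_only",)
            name = f"guanidine-related compound ({entry.formula})"
    else:
        # acids, small crambescins and guanidine-related compounds are
        # identified on formula alone
        flags = ("formula_only",)
    return Annotation(
        feature=feature,
        name=name,
        formula=entry.formula,
        mw_exp=mw_exp,
        mw_theor=monoisotopic_mass(entry.formula),
        delta_ppm=dppm,
        entry=entry,
        matched=matched,
        score=score,
        n_rules=n_rules,
        flags=flags,
    )


def annotate_crambescidin(
    feature: Feature,
    library: Optional[ScaffoldLibrary] = None,
    precursor_tol: float = 5.0,
    fragment_tol: float = 5.0,
) -> Optional[Annotation]:
    """Best closed-list annotation for a feature (marker-ion logic only)."""
    lib = library or default_library()
    if feature.z is None:
        return None
    mw_exp = neutral_mass_from_mz(feature.mz, feature.z)
    hits = lib.enumerate_closed(mw_exp, precursor_tol)
    if not hits:
        return None
    anns = [
        _annotate_closed(feature, e, mw_exp, d, lib, fragment_tol) for e, d in hits
    ]
    anns.sort(key=_sort_key)
    anns[0].rank = 1
    return anns[0]


def discriminate_B_vs_C(
    spectrum: Ms2Spectrum,
    b_params: SeriesParams,
    c_params: SeriesParams,
    library: Optional[ScaffoldLibrary] = None,
    theta: float = 0.5,
    fragment_tol: float = 5.0,
):
    """Choose between isobaric B and C homologues from fragment intensities.

    ``I_C`` is the intensity of the doubly charged C-diagnostic ion, ``I_B``
    the summed intensity of the retro-Diels-Alder pair.  Returns
    ``(choice, ratio, evidence)`` with choice "C" if
    ``I_C/(I_C + I_B) >= theta``, "B" otherwise, and None (undetermined)
    when neither diagnostic is present.
    """
    lib = library or default_library()
    c_frags = [f for f in lib.diagnostic_fragments(c_params) if f.role == "c_diagnostic"]
    b_frags = [
        f
        for f in lib.diagnostic_fragments(b_params)
        if f.role in ("rda_upper", "rda_lower")
    ]
    i_c = sum(m.intensity for m in _match_spectrum(spectrum, c_frags, fragment_tol))
    i_b = sum(m.intensity for m in _match_spectrum(spectrum, b_frags, fragment_tol))
    evidence = {"I_C": i_c, "I_B": i_b}
    if i_c == 0 and i_b == 0:
        return None, None, evidence
    ratio = i_c / (i_c + i_b)
    evidence["ratio"] = ratio
    return ("C" if ratio >= theta else "B"), ratio, evidence


def _bc_partner(subfamily: str) -> Optional[str]:
    return {"B": "C", "C": "B", "B3": "C3", "C3": "B3"}.get(subfamily)


def _resolve_bc(feature, anns, lib, fragment_tol, theta):
    """Reorder same-formula B/C pairs by the intensity discriminator."""
    if feature.ms2 is None:
        return anns
    out = list(anns)
    seen = set()
    for a in anns:
        if a.params is None or a.params.subfamily not in ("B", "C", "B3", "C3"):
            continue
        partner_fam = _bc_partner(a.params.subfamily)
        key = (a.formula, frozenset({a.params.subfamily, partner_fam}), a.params.m)
        if key in seen:
            continue
        partner = next(
            (
                b
                for b in anns
                if b.params is not None
                and b.params.subfamily == partner_fam
                and b.formula == a.formula
                and b.params.m == a.params.m
            ),
            None,
        )
        if partner is None:
            continue
        seen.add(key)
        b_ann = a if a.params.subfamily.startswith("B") else partner
        c_ann = partner if b_ann is a else a
        choice, ratio, evidence = discriminate_B_vs_C(
            feature.ms2, b_ann.params, c_ann.params, lib, theta, fragment_tol
        )
        b_ann.evidence.update(evidence)
        c_ann.evidence.update(evidence)
        if choice is None:
            alt = f"{b_ann.name} or {c_ann.name}"
            b_ann.flags += ("bc_undetermined",)
            c_ann.flags += ("bc_undetermined",)
            b_ann.evidence["alternative"] = alt
            c_ann.evidence["alternative"] = alt
            b_ann.name = _bc_merged_name(b_ann, c_ann, lib)
            c_ann.name = b_ann.name
            continue
        winner, loser = (c_ann, b_ann) if choice == "C" else (b_ann, c_ann)
        # promote the winner directly ahead of the loser
        wi, li = out.index(winner), out.index(loser)
        if wi > li:
            out.insert(li, out.pop(wi))
    return out


def _bc_merged_name(b_ann, c_ann, lib) -> str:
    # "crambescin B1 480" + "crambescin C1 480" -> "crambescin B or C 1 480"
    return f"{b_ann.name} or {c_ann.name.replace('crambescin ', '')}"


def label_isomer_pairs(annotations: Sequence[Annotation]) -> list[Annotation]:
    """Label A3 formula-sharing pairs cis (earlier RT) / trans (later RT).

    Groups of any other size are left unlabelled (with a warning for > 2):
    relative polarity only orders a pair.
    """
    out = list(annotations)
    groups: dict = {}
    for a in out:
        if a.params is not None and a.params.subfamily == "A3":
            groups.setdefault(str(a.formula), []).append(a)
    for formula, group in sorted(groups.items()):
        if len(group) != 2:
            if len(group) > 2:
                warnings.warn(
                    f"{len(group)} co-formula A3 features for {formula}; "
                    "cis/trans labels need exactly two",
                    stacklevel=2,
                )
            continue
        group.sort(key=lambda a: a.feature.rt)
        for a, label in zip(group, ("cis", "trans")):
            if not a.name.endswith(f"({label})"):
                a.name = f"{a.name} ({label})"
            a.flags += (f"isomer_{label}",)
    return out


def annotate_run(
    features: Sequence[Feature],
    library: Optional[ScaffoldLibrary] = None,
    precursor_tol: float = 5.0,
    fragment_tol: float = 5.0,
    bc_theta: float = 0.5,
) -> list[Annotation]:
    """Top annotation per feature across a run, with isomer labelling.

    Internal standards are recognised first (formula match of the [M+H]+
    ion); remaining features go through the full candidate ranking.
    Features with no candidate are skipped.
    """
    lib = library or default_library()
    top: list[Annotation] = []
    for f in sorted(features, key=lambda f: (f.rt, f.mz, f.feature_id)):
        std = _match_standard(f, lib, precursor_tol)
        if std is not None:
            top.append(std)
            continue
        anns = annotate_feature(f, lib, precursor_tol, fragment_tol, bc_theta)
        if anns:
            top.append(anns[0])
    return label_isomer_pairs(top)


def _match_standard(feature, lib, tol_ppm) -> Optional[Annotation]:
    if feature.z not in (None, 1):
        return None
    for std in lib.internal_standards:
        mz_exp = monoisotopic_mass(std["formula"]) + REPORTED["H"]
        dppm = 1e6 * (feature.mz - mz_exp) / mz_exp
        if abs(dppm) <= tol_ppm and abs(feature.rt - std["rt"]) <= 0.5:
            mw_exp = neutral_mass_from_mz(feature.mz, 1)
            return Annotation(
                feature=feature,
                name=std["name"],
                formula=std["formula"],
                mw_exp=mw_exp,
                mw_theor=monoisotopic_mass(std["formula"]),
                delta_ppm=1e6
                * (mw_exp - monoisotopic_mass(std["formula"]))
                / monoisotopic_mass(std["formula"]),
                flags=("internal_standard",),
                rank=1,
            )
    return None


def build_report(annotations: Sequence[Annotation]) -> pd.DataFrame:
    """Tabular report: one row per annotation, in the reporting conventions.

    m/z and molecular weights to 4 decimals, ppm to 2, up to four matched
    MS/MS fragments with charge states.  Row order (retention time, m/z,
    name) and formatting are deterministic, so identical inputs yield
    byte-identical TSVs.
    """
    rows = []
    anns = sorted(annotations, key=lambda a: (a.feature.rt, a.feature.mz, a.name))
    for i, a in enumerate(anns, start=1):
        seen: set = set()
        frags = []
        for m in sorted(a.matched, key=lambda m: -m.intensity):
            if m.mz_obs not in seen:  # one peak can satisfy several rules
                seen.add(m.mz_obs)
                frags.append(m)
        frags = frags[:4]
        frag_txt = "; ".join(f"{round_half_away(m.mz_obs, 4):.4f} ({m.z})" for m in frags)
        rows.append(
            {
                "index": i,
                "mz": f"{round_half_away(a.feature.mz, 4):.4f}",
                "rt": f"{a.feature.rt:.2f}",
                "z": a.feature.z if a.feature.z is not None else "",
                "mw_exp": f"{round_half_away(a.mw_exp, 4):.4f}",
                "formula": str(a.formula),
                "delta_ppm": f"{round_half_away(a.delta_ppm, 2):.2f}",
                "ms2_fragments": frag_txt,
                "identification": a.name,
                "flags": ",".join(a.flags),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "index",
            "mz",
            "rt",
            "z",
            "mw_exp",
            "formula",
            "delta_ppm",
            "ms2_fragments",
            "identification",
            "flags",
        ],
    )
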