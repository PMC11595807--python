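"""Parametric crambescin series and the closed crambescidin list.

Crambescins share a guanidine core (bicyclic for the A sub-family, spiro for
B, monocyclic for C) carrying two alkyl side chains: an upper chain with
(n + 2) methylenes and a lower guanidinoalkyl chain with (m + 2) methylenes.
Homologues therefore live on a small integer grid, and each sub-family's
neutral formula and diagnostic fragment ions are linear in (m, n).  The A3,
B3 and C3 sub-families carry a fixed, four-fold unsaturated upper chain and
are parameterized by m alone.

The library is loaded from a human-editable YAML config (series coefficients,
enumeration ranges, closed crambescidin list, marker ions); see
``data/crambe_scaffolds.yaml`` for the file format.  New scaffolds can be
added without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Optional

import yaml

from .formula import Formula, IonSpecies, monoisotopic_mass, parse_formula

__all__ = [
    "SeriesParams",
    "FragmentIon",
    "FragmentRule",
    "CrambescidinEntry",
    "ScaffoldLibrary",
    "default_library",
    "series_formula",
    "diagnostic_fragments",
    "enumerate_candidates",
    "sidechain_type",
    "compound_name",
]

#: Sub-families whose upper chain is fixed (parameterized by m only).
FIXED_UPPER = frozenset({"A3", "B3", "C3"})


@dataclass(frozen=True)
class SeriesParams:
    """A point on a crambescin homologue grid."""

    subfamily: str
    m: int
    n: Optional[int] = None

    def __post_init__(self):
        if self.m < 2:
            raise ValueError(f"m must be >= 2, got {self.m}")
        if self.subfamily in FIXED_UPPER:
            if self.n is not None:
                raise ValueError(f"{self.subfamily} takes no n parameter")
        else:
            if self.n is None or self.n < 2:
                raise ValueError(f"n must be >= 2 for subfamily {self.subfamily}")


@dataclass(frozen=True)
class FragmentRule:
    """A diagnostic fragment as linear element-count functions of (m, n)."""

    role: str
    z: int
    weight: float
    coeffs: tuple  # ((element, (coef_m, coef_n, const)), ...)

    def formula(self, m: int, n: int = 0) -> Formula:
        counts = {}
        for el, (cm, cn, c0) in self.coeffs:
            c = cm * m + cn * n + c0
            if c < 0:
                raise ValueError(f"rule {self.role} yields negative {el} at m={m}, n={n}")
            counts[el] = c
        return Formula(counts)

    def ion(self, m: int, n: int = 0) -> IonSpecies:
        return IonSpecies(self.formula(m, n), self.z)


@dataclass(frozen=True)
class FragmentIon:
    """A concrete diagnostic ion generated for one (subfamily, m, n)."""

    role: str
    ion: IonSpecies
    weight: float
    mz: float  # theoretical m/z under the reporting mass table


@dataclass(frozen=True)
class CrambescidinEntry:
    """A closed-list compound, named by the integer part of its weight."""

    name: str
    formula: Formula
    kind: str = "crambescidin"
    new: bool = False

    @property
    def nominal_mass(self) -> int:
        return int(monoisotopic_mass(self.formula))


@dataclass
class _SeriesDef:
    display: str
    uses_n: bool
    k_base: int
    h_offset: int
    heteroatoms: dict
    fragments: list = field(default_factory=list)


class ScaffoldLibrary:
    """All scaffolds of the C. crambe guanidine-alkaloid dereplication library."""

    def __init__(self, config: dict):
        enum = config.get("enumeration", {})
        self.m_range = tuple(enum.get("m_range", (2, 8)))
        self.n_range = tuple(enum.get("n_range", (2, 12)))
        self.series: dict[str, _SeriesDef] = {}
        for name, sd in config.get("series", {}).items():
            rules = [
                FragmentRule(
                    role=fr["role"],
                    z=int(fr["z"]),
                    weight=float(fr["weight"]),
                    coeffs=tuple(
                        (el, tuple(int(x) for x in trip))
                        for el, trip in fr["counts"].items()
                    ),
                )
                for fr in sd.get("fragments", [])
            ]
            self.series[name] = _SeriesDef(
                display=sd.get("display", f"crambescin {name}"),
                uses_n=bool(sd["uses_n"]),
                k_base=int(sd["k_base"]),
                h_offset=int(sd["h_offset"]),
                heteroatoms=dict(sd.get("heteroatoms", {})),
                fragments=rules,
            )
        self.closed_list = [
            CrambescidinEntry(
                name=e["name"],
                formula=parse_formula(e["formula"]),
                kind=e.get("kind", "crambescidin"),
                new=bool(e.get("new", False)),
            )
            for e in config.get("closed_list", [])
        ]
        self.crambescidin_markers = [
            FragmentIon(
                role=mk["role"],
                ion=IonSpecies(parse_formula(mk["formula"]), int(mk.get("z", 1))),
                weight=1.0,
                mz=IonSpecies(parse_formula(mk["formula"]), int(mk.get("z", 1))).mz(),
            )
            for mk in config.get("crambescidin_markers", [])
        ]
        self.internal_standards = [
            {"name": s["name"], "formula": parse_formula(s["formula"]), "rt": float(s["rt"])}
            for s in config.get("internal_standards", [])
        ]

    # construction ----------------------------------------------------------
    @classmethod
    def from_yaml(cls, path) -> "ScaffoldLibrary":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "ScaffoldLibrary":
        return default_library()

    # core operations -------------------------------------------------------
    def _check_range(self, p: SeriesParams) -> None:
        lo, hi = self.m_range
        if not lo <= p.m <= hi:
            raise ValueError(f"m={p.m} outside configured range {self.m_range}")
        if p.n is not None:
            lo, hi = self.n_range
            if not lo <= p.n <= hi:
                raise ValueError(f"n={p.n} outside configured range {self.n_range}")

    def series_formula(self, p: SeriesParams) -> Formula:
        """Neutral molecular formula of a homologue-grid point."""
        sd = self.series[p.subfamily]
        self._check_range(p)
        k = sd.k_base + p.m + (p.n if sd.uses_n else 0)
        counts = {"C": k, "H": 2 * k + sd.h_offset}
        counts.update(sd.heteroatoms)
        return Formula(counts)

    def diagnostic_fragments(self, p: SeriesParams) -> list[FragmentIon]:
        """Concrete diagnostic ions of the sub-family at (m, n)."""
        sd = self.series[p.subfamily]
        self._check_range(p)
        n = p.n if sd.uses_n else 0
        out = []
        for rule in sd.fragments:
            ion = rule.ion(p.m, n)
            out.append(FragmentIon(rule.role, ion, rule.weight, ion.mz()))
        return out

    def grid(self):
        """Every in-range (subfamily, m, n) point, in deterministic order."""
        for name in sorted(self.series):
            sd = self.series[name]
            for m in range(self.m_range[0], self.m_range[1] + 1):
                if sd.uses_n:
                    for n in range(self.n_range[0], self.n_range[1] + 1):
                        yield SeriesParams(name, m, n)
                else:
                    yield SeriesParams(name, m)

    def enumerate_candidates(
        self, neutral_mass: float, tol_ppm: float = 5.0
    ) -> list[tuple[SeriesParams, Formula, float]]:
        """All series points whose formula mass is within tol of neutral_mass.

        Returned sorted by |delta ppm| (then subfamily, m, n for determinism).
        Isobaric B/C pairs both appear (same formula).
        """
        if tol_ppm <= 0:
            raise ValueError("tolerance must be positive")
        hits = []
        for p, f, mass in self._grid_masses():
            dppm = 1e6 * (neutral_mass - mass) / mass
            if abs(dppm) <= tol_ppm:
                hits.append((p, f, dppm))
        hits.sort(key=lambda h: (abs(h[2]), h[0].subfamily, h[0].m, h[0].n or 0))
        return hits

    def enumerate_closed(
        self, neutral_mass: float, tol_ppm: float = 5.0
    ) -> list[tuple[CrambescidinEntry, float]]:
        """Closed-list entries within tol of neutral_mass, by |delta ppm|."""
        hits = []
        for e in self.closed_list:
            mass = monoisotopic_mass(e.formula)
            dppm = 1e6 * (neutral_mass - mass) / mass
            if abs(dppm) <= tol_ppm:
                hits.append((e, dppm))
        hits.sort(key=lambda h: (abs(h[1]), h[0].name))
        return hits

    @lru_cache(maxsize=1)
    def _grid_masses(self):
        return tuple(
            (p, f, monoisotopic_mass(f))
            for p in self.grid()
            for f in (self.series_formula(p),)
        )

    def __hash__(self):  # lru_cache on the bound method needs a hashable self
        return id(self)

    def __eq__(self, other):
        return self is other

    # naming ----------------------------------------------------------------
    @staticmethod
    def sidechain_type(p: SeriesParams) -> str:
        """Side-chain moiety label: "1", "2", "3" or "homologue".

        Type 3 is the fixed unsaturated upper chain; type 1 the classical
        n = 6 chain with m in 4..6; type 2 the m = 2 guanidinoalkyl chain.
        Everything else is a newly observed homologue.
        """
        if p.subfamily in FIXED_UPPER:
            return "3"
        if p.m == 2:
            return "2"
        if p.n == 6 and p.m in (4, 5, 6):
            return "1"
        return "homologue"

    def compound_name(self, p: SeriesParams, f: Optional[Formula] = None) -> str:
        """Conventional name: sub-family type followed by the molecular weight.

        The weight is the integer part of the monoisotopic mass (every
        reported guanidine-alkaloid name, crambescidin 800 and 875 included,
        truncates rather than rounds).
        """
        if f is None:
            f = self.series_formula(p)
        nominal = math.floor(monoisotopic_mass(f))
        base = "didehydrocrambescin" if p.subfamily.startswith("didehydro") else "crambescin"
        letter = p.subfamily.replace("didehydro", "")[0]
        t = self.sidechain_type(p)
        if t == "homologue":
            return f"{base} {letter} {nominal} homologue (m = {p.m}, n = {p.n})"
        return f"{base} {letter}{t} {nominal}"


@lru_cache(maxsize=1)
def default_library() -> ScaffoldLibrary:
    ref = resources.files("crambederep.data") / "crambe_scaffolds.yaml"
    with ref.open() as fh:
        return ScaffoldLibrary(yaml.safe_load(fh))


# Module-level conveniences bound to the default library ---------------------

def series_formula(p: SeriesParams) -> Formula:
    return default_library().series_formula(p)


def diagnostic_fragments(p: SeriesParams) -> list[FragmentIon]:
    return default_library().diagnostic_fragments(p)


def enumerate_candidates(neutral_mass: float, tol_ppm: float = 5.0):
    return default_library().enumerate_candidates(neutral_mass, tol_ppm)


def sidechain_type(p: SeriesParams) -> str:
    return ScaffoldLibrary.sidechain_type(p)


def compound_name(p: SeriesParams, f: Optional[Formula] = None) -> str:
    return default_library().compound_name(p, f)
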