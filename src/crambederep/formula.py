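"""Elemental-formula arithmetic and exact-mass / ppm conventions.

All downstream annotation logic reduces to a handful of conventions that this
module pins down:

* a *mass table* maps element symbols to monoisotopic masses.  The default
  ``REPORTED`` table uses the four-decimal values conventionally used when
  reporting guanidine-alkaloid annotations (H 1.0078, C 12, N 14.0031,
  O 15.9949); a ``PRECISE`` table with full-precision monoisotopic masses is
  available for instrument-grade work.
* protonation adds exactly one hydrogen mass per charge; the electron mass is
  ignored throughout, so the neutral (molecular-weight) scale is
  ``Mw = m/z * z - z * M_H``.
* relative mass errors on the neutral scale are
  ``1e6 * (Mw_obs - Mw_theor) / Mw_theor``.
* relative mass errors for *fragment ions* are referenced to the full cation
  mass, ``1e6 * (mz_obs - mz_theor) / (z * mz_theor)``.  For singly charged
  ions this is the ordinary ppm on m/z; for multiply charged ions it keeps the
  error on the mass scale of the whole cation, which is the convention under
  which the reported fragment errors of crambescin spectra are reproducible.

Reported numbers are rounded half-away-from-zero: m/z and masses to 4
decimals, ppm to 2 decimals.
"""

from __future__ import annotations

import re
from collections.abc import Mapping
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "Formula",
    "IonSpecies",
    "MassMeasurement",
    "REPORTED",
    "PRECISE",
    "MASS_TABLES",
    "parse_formula",
    "monoisotopic_mass",
    "rdbe",
    "neutral_mass_from_mz",
    "delta_ppm_neutral",
    "theoretical_mz",
    "delta_ppm_fragment",
    "round_half_away",
]

#: Four-decimal monoisotopic masses used for all reported numbers.
REPORTED: Mapping[str, float] = {
    "H": 1.0078,
    "C": 12.0,
    "N": 14.0031,
    "O": 15.9949,
}

#: CODATA/IUPAC monoisotopic masses of the light isotopes.
PRECISE: Mapping[str, float] = {
    "H": 1.00782503207,
    "C": 12.0,
    "N": 14.0030740048,
    "O": 15.9949146196,
}

MASS_TABLES: Mapping[str, Mapping[str, float]] = {"reported": REPORTED, "precise": PRECISE}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def round_half_away(x: float, ndigits: int) -> float:
    """Round with ties going away from zero (the convention of reported tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class Formula(Mapping):
    """An elemental composition: an immutable element -> count mapping.

    Counts are non-negative integers; zero-count elements are dropped.
    Supports element-wise ``+`` and ``-`` (subtraction below zero raises).
    """

    __slots__ = ("_counts",)

    def __init__(self, counts: Mapping[str, int] | None = None, **kw: int):
        merged: dict[str, int] = {}
        for src in (counts or {}), kw:
            for el, c in src.items():
                merged[el] = merged.get(el, 0) + int(c)
        for el, c in merged.items():
            if c < 0:
                raise ValueError(f"negative count for element {el}: {c}")
        self._counts = {el: c for el, c in sorted(merged.items()) if c > 0}

    # Mapping interface -----------------------------------------------------
    def __getitem__(self, el: str) -> int:
        return self._counts.get(el, 0)

    def __iter__(self):
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    def __contains__(self, el) -> bool:
        return el in self._counts

    # arithmetic ------------------------------------------------------------
    def __add__(self, other: "Formula") -> "Formula":
        els = set(self._counts) | set(other)
        return Formula({el: self[el] + other[el] for el in els})

    def __sub__(self, other: "Formula") -> "Formula":
        els = set(self._counts) | set(other)
        out = {}
        for el in els:
            c = self[el] - other[el]
            if c < 0:
                raise ValueError(
                    f"subtraction yields negative {el} count ({self[el]} - {other[el]})"
                )
            out[el] = c
        return Formula(out)

    def __eq__(self, other) -> bool:
        if isinstance(other, Formula):
            return self._counts == other._counts
        if isinstance(other, Mapping):
            return self._counts == {k: v for k, v in other.items() if v}
        return NotImplemented

    def __hash__(self) -> int:
        return hash(tuple(self._counts.items()))

    def __bool__(self) -> bool:
        return bool(self._counts)

    def __repr__(self) -> str:
        return f"Formula({self!s})"

    def __str__(self) -> str:
        # C, H first then remaining elements alphabetically (Hill order).
        parts = []
        for el in ("C", "H"):
            c = self[el]
            if c:
                parts.append(el + (str(c) if c != 1 else ""))
        for el, c in self._counts.items():
            if el in ("C", "H"):
                continue
            parts.append(el + (str(c) if c != 1 else ""))
        return "".join(parts)


def parse_formula(text: str) -> Formula:
    """Parse a molecular formula string such as ``"C24H44N6O2"``.

    An omitted count means 1.  Element symbols may appear in any order and
    repeat (counts accumulate).  Raises ``ValueError`` on malformed input.
    """
    if not text or not text.strip():
        raise ValueError("empty formula string")
    text = text.strip()
    pos = 0
    counts: dict[str, int] = {}
    for match in _FORMULA_TOKEN.finditer(text):
        if match.start() != pos:
            raise ValueError(f"malformed formula {text!r} at position {pos}")
        if not match.group(0):
            break
        el, num = match.group(1), match.group(2)
        counts[el] = counts.get(el, 0) + (int(num) if num else 1)
        pos = match.end()
    if pos != len(text):
        raise ValueError(f"malformed formula {text!r} at position {pos}")
    return Formula(counts)


def _as_formula(f: "Formula | str | Mapping[str, int]") -> Formula:
    if isinstance(f, Formula):
        return f
    if isinstance(f, str):
        return parse_formula(f)
    return Formula(f)


def _table(t: "Mapping[str, float] | str") -> Mapping[str, float]:
    if isinstance(t, str):
        try:
            return MASS_TABLES[t]
        except KeyError:
            raise KeyError(f"unknown mass table {t!r}; choose from {sorted(MASS_TABLES)}")
    return t


def monoisotopic_mass(f, table="reported") -> float:
    """Monoisotopic mass in Da: sum of count x element mass over the table."""
    f = _as_formula(f)
    t = _table(table)
    total = 0.0
    for el, c in f.items():
        if el not in t:
            raise KeyError(f"element {el} missing from mass table")
        total += c * t[el]
    return total


def rdbe(f) -> float:
    """Rings plus double-bond equivalents: C - H/2 + N/2 + 1 (O contributes 0)."""
    f = _as_formula(f)
    return f["C"] - f["H"] / 2 + f["N"] / 2 + 1


def neutral_mass_from_mz(mz_obs: float, z: int, table="reported") -> float:
    """Neutral (molecular-weight scale) mass from an observed m/z of [M+zH]z+."""
    if z < 1:
        raise ValueError(f"charge must be >= 1, got {z}")
    t = _table(table)
    return mz_obs * z - z * t["H"]


def delta_ppm_neutral(mw_exp: float, mw_theor: float) -> float:
    """Relative mass error in ppm on the neutral-mass scale."""
    if mw_theor <= 0:
        raise ValueError("theoretical mass must be positive")
    return 1e6 * (mw_exp - mw_theor) / mw_theor


@dataclass(frozen=True)
class IonSpecies:
    """A cation: full composition of the charged species plus its charge.

    ``cation_formula`` includes any added protons, e.g. [M+2H]2+ carries the
    two extra hydrogens explicitly.
    """

    cation_formula: Formula
    z: int = 1

    def __post_init__(self):
        if self.z < 1:
            raise ValueError(f"charge must be >= 1, got {self.z}")
        object.__setattr__(self, "cation_formula", _as_formula(self.cation_formula))

    def mz(self, table="reported") -> float:
        return theoretical_mz(self, table)

    def __str__(self) -> str:
        zs = "+" if self.z == 1 else f"{self.z}+"
        return f"[{self.cation_formula}]{zs}"


def theoretical_mz(ion: IonSpecies, table="reported") -> float:
    """Theoretical m/z: cation mass / z, with no electron-mass correction."""
    return monoisotopic_mass(ion.cation_formula, table) / ion.z


def delta_ppm_fragment(mz_obs: float, ion: IonSpecies, table="reported") -> float:
    """Fragment mass error in ppm referenced to the full cation mass.

    ``1e6 * (mz_obs - mz_theor) / (z * mz_theor)``.  For z = 1 this reduces to
    the ordinary ppm error on m/z.
    """
    mz_theor = theoretical_mz(ion, table)
    return 1e6 * (mz_obs - mz_theor) / (ion.z * mz_theor)


@dataclass(frozen=True)
class MassMeasurement:
    """A precursor mass measurement reduced to the reporting conventions."""

    mz_obs: float
    z: int
    mw_exp: float
    mw_theor: float
    delta_ppm: float

    @classmethod
    def from_observation(cls, mz_obs: float, z: int, formula, table="reported"):
        mw_exp = neutral_mass_from_mz(mz_obs, z, table)
        mw_theor = monoisotopic_mass(formula, table)
        return cls(mz_obs, z, mw_exp, mw_theor, delta_ppm_neutral(mw_exp, mw_theor))

    @property
    def mw_exp_rounded(self) -> float:
        return round_half_away(self.mw_exp, 4)

    @property
    def delta_ppm_rounded(self) -> float:
        return round_half_away(self.delta_ppm, 2)
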