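"""Feedstock characterization: ultimate/proximate analysis and empirical formulas.

An *ultimate analysis* gives the elemental mass composition (C, H, N, S, O) of
a dried substrate; a *proximate analysis* partitions the same material into
moisture, volatile solids, ash and fixed carbon.  Both are the standard inputs
for waste-to-energy calculations: the elemental composition feeds the
Buswell-Boyle gas stoichiometry and the Dulong heating-value correlation,
while the volatile-solid fraction normalizes yields.

This module parses the delimited tables these assays are reported as,
validates closure (percentages must sum to ~100%), and converts a mass
composition into an empirical molecular formula C_a H_b O_c N_d S_e on a
chosen basis mass.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Mapping

import pandas as pd

from .errors import ClosureError, FeedstockValidationError

__all__ = [
    "ATOMIC_WEIGHTS",
    "UltimateAnalysis",
    "ProximateAnalysis",
    "ElementalFormula",
    "load_ultimate_analysis",
    "load_proximate_analysis",
    "to_empirical_formula",
]

#: 4-decimal IUPAC standard atomic weights (g/mol), fixed for reproducibility.
ATOMIC_WEIGHTS: Mapping[str, float] = {
    "C": 12.011,
    "H": 1.008,
    "O": 15.999,
    "N": 14.007,
    "S": 32.06,
}

_ELEMENTS = ("C", "H", "N", "S", "O")
_PROXIMATE_COMPONENTS = ("moisture", "volatile_solid", "ash", "fixed_carbon", "sulfur")


@dataclass(frozen=True)
class UltimateAnalysis:
    """Dry-basis elemental mass fractions of a feedstock.

    Fractions are dimensionless (0-1).  ``basis`` records whether the
    composition is per dry mass (``"dry"``) or per dry-ash-free mass
    (``"daf"``); the arithmetic downstream is identical, only the
    denominator of reported yields changes.
    """

    c_frac: float
    h_frac: float
    n_frac: float
    s_frac: float
    o_frac: float
    basis: str = "dry"

    def __post_init__(self) -> None:
        for name in ("c_frac", "h_frac", "n_frac", "s_frac", "o_frac"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0) or v != v:
                raise FeedstockValidationError(f"{name}={v!r} outside [0, 1]")
        if self.c_frac <= 0.0:
            raise FeedstockValidationError("carbon fraction must be positive")
        s = self.fraction_sum
        if not (0.95 <= s <= 1.0 + 1e-9):
            raise ClosureError(
                f"element fractions sum to {s:.4f}; expected closure in [0.95, 1.00]"
            )
        if self.basis not in ("dry", "daf"):
            raise FeedstockValidationError(f"unknown basis {self.basis!r}")

    @property
    def fraction_sum(self) -> float:
        return self.c_frac + self.h_frac + self.n_frac + self.s_frac + self.o_frac

    def fractions(self) -> dict[str, float]:
        """Mass fractions keyed by element symbol."""
        return {
            "C": self.c_frac,
            "H": self.h_frac,
            "N": self.n_frac,
            "S": self.s_frac,
            "O": self.o_frac,
        }

    @classmethod
    def from_percentages(cls, percents: Mapping[str, float], basis: str = "dry") -> "UltimateAnalysis":
        """Build from an ``{element: percent}`` mapping (percent of dry mass).

        Elements absent from the mapping default to 0% (closure still has to
        hold, so an incomplete assay that does not sum to ~100% is rejected);
        carbon is mandatory.  Unknown element symbols are an error rather
        than being silently dropped.
        """
        unknown = sorted(set(percents) - set(_ELEMENTS))
        if unknown:
            raise FeedstockValidationError(
                f"unknown element row(s): {', '.join(unknown)}; "
                f"expected among {', '.join(_ELEMENTS)}"
            )
        if "C" not in percents:
            raise FeedstockValidationError("missing element row: C")
        return cls(
            c_frac=percents["C"] / 100.0,
            h_frac=percents.get("H", 0.0) / 100.0,
            n_frac=percents.get("N", 0.0) / 100.0,
            s_frac=percents.get("S", 0.0) / 100.0,
            o_frac=percents.get("O", 0.0) / 100.0,
            basis=basis,
        )


@dataclass(frozen=True)
class ProximateAnalysis:
    """Proximate characterization, in percent as conventionally printed.

    Moisture is a percentage of the as-received (wet) mass; volatile solid,
    ash and fixed carbon are percentages of dry mass.  The four closure
    components are allowed to sum anywhere in [95, 105] because published
    tables frequently do not close exactly.
    """

    moisture: float
    volatile_solid: float
    ash: float
    fixed_carbon: float
    sulfur: float = 0.0

    def __post_init__(self) -> None:
        for name in _PROXIMATE_COMPONENTS:
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0) or v != v:
                raise FeedstockValidationError(f"{name}={v!r} outside [0, 100]")
        s = self.moisture + self.volatile_solid + self.ash + self.fixed_carbon
        if not (95.0 <= s <= 105.0):
            raise ClosureError(
                f"moisture+VS+ash+fixed_carbon = {s:.2f}%; expected within [95, 105]"
            )

    @property
    def volatile_solid_frac(self) -> float:
        """Volatile solids as a fraction of dry mass."""
        return self.volatile_solid / 100.0

    @property
    def moisture_frac(self) -> float:
        return self.moisture / 100.0


@dataclass(frozen=True)
class ElementalFormula:
    """Empirical formula C_a H_b O_c N_d S_e per ``basis_mass`` grams.

    ``a``..``e`` are moles of C, H, O, N, S respectively.  Reconstructing
    mass from moles and atomic weights must recover
    ``basis_mass * (sum of input fractions)`` within 0.1%.
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    basis_mass: float = 100.0

    def __post_init__(self) -> None:
        if self.basis_mass <= 0:
            raise FeedstockValidationError("basis_mass must be positive")
        for name in "abcde":
            if getattr(self, name) < 0:
                raise FeedstockValidationError(f"moles {name} must be non-negative")
        if self.a <= 0:
            raise FeedstockValidationError("carbon moles must be positive")

    @property
    def molar_mass(self) -> float:
        """Mass (g) represented by the formula = sum of moles x atomic weight."""
        w = ATOMIC_WEIGHTS
        return (
            self.a * w["C"]
            + self.b * w["H"]
            + self.c * w["O"]
            + self.d * w["N"]
            + self.e * w["S"]
        )

    def mass_fractions(self) -> dict[str, float]:
        """Recover elemental mass fractions of the basis mass (round trip)."""
        w = ATOMIC_WEIGHTS
        m = self.basis_mass
        return {
            "C": self.a * w["C"] / m,
            "H": self.b * w["H"] / m,
            "O": self.c * w["O"] / m,
            "N": self.d * w["N"] / m,
            "S": self.e * w["S"] / m,
        }

    def scaled(self, new_basis_mass: float) -> "ElementalFormula":
        """Same composition re-expressed on a different basis mass (linear)."""
        f = new_basis_mass / self.basis_mass
        return replace(
            self,
            a=self.a * f,
            b=self.b * f,
            c=self.c * f,
            d=self.d * f,
            e=self.e * f,
            basis_mass=new_basis_mass,
        )

    def __str__(self) -> str:
        return (
            f"C{self.a:.4g}H{self.b:.4g}O{self.c:.4g}"
            f"N{self.d:.4g}S{self.e:.4g} (per {self.basis_mass:g} g)"
        )


def _read_two_column_table(source, key_col: str, val_col: str) -> dict[str, float]:
    """Read CSV path/buffer, JSON path, dict, or DataFrame into a mapping."""
    if isinstance(source, Mapping):
        return {str(k): float(v) for k, v in source.items()}
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        p = Path(source) if isinstance(source, (str, Path)) else None
        if p is not None and p.suffix.lower() == ".json":
            with open(p) as fh:
                return {str(k): float(v) for k, v in json.load(fh).items()}
        df = pd.read_csv(source)
    df = df.rename(columns=str.strip)
    if key_col not in df.columns or val_col not in df.columns:
        raise FeedstockValidationError(
            f"table must have columns '{key_col}' and '{val_col}'; got {list(df.columns)}"
        )
    out: dict[str, float] = {}
    for _, row in df.iterrows():
        out[str(row[key_col]).strip()] = float(row[val_col])
    return out


def load_ultimate_analysis(source, basis: str = "dry") -> UltimateAnalysis:
    """Load an ultimate analysis from a table with ``element,percent`` columns.

    ``source`` may be a CSV/JSON path, an open buffer, a DataFrame, or an
    ``{element: percent}`` mapping.  Raises :class:`FeedstockValidationError`
    naming any missing element, and :class:`ClosureError` when the
    percentages sum outside [95, 100]%.
    """
    percents = _read_two_column_table(source, "element", "percent")
    return UltimateAnalysis.from_percentages(percents, basis=basis)


def load_proximate_analysis(source) -> ProximateAnalysis:
    """Load a proximate analysis from a table with ``component,percent`` columns."""
    vals = _read_two_column_table(source, "component", "percent")
    missing = [c for c in _PROXIMATE_COMPONENTS[:4] if c not in vals]
    if missing:
        raise FeedstockValidationError(
            f"missing component row(s): {', '.join(missing)}"
        )
    return ProximateAnalysis(
        moisture=vals["moisture"],
        volatile_solid=vals["volatile_solid"],
        ash=vals["ash"],
        fixed_carbon=vals["fixed_carbon"],
        sulfur=vals.get("sulfur", 0.0),
    )


def to_empirical_formula(ua: UltimateAnalysis, basis_mass: float = 100.0) -> ElementalFormula:
    """Convert mass fractions to moles of each element per ``basis_mass`` g.

    a = m*C/12.011, b = m*H/1.008, c = m*O/15.999, d = m*N/14.007,
    e = m*S/32.06 with m the basis mass in grams.
    """
    if basis_mass <= 0:
        raise FeedstockValidationError("basis_mass must be positive")
    w = ATOMIC_WEIGHTS
    return ElementalFormula(
        a=basis_mass * ua.c_frac / w["C"],
        b=basis_mass * ua.h_frac / w["H"],
        c=basis_mass * ua.o_frac / w["O"],
        d=basis_mass * ua.n_frac / w["N"],
        e=basis_mass * ua.s_frac / w["S"],
        basis_mass=basis_mass,
    )
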