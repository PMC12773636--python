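"""Elemental bookkeeping for fermentation balances.

Every balance computed by this package reduces each compound to two numbers:
its carbon count and its *degree of reduction* -- the available electrons per
mole that complete oxidation to CO2 and H2O would release,

    gamma = 4*C + 1*H - 2*O

Nitrogen is weighted zero; none of the fermentation substrates or products
handled here contain it.  Organic acids are registered in their neutral
(fully protonated) forms so that element and electron balances stay
charge-free, matching the molar bookkeeping convention of anaerobic
fermentation studies.  Water carries gamma 0 and CO2 carries gamma 0, so a
correctly balanced fermentation conserves gamma on both sides exactly.

Biomass is deliberately *not* a registered compound: recovery percentages
below 100% in growing cultures reflect carbon and electrons diverted into
cell material that this module does not attempt to model.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping

import pandas as pd

__all__ = [
    "Compound",
    "CompoundRegistry",
    "DEFAULT_REGISTRY",
    "parse_formula",
    "format_formula",
    "degree_of_reduction",
    "carbon_count",
]

# gamma weights per atom; N present for completeness, weighted zero
_GAMMA_WEIGHTS = {"C": 4.0, "H": 1.0, "O": -2.0, "N": 0.0}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> Dict[str, int]:
    """Parse a Hill-like formula string such as ``"C6H12O6"`` into an
    element -> count mapping.

    Raises
    ------
    ValueError
        If the string contains anything but element symbols followed by
        optional counts, or an element outside C/H/O/N.
    """
    counts: Dict[str, int] = {}
    pos = 0
    for match in _FORMULA_TOKEN.finditer(formula):
        if match.start() != pos:
            raise ValueError(f"malformed formula {formula!r} at position {pos}")
        if not match.group(0):
            break
        element = match.group(1)
        if element not in _GAMMA_WEIGHTS:
            raise ValueError(f"unknown element {element!r} in formula {formula!r}")
        n = int(match.group(2)) if match.group(2) else 1
        counts[element] = counts.get(element, 0) + n
        pos = match.end()
        if pos == len(formula):
            break
    if pos != len(formula) or not counts:
        raise ValueError(f"malformed formula {formula!r}")
    return counts


def format_formula(formula: Mapping[str, int]) -> str:
    """Render an element map in Hill-like order (C, H, then alphabetic)."""
    order = ["C", "H"] + sorted(k for k in formula if k not in ("C", "H"))
    parts = []
    for el in order:
        n = formula.get(el, 0)
        if n == 0:
            continue
        parts.append(el if n == 1 else f"{el}{n}")
    return "".join(parts)


def _as_counts(formula: Mapping[str, int] | str) -> Mapping[str, int]:
    if isinstance(formula, str):
        return parse_formula(formula)
    for element in formula:
        if element not in _GAMMA_WEIGHTS:
            raise ValueError(f"unknown element {element!r}")
    return formula


def degree_of_reduction(formula: Mapping[str, int] | str) -> float:
    """Available electrons per mole: ``4*C + H - 2*O`` (N weighted zero)."""
    counts = _as_counts(formula)
    return float(sum(_GAMMA_WEIGHTS[el] * n for el, n in counts.items()))


def carbon_count(formula: Mapping[str, int] | str) -> int:
    """Number of carbon atoms in the formula."""
    return int(_as_counts(formula).get("C", 0))


@dataclass(frozen=True)
class Compound:
    """A named compound with its elemental composition.

    ``carbons`` and ``gamma`` are derived from the formula at construction
    and kept as plain fields so a registry row serializes trivially.
    """

    name: str
    formula: Mapping[str, int]
    carbons: int = field(init=False)
    gamma: float = field(init=False)

    def __post_init__(self) -> None:
        counts = dict(_as_counts(self.formula))
        object.__setattr__(self, "formula", counts)
        object.__setattr__(self, "carbons", carbon_count(counts))
        object.__setattr__(self, "gamma", degree_of_reduction(counts))
        if self.gamma < 0:
            raise ValueError(f"negative degree of reduction for {self.name}")

    @property
    def formula_string(self) -> str:
        return format_formula(self.formula)


class CompoundRegistry:
    """Mapping of compound name -> :class:`Compound`.

    Lookup is exact first, then case-insensitive, so CSV channel headers like
    ``h2`` resolve against the canonical ``H2`` entry.
    """

    def __init__(self, compounds: Mapping[str, str] | None = None) -> None:
        self._compounds: Dict[str, Compound] = {}
        if compounds:
            for name, formula in compounds.items():
                self.register(name, formula)

    def register(self, name: str, formula: Mapping[str, int] | str) -> Compound:
        compound = Compound(name, _as_counts(formula))
        self._compounds[name] = compound
        return compound

    def __getitem__(self, name: str) -> Compound:
        if name in self._compounds:
            return self._compounds[name]
        lowered = name.lower()
        for key, compound in self._compounds.items():
            if key.lower() == lowered:
                return compound
        raise KeyError(f"compound {name!r} is not registered")

    def __contains__(self, name: str) -> bool:
        try:
            self[name]
        except KeyError:
            return False
        return True

    def __iter__(self) -> Iterator[Compound]:
        return iter(self._compounds.values())

    def __len__(self) -> int:
        return len(self._compounds)

    @property
    def names(self) -> list[str]:
        return list(self._compounds)

    def to_table(self) -> pd.DataFrame:
        """Registry as a plain table (name, formula, carbons, gamma)."""
        rows = [
            {
                "name": c.name,
                "formula": c.formula_string,
                "carbons": c.carbons,
                "gamma": c.gamma,
            }
            for c in self
        ]
        return pd.DataFrame(rows, columns=["name", "formula", "carbons", "gamma"])


#: Compounds the analysis touches: the eight growth sugars, the five
#: fermentation products, the C1 gases, and water.
DEFAULT_REGISTRY = CompoundRegistry(
    {
        "glucose": "C6H12O6",
        "sorbitol": "C6H14O6",
        "xylose": "C5H10O5",
        "arabinose": "C5H10O5",
        "sucrose": "C12H22O11",
        "trehalose": "C12H22O11",
        "maltose": "C12H22O11",
        "raffinose": "C18H32O16",
        "acetate": "C2H4O2",
        "succinate": "C4H6O4",
        "lactate": "C3H6O3",
        "formate": "CH2O2",
        "H2": "H2",
        "CO": "CO",
        "CO2": "CO2",
        "water": "H2O",
    }
)
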