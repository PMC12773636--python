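"""Molar fermentation balances and carbon / electron recovery.

Given endpoint substrate consumption and product formation (mM), this module
computes molar yields (mol product per mol primary substrate), the carbon
recovery

    100 * sum_products(C_p * mM_p) / sum_substrates(C_s * mM_s),

per-product carbon fractions, and the degree-of-reduction electron recovery

    100 * sum_products(gamma_p * mM_p) / sum_substrates(gamma_s * mM_s),

with H2 counted among the products and CO, when supplied, among the
substrates.  CO2 (abundant in the bicarbonate-buffered cultures) is excluded
from both sides by default; net CO2 fixation into succinate and
Wood-Ljungdahl acetate therefore shows up as a carbon recovery above 100%.
Passing ``include_co2=True`` restores exact closure for element-balanced
synthetic data.

A note on transient intermediates: formate is produced early and later
re-consumed under mixotrophic conditions, so a "product" channel can end
below its peak or even below its start.  Endpoint deltas clamp such
negatives at zero (with a warning collected on the balance); the alternative
``mode="peak"`` reports the transient maximum instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

from .compounds import DEFAULT_REGISTRY, CompoundRegistry
from .timecourse import TimeCourse, summarize

__all__ = [
    "FermentationBalance",
    "molar_yields",
    "carbon_recovery",
    "carbon_fractions",
    "electron_recovery",
    "render_balance_equation",
    "endpoint_deltas",
    "compute_balance",
]

#: canonical product order of the balance equations
_CANONICAL_ORDER = ["acetate", "succinate", "lactate", "formate", "H2"]


def molar_yields(
    consumed: Mapping[str, float],
    formed: Mapping[str, float],
    primary: str,
) -> Dict[str, float]:
    """Mol product formed per mol of the primary substrate consumed."""
    if primary not in consumed or consumed[primary] <= 0:
        raise ValueError(f"no consumption of primary substrate {primary!r}")
    base = consumed[primary]
    return {p: delta / base for p, delta in formed.items()}


def _weighted_sum(amounts: Mapping[str, float], registry: CompoundRegistry, attr: str, include_co2: bool) -> float:
    total = 0.0
    for name, mm in amounts.items():
        compound = registry[name]  # KeyError -> unregistered compound
        if not include_co2 and compound.name in ("CO2", "water"):
            continue
        total += getattr(compound, attr) * mm
    return total


def carbon_recovery(
    consumed: Mapping[str, float],
    formed: Mapping[str, float],
    registry: CompoundRegistry = DEFAULT_REGISTRY,
    include_co2: bool = False,
) -> float:
    """Percent of consumed substrate carbon recovered in the listed products."""
    denom = _weighted_sum(consumed, registry, "carbons", include_co2)
    if denom == 0:
        raise ValueError("no carbon-bearing substrate consumed")
    return 100.0 * _weighted_sum(formed, registry, "carbons", include_co2) / denom


def electron_recovery(
    consumed: Mapping[str, float],
    formed: Mapping[str, float],
    registry: CompoundRegistry = DEFAULT_REGISTRY,
    include_co2: bool = False,
) -> float:
    """Percent of available electrons (degree of reduction) recovered."""
    denom = _weighted_sum(consumed, registry, "gamma", include_co2)
    if denom == 0:
        raise ValueError("substrates carry no available electrons")
    return 100.0 * _weighted_sum(formed, registry, "gamma", include_co2) / denom


def carbon_fractions(
    yields: Mapping[str, float],
    primary: str,
    registry: CompoundRegistry = DEFAULT_REGISTRY,
) -> Dict[str, float]:
    """Percent of substrate carbon ending in each product: 100*y_p*C_p/C_s."""
    c_primary = registry[primary].carbons
    if c_primary <= 0:
        raise ValueError(f"primary substrate {primary!r} carries no carbon")
    out = {}
    for name, y in yields.items():
        c = registry[name].carbons
        if c == 0:
            continue
        out[name] = 100.0 * y * c / c_primary
    return out


def render_balance_equation(
    yields: Mapping[str, float],
    primary: str = "glucose",
    precision: int = 2,
    include_zero: Sequence[str] = (),
    co_substrates: Optional[Mapping[str, float]] = None,
) -> str:
    """Render a fermentation balance like ``1glucose→1.12acetate+...``.

    Products appear in the canonical order acetate, succinate, lactate,
    formate, H2, then any others alphabetically.  Coefficients are rounded to
    ``precision`` decimals; products rounding to zero are dropped unless
    named in ``include_zero`` (some balances deliberately print
    ``0.00formate`` to emphasise its absence).  ``co_substrates`` adds
    co-consumed species on the left, e.g. ``{"CO": 1.57}``.
    """
    lhs = f"1{primary}"
    if co_substrates:
        for name in sorted(co_substrates):
            lhs += f"+{co_substrates[name]:.{precision}f}{name}"
    ordered = [p for p in _CANONICAL_ORDER if p in yields]
    ordered += sorted(p for p in yields if p not in _CANONICAL_ORDER)
    terms = []
    for name in ordered:
        coeff = round(yields[name], precision)
        if coeff == 0 and name not in include_zero:
            continue
        terms.append(f"{coeff:.{precision}f}{name}")
    return f"{lhs}→{'+'.join(terms)}"


@dataclass
class FermentationBalance:
    """Full balance of one fermentation: deltas, yields and recoveries."""

    primary: str
    substrates_consumed: Dict[str, float]  # mM, > 0 for consumed
    products_formed: Dict[str, float]  # mM, > 0 for formed
    yields: Dict[str, float]  # mol per mol primary substrate
    carbon_recovery: float  # percent
    carbon_fractions: Dict[str, float]  # percent of substrate carbon
    electron_recovery: float  # percent
    warnings: List[str] = field(default_factory=list)

    @property
    def equation(self) -> str:
        co = {
            s: c / self.substrates_consumed[self.primary]
            for s, c in self.substrates_consumed.items()
            if s != self.primary
        }
        return render_balance_equation(self.yields, self.primary, co_substrates=co or None)


def endpoint_deltas(
    tc: TimeCourse,
    primary: str,
    mode: str = "endpoint",
) -> tuple[Dict[str, float], Dict[str, float], List[str]]:
    """Split mean-channel deltas into consumed substrates and formed products.

    ``mode="endpoint"`` uses last-mean minus first-mean; ``mode="peak"`` uses
    the channel maximum minus the first mean for products (transient
    intermediates).  A nominal product whose endpoint delta is negative is
    clamped to zero and a warning recorded.
    """
    if mode not in ("endpoint", "peak"):
        raise ValueError(f"unknown delta mode {mode!r}")
    consumed: Dict[str, float] = {}
    formed: Dict[str, float] = {}
    warnings: List[str] = []
    for name in tc.concentrations:
        mean = summarize(tc, name).mean
        delta_end = float(mean[-1] - mean[0])
        if name == primary or delta_end < 0 and float(mean.max() - mean[0]) <= 0:
            # substrate-like: net consumed over the run
            consumed[name] = -delta_end
            continue
        if mode == "peak":
            formed[name] = float(mean.max() - mean[0])
        else:
            if delta_end < 0:
                warnings.append(
                    f"product channel {name!r} decreased by {-delta_end:.3g} mM; clamped to 0"
                )
                delta_end = 0.0
            formed[name] = delta_end
    if primary not in consumed:
        raise ValueError(f"primary substrate {primary!r} not found among consumed channels")
    return consumed, formed, warnings


def compute_balance(
    tc: TimeCourse,
    primary: str,
    registry: CompoundRegistry = DEFAULT_REGISTRY,
    mode: str = "endpoint",
    include_co2: bool = False,
) -> FermentationBalance:
    """End-to-end balance of a time course around its primary substrate."""
    consumed, formed, warnings = endpoint_deltas(tc, primary, mode=mode)
    yields = molar_yields(consumed, formed, primary)
    return FermentationBalance(
        primary=primary,
        substrates_consumed=consumed,
        products_formed=formed,
        yields=yields,
        carbon_recovery=carbon_recovery(consumed, formed, registry, include_co2),
        carbon_fractions=carbon_fractions(yields, primary, registry),
        electron_recovery=electron_recovery(consumed, formed, registry, include_co2),
        warnings=warnings,
    )
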