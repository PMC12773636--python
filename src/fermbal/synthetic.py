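"""Seeded synthetic datasets with the statistical structure the analysis assumes.

Growth courses are exponential with a hard plateau (OD = min(od0*e^{mu t},
od_max)); substrate consumption and product formation are strictly
growth-associated (Luedeking-Piret with zero non-growth term), scaled so the
substrate is exhausted exactly when OD plateaus.  Resting-cell courses
consume substrate at a constant rate with no OD change, optionally with a
transiently accumulating formate pool (produced early, re-consumed later)
and a co-consumed CO channel.  Replicate noise is multiplicative Gaussian
with a fixed coefficient of variation -- chromatographic error scales with
signal -- and every generator draws from a single ``numpy`` Generator
seeded from the spec, so a fixed seed reproduces tables byte-identically.

``PRESETS`` mirrors the studied growth conditions (glucose, sorbitol,
maltose, each with and without the PFL inhibitor phosphinate, plus the
resting-cell glucose fermentation): growth rates, final optical densities
and product yields are the reported condition values; the phosphinate
presets carry zero formate yield and elevated lactate.  What these fixtures
deliberately do *not* emulate: lag phases, biomass carbon drain, gas-liquid
partitioning, and instrument drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Mapping, Optional, Sequence

import numpy as np

from .assays import AssayTrace
from .timecourse import TimeCourse

__all__ = [
    "SimulationSpec",
    "PRESETS",
    "get_preset",
    "simulate_growth_course",
    "simulate_resting_cells",
    "simulate_assay_trace",
]


@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of one simulated fermentation."""

    substrate: str = "glucose"
    substrate0: float = 20.0  # mM at t = 0
    yields: Mapping[str, float] = field(default_factory=dict)  # mol/mol substrate
    mu: Optional[float] = 0.69  # h^-1; None for resting cells
    od0: float = 0.1
    od_max: float = 5.0
    noise_cv: float = 0.0  # multiplicative CV on every replicate value
    replicate_count: int = 3
    time_grid: Sequence[float] = tuple(np.arange(0.0, 10.5, 0.5))
    seed: int = 0
    condition: str = ""

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be nonnegative")
        if self.replicate_count < 1:
            raise ValueError("replicate_count must be >= 1")
        if self.substrate0 <= 0:
            raise ValueError("substrate0 must be positive")


def _replicate_noise(rng: np.random.Generator, mean: np.ndarray, cv: float, n_rep: int) -> np.ndarray:
    """(n_rep, n_t) multiplicative-noise replicates of a mean series."""
    mean = np.asarray(mean, dtype=float)
    if cv == 0.0:
        return np.tile(mean, (n_rep, 1))
    factors = 1.0 + cv * rng.standard_normal((n_rep, mean.size))
    return np.clip(mean * factors, 0.0, None)


def _assemble_course(
    spec: SimulationSpec,
    time: np.ndarray,
    mean_channels: Dict[str, np.ndarray],
) -> TimeCourse:
    rng = np.random.default_rng(spec.seed)
    channels = {
        name: _replicate_noise(rng, series, spec.noise_cv, spec.replicate_count)
        for name, series in mean_channels.items()
    }
    return TimeCourse(time=time, channels=channels, condition=spec.condition)


def simulate_growth_course(spec: SimulationSpec) -> TimeCourse:
    """Exponential growth with growth-associated product formation.

    The consumed-substrate fraction tracks the OD rise, reaching exhaustion
    at the plateau; each product accumulates as yield * consumed substrate.
    """
    if spec.mu is None:
        raise ValueError("growth simulation requires mu; use simulate_resting_cells")
    time = np.asarray(list(spec.time_grid), dtype=float)
    od = np.minimum(spec.od0 * np.exp(spec.mu * time), spec.od_max)
    frac = (od - spec.od0) / (spec.od_max - spec.od0)  # consumed fraction, 0..1
    substrate = spec.substrate0 * (1.0 - frac)
    mean_channels: Dict[str, np.ndarray] = {
        "od600": od,
        spec.substrate: substrate,
    }
    consumed = spec.substrate0 * frac
    for product, y in spec.yields.items():
        mean_channels[product] = y * consumed
    return _assemble_course(spec, time, mean_channels)


def simulate_resting_cells(
    spec: SimulationSpec,
    formate_peak: Optional[float] = None,
    formate_peak_time: Optional[float] = None,
    co_per_substrate: float = 0.0,
) -> TimeCourse:
    """Non-growing washed-cell fermentation at constant substrate uptake.

    ``formate_peak`` (mM) switches the formate channel to transient-
    intermediate mode: it rises linearly to the peak at ``formate_peak_time``
    (default mid-course) and then falls linearly to its terminal value
    ``yields['formate'] * substrate0``.  ``co_per_substrate`` co-consumes a
    CO channel at that molar ratio.
    """
    time = np.asarray(list(spec.time_grid), dtype=float)
    frac = time / time[-1] if time[-1] > 0 else np.zeros_like(time)
    consumed = spec.substrate0 * frac
    mean_channels: Dict[str, np.ndarray] = {
        "od600": np.full_like(time, spec.od0),
        spec.substrate: spec.substrate0 - consumed,
    }
    for product, y in spec.yields.items():
        mean_channels[product] = y * consumed
    if formate_peak is not None:
        terminal = spec.yields.get("formate", 0.0) * spec.substrate0
        if terminal < 0:
            raise ValueError("terminal formate must be nonnegative")
        t_peak = formate_peak_time if formate_peak_time is not None else float(time[-1]) / 2
        rise = np.interp(time, [time[0], t_peak], [0.0, formate_peak])
        fall = np.interp(time, [t_peak, time[-1]], [formate_peak, terminal])
        mean_channels["formate"] = np.where(time <= t_peak, rise, fall)
    if co_per_substrate > 0:
        co0 = co_per_substrate * spec.substrate0
        mean_channels["CO"] = co0 - co_per_substrate * consumed
    return _assemble_course(spec, time, mean_channels)


def simulate_assay_trace(
    rate: float,
    protein: float = 1.0,
    extinction: float = 6.22,
    path_length: float = 0.2,
    chromophores_per_turnover: float = 1.0,
    duration: float = 3.0,
    n_points: int = 13,
    a0: float = 1.0,
    direction: int = -1,
    plateau_after: Optional[float] = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> AssayTrace:
    """Linear absorbance trace implied by a specific activity.

    ``rate`` in mU/mg, ``protein`` in mg/mL; ``direction=-1`` models
    chromophore consumption (e.g. NADH oxidation at 340 nm).  The absorbance
    slope inverts the Beer-Lambert activity formula exactly, so at zero
    noise :func:`fermbal.assays.specific_activity_from_trace` recovers
    ``rate``.  ``plateau_after`` (minutes) freezes the trace once substrate
    is exhausted; additive Gaussian noise has ``noise_sd`` AU.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    time = np.linspace(0.0, duration, n_points)
    slope = direction * rate / 1000.0 * protein * extinction * path_length * chromophores_per_turnover
    effective_t = np.minimum(time, plateau_after) if plateau_after is not None else time
    absorbance = a0 + slope * effective_t
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        absorbance = absorbance + noise_sd * rng.standard_normal(time.size)
    absorbance = np.clip(absorbance, 0.0, None)
    return AssayTrace(
        time=time,
        absorbance=absorbance,
        extinction=extinction,
        path_length=path_length,
        chromophores_per_turnover=chromophores_per_turnover,
        protein=protein,
    )


def _growth_preset(condition, substrate, mu, od_max, yields, substrate0=20.0, hours=12.0):
    n = int(hours / 0.5) + 1
    return SimulationSpec(
        substrate=substrate,
        substrate0=substrate0,
        yields=dict(yields),
        mu=mu,
        od0=0.1,
        od_max=od_max,
        noise_cv=0.05,
        replicate_count=3,
        time_grid=tuple(np.linspace(0.0, hours, n)),
        condition=condition,
    )


#: Named presets mirroring the studied conditions.  Yields are the reported
#: molar fermentation balances; phosphinate presets have formate suppressed
#: (PFL inhibited) and lactate as the dominant product.
PRESETS: Dict[str, SimulationSpec] = {
    "glucose": _growth_preset(
        "glucose", "glucose", 0.69, 5.05,
        {"acetate": 0.97, "succinate": 0.42, "lactate": 0.15, "formate": 0.15, "H2": 0.17},
    ),
    "sorbitol": _growth_preset(
        "sorbitol", "sorbitol", 0.59, 4.37,
        {"acetate": 0.67, "succinate": 0.62, "lactate": 0.25, "formate": 0.10, "H2": 0.29},
    ),
    "maltose": _growth_preset(
        "maltose", "maltose", 0.77, 5.29,
        {"acetate": 1.29, "succinate": 0.83, "lactate": 0.28, "formate": 0.45, "H2": 0.63},
    ),
    "glucose_phosphinate": _growth_preset(
        "glucose + phosphinate", "glucose", 0.38, 2.5,
        {"acetate": 0.26, "succinate": 0.34, "lactate": 0.60, "formate": 0.0, "H2": 0.11},
        hours=18.0,
    ),
    "sorbitol_phosphinate": _growth_preset(
        "sorbitol + phosphinate", "sorbitol", 0.38, 1.48,
        {"acetate": 0.03, "succinate": 0.54, "lactate": 0.65, "formate": 0.0, "H2": 0.10},
        hours=18.0,
    ),
    "maltose_phosphinate": _growth_preset(
        "maltose + phosphinate", "maltose", 0.50, 4.0,
        {"acetate": 0.75, "succinate": 0.54, "lactate": 1.04, "formate": 0.0, "H2": 0.59},
        hours=18.0,
    ),
    "resting_glucose": SimulationSpec(
        substrate="glucose",
        substrate0=12.15,
        yields={"acetate": 1.1210, "succinate": 0.8329, "lactate": 0.0296,
                "formate": 0.4305, "H2": 0.4156},
        mu=None,
        od0=1.0,
        noise_cv=0.0,
        replicate_count=2,
        time_grid=tuple(np.linspace(0.0, 24.0, 13)),
        condition="resting cells, glucose",
    ),
}


def get_preset(name: str, seed: int = 0, noise_cv: Optional[float] = None) -> SimulationSpec:
    """A copy of a named preset with the given seed (and optionally noise)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    spec = replace(PRESETS[name], seed=seed)
    if noise_cv is not None:
        spec = replace(spec, noise_cv=noise_cv)
    return spec
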