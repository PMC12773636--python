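"""Configuration-driven analysis pipeline and report assembly.

A single declarative config (YAML/JSON) names the input time course and the
analysis stages to run: growth fit, fermentation balance, and optionally the
flux/bioenergetics model per scenario.  The resulting
:class:`AnalysisReport` serializes losslessly to JSON and renders to a short
human-readable text block; provenance (input hashes, config echo, package
version) is always attached so a report can be traced to its exact inputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Mapping, Optional

import numpy as np

from . import __version__
from .balances import FermentationBalance, compute_balance
from .fluxmodel import FluxSolution, Scenario, build_network, solve_fluxes
from .growth import GrowthFit, fit_growth_rate
from .timecourse import read_timecourse

__all__ = ["AnalysisReport", "PipelineError", "InfeasibleError", "run_pipeline"]

_VALID_KEYS = {"input", "sep", "condition", "primary", "mode", "growth", "flux", "seed"}
_VALID_GROWTH_KEYS = {"window", "r2_threshold", "min_points"}
_VALID_FLUX_KEYS = {"scenarios", "h_per_atp", "rnf_h_per_2e", "fumarate_reductase_donor", "objective"}


class PipelineError(ValueError):
    """Invalid configuration or unreadable input."""


class InfeasibleError(RuntimeError):
    """A flux scenario failed to balance and the run is not permissive."""


@dataclass
class AnalysisReport:
    condition: str
    growth: Optional[GrowthFit]
    balance: FermentationBalance
    equation: str
    flux: Optional[Dict[str, FluxSolution]]
    provenance: Dict[str, object] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return _plain(
            {
                "condition": self.condition,
                "growth": self.growth,
                "balance": self.balance,
                "equation": self.equation,
                "flux": self.flux,
                "provenance": self.provenance,
            }
        )

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)

    def to_text(self) -> str:
        lines = [f"condition: {self.condition}"]
        if self.growth is not None:
            lines.append(
                f"growth: mu = {self.growth.mu:.3f} h^-1 over t = "
                f"{self.growth.window[0]:g}-{self.growth.window[1]:g} h "
                f"(r^2 = {self.growth.r_squared:.4f}), max OD600 = {self.growth.od_final:.2f}"
            )
        lines.append(f"balance: {self.equation}")
        lines.append(
            f"carbon recovery = {self.balance.carbon_recovery:.1f}%  "
            f"electron recovery = {self.balance.electron_recovery:.1f}%"
        )
        for warning in self.balance.warnings:
            lines.append(f"warning: {warning}")
        if self.flux:
            for name, sol in self.flux.items():
                status = "ok" if sol.feasible else f"INFEASIBLE (max residual {sol.max_residual:.2e})"
                lines.append(
                    f"flux[{name}]: ATP/glucose net = {sol.atp_net:.2f} "
                    f"(SLP {sol.atp_slp:.2f}, chemiosmotic {sol.atp_chemiosmotic:.2f}) [{status}]"
                )
        return "\n".join(lines)


def _plain(obj):
    """Recursively convert dataclasses / numpy scalars into JSON-safe types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _plain(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return [_plain(v) for v in obj.tolist()]
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(
    config: Mapping,
    base_dir: Optional[Path] = None,
    permissive: bool = False,
) -> AnalysisReport:
    """Execute growth -> balance -> (optional) flux for one configuration.

    ``config`` keys: ``input`` (CSV path, required), ``sep``, ``condition``,
    ``primary`` (default glucose), ``mode`` (endpoint/peak deltas),
    ``growth`` (sub-dict or false to skip), ``flux`` (sub-dict with
    ``scenarios`` list and bioenergetic parameters; omit to skip).  Unknown
    keys raise :class:`PipelineError` naming them; an infeasible flux
    scenario raises :class:`InfeasibleError` unless ``permissive``.
    """
    unknown = set(config) - _VALID_KEYS
    if unknown:
        raise PipelineError(f"invalid config keys: {sorted(unknown)}")
    if "input" not in config:
        raise PipelineError("config must name an 'input' time-course file")
    path = Path(config["input"])
    if base_dir is not None and not path.is_absolute():
        path = Path(base_dir) / path
    if not path.exists():
        raise PipelineError(f"input file not found: {path}")

    condition = str(config.get("condition", path.stem))
    tc = read_timecourse(path, sep=str(config.get("sep", ",")), condition=condition)
    primary = str(config.get("primary", "glucose"))

    growth_cfg = config.get("growth", {})
    growth_fit: Optional[GrowthFit] = None
    if growth_cfg is not False and tc.od600 is not None:
        growth_cfg = growth_cfg or {}
        bad = set(growth_cfg) - _VALID_GROWTH_KEYS
        if bad:
            raise PipelineError(f"invalid growth config keys: {sorted(bad)}")
        window = growth_cfg.get("window")
        growth_fit = fit_growth_rate(
            tc,
            window=tuple(window) if window else None,
            r2_threshold=float(growth_cfg.get("r2_threshold", 0.995)),
            min_points=int(growth_cfg.get("min_points", 4)),
        )

    balance = compute_balance(tc, primary, mode=str(config.get("mode", "endpoint")))

    flux_solutions: Optional[Dict[str, FluxSolution]] = None
    flux_cfg = config.get("flux")
    if flux_cfg:
        bad = set(flux_cfg) - _VALID_FLUX_KEYS
        if bad:
            raise PipelineError(f"invalid flux config keys: {sorted(bad)}")
        scenario_names = flux_cfg.get("scenarios", ["hydm", "hydabc"])
        yields = {
            k: v for k, v in balance.yields.items()
            if k.lower() in ("acetate", "succinate", "lactate", "formate", "h2")
        }
        flux_solutions = {}
        for name in scenario_names:
            scenario = Scenario(
                hydrogenase=name,
                fumarate_reductase_donor=str(flux_cfg.get("fumarate_reductase_donor", "nadh")),
                h_per_atp=float(flux_cfg.get("h_per_atp", 3.6)),
                rnf_h_per_2e=float(flux_cfg.get("rnf_h_per_2e", 2.0)),
            )
            sol = solve_fluxes(
                build_network(scenario),
                yields,
                scenario,
                objective=str(flux_cfg.get("objective", "min_norm")),
            )
            flux_solutions[name] = sol
            if not sol.feasible and not permissive:
                worst = max(sol.residuals, key=lambda n: abs(sol.residuals[n]))
                raise InfeasibleError(
                    f"scenario {name!r} cannot balance node {worst!r} "
                    f"(residual {sol.residuals[worst]:.3g}); rerun with --permissive to keep going"
                )

    provenance = {
        "input": str(path),
        "input_sha256": _sha256(path),
        "config": _plain(dict(config)),
        "seed": config.get("seed"),
        "fermbal_version": __version__,
    }
    return AnalysisReport(
        condition=condition,
        growth=growth_fit,
        balance=balance,
        equation=balance.equation,
        flux=flux_solutions,
        provenance=provenance,
    )
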