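"""Stoichiometric flux and bioenergetics model of acetogen glucose fermentation.

The network couples the oxidative branch of glucose catabolism (EMP
glycolysis to PEP, the pyruvate node with its three exits PFL / PFOR / LDH,
and the PEP-carboxykinase succinate branch) to a formate-fed Wood-Ljungdahl
pathway (WLP) and the redox machinery of an acetogen that lacks formate
dehydrogenase:

* glycolysis to PEP: glucose -> 2 PEP + 2 NADH, net 0 ATP (plain EMP
  accounting, no PTS);
* pyruvate kinase (+1 ATP) and PEP carboxykinase (+1 ATP per oxaloacetate,
  fixing CO2), then malate dehydrogenase, fumarase and fumarate reductase to
  succinate;
* PFL (pyruvate -> acetyl-CoA + formate), PFOR (pyruvate -> acetyl-CoA +
  CO2 + Fdred) and LDH at the pyruvate node; phosphotransacetylase/acetate
  kinase (+1 ATP);
* a WLP lumped to one reaction per acetate: formate + CO2 + NADPH
  (methylene-THF dehydrogenase) + NADH (methylene-THF reductase, simple
  non-bifurcating) + Fdred (CODH/ACS) -> acetate, with the formyl-THF
  synthetase ATP cost cancelled by the acetate kinase gain (net 0 ATP);
* the electron-bifurcating transhydrogenase Nfn (NADH + Fdred -> 2 NADPH),
  the proton-translocating Rnf (Fdred -> NADH, ``rnf_h_per_2e`` H+ out,
  reversible), the ATP synthase (``h_per_atp`` H+ per ATP, reversible), and
  one of two hydrogenases: ferredoxin-dependent HydM (Fdred -> H2) or
  electron-bifurcating HydABC (1/2 NADH + 1/2 Fdred -> H2).

Exchange fluxes for the five measured products (acetate, succinate, lactate,
formate, H2) are pinned to measured yields per glucose; CO2 and water
exchange freely.  The steady-state system ``S v = b`` is then generically
fully determined; underdetermined variants are resolved by the minimum-norm
nonnegative flux, and infeasible measurements return a least-squares
solution with per-node residuals flagged rather than an exception.

The ATP ledger separates substrate-level phosphorylation (pyruvate kinase +
PEP carboxykinase + acetate kinase - formyl-THF synthetase) from
chemiosmotic ATP (translocated H+ / ``h_per_atp``); a negative chemiosmotic
term means the gradient is fed by ATP hydrolysis (Rnf running in reverse to
supply reduced ferredoxin), as in the strictly homoacetogenic reference
conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import linprog, lsq_linear, minimize

__all__ = [
    "Reaction",
    "Scenario",
    "FluxSolution",
    "SPECIES",
    "REFERENCE_GLUCOSE_YIELDS",
    "build_network",
    "check_network",
    "solve_fluxes",
    "atp_ledger",
    "compare_scenarios",
    "minimum_norm_solve",
    "network_to_dict",
    "network_from_dict",
]

#: species -> (carbons, degree of reduction).  Carriers NADH/NADPH/Fdred are
#: two-electron equivalents; phosphorylated intermediates carry the gamma of
#: their carbon skeleton (the phosphate moiety is redox-neutral).
SPECIES: Dict[str, Tuple[int, float]] = {
    "glucose": (6, 24.0),
    "pep": (3, 10.0),
    "pyruvate": (3, 10.0),
    "oxaloacetate": (4, 10.0),
    "malate": (4, 12.0),
    "fumarate": (4, 12.0),
    "succinate": (4, 14.0),
    "acetyl_coa": (2, 8.0),
    "acetate": (2, 8.0),
    "lactate": (3, 12.0),
    "formate": (1, 2.0),
    "co2": (1, 0.0),
    "h2": (0, 2.0),
    "h2o": (0, 0.0),
    "nadh": (0, 2.0),
    "nadph": (0, 2.0),
    "fdred": (0, 2.0),
    "h_out": (0, 0.0),  # translocated protons
    "atp": (0, 0.0),  # tracked, never balanced
}

#: exchangeable products whose yields pin the solution
PRODUCTS = ("acetate", "succinate", "lactate", "formate", "h2")

#: Idealized, exactly element- and redox-balanced glucose fermentation
#: yields used for the bioenergetic scenario comparison.  They are the
#: closed-stoichiometry counterpart of the measured resting-cell balance
#: (acetate 1.12, succinate 0.83, lactate 0.03, formate 0.43, H2 0.41):
#: the unique nearby yield set for which every carrier node balances with
#: zero residual in the HydM scenario.
REFERENCE_GLUCOSE_YIELDS: Dict[str, float] = {
    "acetate": 1.15,
    "succinate": 0.90,
    "lactate": 0.05,
    "formate": 0.40,
    "H2": 0.40,
}


@dataclass(frozen=True)
class Reaction:
    """One reaction: species -> signed stoichiometric coefficient.

    ``atp`` appears inside ``stoichiometry`` like any species but is never
    balanced; it feeds the ATP ledger.
    """

    name: str
    stoichiometry: Mapping[str, float]
    reversible: bool = False

    def coefficient(self, species: str) -> float:
        return float(self.stoichiometry.get(species, 0.0))


@dataclass(frozen=True)
class Scenario:
    """Bioenergetic assumptions of one model variant."""

    hydrogenase: str = "hydm"  # "hydm" | "hydabc" | "none"
    fumarate_reductase_donor: str = "nadh"  # "nadh" | "none"
    h_per_atp: float = 3.6  # H+ per ATP at the synthase
    rnf_h_per_2e: float = 2.0  # H+ translocated per 2 electrons at Rnf

    def __post_init__(self) -> None:
        if self.hydrogenase not in ("hydm", "hydabc", "none"):
            raise ValueError(f"unknown hydrogenase {self.hydrogenase!r}")
        if self.fumarate_reductase_donor not in ("nadh", "none"):
            raise ValueError(f"unknown fumarate reductase donor {self.fumarate_reductase_donor!r}")
        if self.h_per_atp <= 0:
            raise ValueError("h_per_atp must be positive")
        if self.rnf_h_per_2e < 0:
            raise ValueError("rnf_h_per_2e must be nonnegative")


def build_network(scenario: Scenario = Scenario()) -> List[Reaction]:
    """Assemble the reaction set for a scenario (element-checked)."""
    rxns = [
        Reaction("glycolysis", {"glucose": -1, "pep": 2, "nadh": 2}),
        Reaction("pyruvate_kinase", {"pep": -1, "pyruvate": 1, "atp": 1}),
        Reaction("pep_carboxykinase", {"pep": -1, "co2": -1, "oxaloacetate": 1, "atp": 1}),
        Reaction("malate_dehydrogenase", {"oxaloacetate": -1, "nadh": -1, "malate": 1}),
        Reaction("fumarase", {"malate": -1, "fumarate": 1, "h2o": 1}),
        Reaction("pfl", {"pyruvate": -1, "acetyl_coa": 1, "formate": 1}),
        Reaction("pfor", {"pyruvate": -1, "acetyl_coa": 1, "co2": 1, "fdred": 1}),
        Reaction("ldh", {"pyruvate": -1, "nadh": -1, "lactate": 1}),
        Reaction("acetate_kinase", {"acetyl_coa": -1, "acetate": 1, "atp": 1}),
        Reaction(
            "wlp",
            {
                "formate": -1,
                "co2": -1,
                "nadph": -1,
                "nadh": -1,
                "fdred": -1,
                "acetate": 1,
                "h2o": 2,
            },
        ),
        Reaction("nfn", {"nadh": -1, "fdred": -1, "nadph": 2}, reversible=True),
        Reaction(
            "rnf",
            {"fdred": -1, "nadh": 1, "h_out": scenario.rnf_h_per_2e},
            reversible=True,
        ),
        Reaction("atp_synthase", {"h_out": -scenario.h_per_atp, "atp": 1}, reversible=True),
    ]
    if scenario.fumarate_reductase_donor == "nadh":
        rxns.insert(
            5, Reaction("fumarate_reductase", {"fumarate": -1, "nadh": -1, "succinate": 1})
        )
    if scenario.hydrogenase == "hydm":
        rxns.append(Reaction("hydm", {"fdred": -1, "h2": 1}))
    elif scenario.hydrogenase == "hydabc":
        rxns.append(Reaction("hydabc", {"nadh": -0.5, "fdred": -0.5, "h2": 1}))
    check_network(rxns)
    return rxns


def check_network(reactions: Sequence[Reaction], tol: float = 1e-9) -> None:
    """Assert carbon and available-electron conservation for every reaction.

    Together with the fixed H/O content of each species these two balances
    pin down elemental consistency; carriers count two electrons per reduced
    equivalent and translocated protons count zero.
    """
    for rxn in reactions:
        carbon = 0.0
        electrons = 0.0
        for species, coeff in rxn.stoichiometry.items():
            if species not in SPECIES:
                raise ValueError(f"reaction {rxn.name!r}: unknown species {species!r}")
            c, gamma = SPECIES[species]
            carbon += coeff * c
            electrons += coeff * gamma
        if abs(carbon) > tol:
            raise ValueError(f"reaction {rxn.name!r} is carbon-unbalanced by {carbon:g}")
        if abs(electrons) > tol:
            raise ValueError(f"reaction {rxn.name!r} is electron-unbalanced by {electrons:g}")


@dataclass
class FluxSolution:
    """Steady-state fluxes (mol per mol glucose) and the ATP ledger."""

    fluxes: Dict[str, float]
    atp_slp: float  # substrate-level phosphorylation per glucose
    atp_chemiosmotic: float  # Rnf-gradient ATP per glucose (negative = ATP-driven)
    atp_net: float
    residuals: Dict[str, float]  # node -> steady-state imbalance
    feasible: bool
    scenario: Scenario = field(default_factory=Scenario)

    @property
    def max_residual(self) -> float:
        return max((abs(r) for r in self.residuals.values()), default=0.0)


def minimum_norm_solve(
    A: np.ndarray,
    b: np.ndarray,
    lower_bounds: np.ndarray,
    tol: float = 1e-9,
) -> Tuple[np.ndarray, np.ndarray]:
    """Solve ``A v = b`` subject to ``v >= lower_bounds``.

    Returns ``(v, residual_vector)``.  Strategy: the unconstrained
    minimum-norm solution (SVD least squares) is used whenever it already
    respects the bounds; otherwise a bounded least-squares solution is
    computed and, when it attains (near-)zero residual, polished to the
    minimum-norm point of the feasible affine set with SLSQP.
    """
    A = np.asarray(A, dtype=float)
    b = np.asarray(b, dtype=float)
    x, *_ = np.linalg.lstsq(A, b, rcond=None)
    if np.all(x >= lower_bounds - tol):
        x = np.maximum(x, lower_bounds)
        return x, A @ x - b

    bounds = (lower_bounds, np.full_like(lower_bounds, np.inf))
    res = lsq_linear(A, b, bounds=bounds, tol=1e-12)
    x = res.x
    residual = A @ x - b
    if np.max(np.abs(residual)) < 1e-7:
        # feasible: refine toward the minimum-norm feasible point
        out = minimize(
            lambda v: 0.5 * float(v @ v),
            x0=x,
            jac=lambda v: v,
            constraints=[{"type": "eq", "fun": lambda v: A @ v - b, "jac": lambda v: A}],
            bounds=[(lb, None) for lb in lower_bounds],
            method="SLSQP",
            options={"maxiter": 200, "ftol": 1e-14},
        )
        if out.success and np.max(np.abs(A @ out.x - b)) < 1e-7:
            x = out.x
            residual = A @ x - b
    return x, residual


def _assemble(
    network: Sequence[Reaction],
    product_yields: Mapping[str, float],
    glucose_uptake: float = 1.0,
) -> Tuple[np.ndarray, np.ndarray, List[str], List[str], np.ndarray]:
    """Build the steady-state matrix over free reactions.

    Fixed exchange fluxes (glucose in, measured products out) are moved to
    the right-hand side; CO2 and water exchange remain free and reversible.
    """
    yields = {k.lower(): float(v) for k, v in product_yields.items()}
    unknown = set(yields) - set(PRODUCTS)
    if unknown:
        raise ValueError(f"yields given for unknown products: {sorted(unknown)}")

    free: List[Reaction] = list(network) + [
        Reaction("ex_co2", {"co2": -1}, reversible=True),
        Reaction("ex_h2o", {"h2o": -1}, reversible=True),
    ]
    fixed: List[Tuple[Reaction, float]] = [
        (Reaction("uptake_glucose", {"glucose": 1}), glucose_uptake)
    ]
    for product in PRODUCTS:
        fixed.append((Reaction(f"ex_{product}", {product: -1}), yields.get(product, 0.0)))

    nodes = sorted(
        {s for rxn in free for s in rxn.stoichiometry if s != "atp"}
        | {s for rxn, _ in fixed for s in rxn.stoichiometry}
    )
    node_index = {n: i for i, n in enumerate(nodes)}
    A = np.zeros((len(nodes), len(free)))
    for j, rxn in enumerate(free):
        for species, coeff in rxn.stoichiometry.items():
            if species == "atp":
                continue
            A[node_index[species], j] = coeff
    b = np.zeros(len(nodes))
    for rxn, value in fixed:
        for species, coeff in rxn.stoichiometry.items():
            b[node_index[species]] -= coeff * value

    lb = np.array([-np.inf if rxn.reversible else 0.0 for rxn in free])
    return A, b, nodes, [rxn.name for rxn in free], lb


def solve_fluxes(
    network: Sequence[Reaction],
    product_yields: Mapping[str, float],
    scenario: Scenario = Scenario(),
    objective: str = "min_norm",
    glucose_uptake: float = 1.0,
    residual_tol: float = 1e-6,
) -> FluxSolution:
    """Solve steady-state fluxes for measured product yields per glucose.

    ``objective="min_norm"`` (default) returns the minimum-norm nonnegative
    flux when the system is underdetermined; ``objective="max_atp"``
    maximises net ATP over the feasible set instead.  Measurements that
    cannot balance (e.g. H2 reported without any hydrogenase in the
    scenario) yield ``feasible=False`` with per-node residuals rather than
    an exception.
    """
    A, b, nodes, names, lb = _assemble(network, product_yields, glucose_uptake)

    if objective == "max_atp":
        c = -np.array([_atp_weight(rxn) for rxn in network] + [0.0, 0.0])
        res = linprog(c, A_eq=A, b_eq=b, bounds=[(l if np.isfinite(l) else None, None) for l in lb])
        if not res.success:
            # fall back to the least-squares diagnosis below
            v, residual = minimum_norm_solve(A, b, lb)
        else:
            v, residual = res.x, A @ res.x - b
    elif objective == "min_norm":
        v, residual = minimum_norm_solve(A, b, lb)
    else:
        raise ValueError(f"unknown objective {objective!r}")

    fluxes = {name: float(val) for name, val in zip(names, v)}
    residuals = {node: float(r) for node, r in zip(nodes, residual)}
    slp, chemi, net = atp_ledger(fluxes, scenario)
    return FluxSolution(
        fluxes=fluxes,
        atp_slp=slp,
        atp_chemiosmotic=chemi,
        atp_net=net,
        residuals=residuals,
        feasible=bool(np.max(np.abs(residual)) < residual_tol) if len(residual) else True,
        scenario=scenario,
    )


def _atp_weight(rxn: Reaction) -> float:
    return rxn.coefficient("atp")


#: substrate-level phosphorylation contributors (the lumped WLP reaction has
#: its formyl-THF synthetase cost and acetate kinase gain cancelled inside)
_SLP_REACTIONS = {
    "pyruvate_kinase": 1.0,
    "pep_carboxykinase": 1.0,
    "acetate_kinase": 1.0,
}


def atp_ledger(
    fluxes: Mapping[str, float],
    scenario: Scenario = Scenario(),
) -> Tuple[float, float, float]:
    """Split ATP production into (substrate-level, chemiosmotic, net).

    Chemiosmotic ATP is ``rnf_flux * rnf_h_per_2e / h_per_atp``: every
    translocated proton passes the synthase at ``h_per_atp`` H+ per ATP.  A
    reverse Rnf flux makes the term negative (gradient maintained at ATP
    expense).
    """
    slp = sum(w * fluxes.get(name, 0.0) for name, w in _SLP_REACTIONS.items())
    chemiosmotic = fluxes.get("rnf", 0.0) * scenario.rnf_h_per_2e / scenario.h_per_atp
    return float(slp), float(chemiosmotic), float(slp + chemiosmotic)


def compare_scenarios(
    product_yields: Mapping[str, float],
    scenarios: Optional[Mapping[str, Scenario]] = None,
    **solve_kwargs,
) -> Dict[str, FluxSolution]:
    """Solve identical exchange fluxes under alternative hydrogenase scenarios.

    Defaults to the ferredoxin-only HydM scenario versus the
    electron-bifurcating HydABC scenario; the returned mapping carries one
    :class:`FluxSolution` per scenario name (use ``atp_net`` differences to
    quantify the bioenergetic advantage of bifurcation).
    """
    if scenarios is None:
        scenarios = {
            "hydm": Scenario(hydrogenase="hydm"),
            "hydabc": Scenario(hydrogenase="hydabc"),
        }
    return {
        name: solve_fluxes(build_network(sc), product_yields, sc, **solve_kwargs)
        for name, sc in scenarios.items()
    }


# -- declarative (de)serialization -----------------------------------------

def network_to_dict(network: Sequence[Reaction], scenario: Optional[Scenario] = None) -> dict:
    """Plain-dict form of a network (YAML/JSON-serializable)."""
    out: dict = {
        "reactions": [
            {
                "name": rxn.name,
                "stoichiometry": dict(rxn.stoichiometry),
                "reversible": rxn.reversible,
            }
            for rxn in network
        ]
    }
    if scenario is not None:
        out["scenario"] = asdict(scenario)
    return out


def network_from_dict(data: Mapping) -> Tuple[List[Reaction], Optional[Scenario]]:
    """Inverse of :func:`network_to_dict`; the network is balance-checked."""
    reactions = [
        Reaction(r["name"], dict(r["stoichiometry"]), bool(r.get("reversible", False)))
        for r in data["reactions"]
    ]
    check_network(reactions)
    scenario = Scenario(**data["scenario"]) if "scenario" in data else None
    return reactions, scenario
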