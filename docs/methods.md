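# Methods

## Scope and data model

The package quantifies anaerobic sugar fermentation at three levels:
(1) *descriptive* — replicate-summarised time courses, growth rates,
endpoint deltas; (2) *balance* — molar yields, carbon and available-electron
recovery; (3) *mechanistic* — a small carrier-coupled stoichiometric model
of acetogen glucose fermentation with an explicit ATP ledger. All
concentrations are mM in the culture liquid; H₂ is taken as the reported
dissolved-equivalent mM per culture volume, with no gas–liquid partitioning
model.

## Elemental bookkeeping

Each compound is reduced to its carbon count and degree of reduction
γ = 4C + H − 2O (available electrons per mole; N weighted zero, irrelevant
for the compounds in scope). Organic acids are registered as neutral
(protonated) species so balances are charge-free; water and CO₂ both carry
γ = 0, so any element-balanced conversion conserves γ exactly. Biomass is
deliberately unregistered: growing-culture recoveries below 100% measure
the un-modelled biomass drain, and that is information, not error.

**CO₂ convention.** Recoveries exclude CO₂ (and water) from both sides by
default, because the cultures of interest are grown in CO₂/bicarbonate
buffer where net CO₂ exchange is not measurable against the background.
Two consequences are intended: (a) net CO₂ fixation (PEP carboxykinase to
succinate; the WLP) pushes carbon recovery *above* 100% — the washed-cell
glucose fermentation gives 101.6%; (b) electron recovery is insensitive to
the convention since γ(CO₂) = 0. `include_co2=True` restores exact closure
and is used by the synthetic closure tests.

**Endpoint deltas.** Default is last-mean − first-mean per channel. A
channel that declines monotonically from a nonzero start is classified as a
consumed substrate (this is how a CO co-substrate enters the electron
balance); a channel that rises and ends below its start is a transient
intermediate — its endpoint delta is clamped to zero with a warning, and
`mode="peak"` reports the transient maximum instead. This mirrors formate
behaviour under mixotrophic conditions (produced early, re-consumed via the
WLP).

## Replicate statistics and growth fitting

Summaries are mean ± SEM with the sample (n−1) standard deviation,
matching the N = 3 presentation convention of the emulated experiments;
missing values are dropped per timepoint.

μ is the slope of OLS on ln(OD) vs time over an exponential window, fitted
on the mean series (a per-replicate mode provides an SEM of μ). Automatic
window selection scores every contiguous window of ≥ 4 strictly positive
points and takes the longest with r² ≥ 0.995, earliest on ties, with one
refinement: if any window is numerically perfect (r² ≥ 1 − 10⁻⁴), only
perfect windows compete. The refinement makes noise-free data exactly
recoverable even when a plateau follows, and the 0.995 threshold keeps
plateau points from leaking into the window of clean-but-noisy data (at a
laxer 0.98 a window extended by one saturation point typically still
qualifies and biases μ low by several percent). Both knobs are arguments.
If nothing qualifies, the best four-point window is used and the fit is
flagged. r² of a constant series is reported as 0. No lag or death phase is
modelled.

## The flux model

One network per scenario, mol per mol glucose:

| reaction | stoichiometry | ATP |
|---|---|---|
| glycolysis | glucose → 2 PEP + 2 NADH | 0 |
| pyruvate kinase | PEP → pyruvate | +1 |
| PEP carboxykinase | PEP + CO₂ → OAA | +1 |
| malate DH, fumarase, fumarate reductase | OAA + 2 NADH → succinate (+H₂O) | 0 |
| PFL | pyruvate → acetyl-CoA + formate | 0 |
| PFOR | pyruvate → acetyl-CoA + CO₂ + Fd²⁻ | 0 |
| LDH | pyruvate + NADH → lactate | 0 |
| PTA/ACK | acetyl-CoA → acetate | +1 |
| WLP (lumped) | formate + CO₂ + NADPH + NADH + Fd²⁻ → acetate | 0 |
| Nfn | NADH + Fd²⁻ → 2 NADPH | 0 |
| Rnf (reversible) | Fd²⁻ → NADH, translocates `rnf_h_per_2e` H⁺ | — |
| ATP synthase (reversible) | `h_per_atp` H⁺ → ATP | — |
| HydM *or* HydABC | Fd²⁻ → H₂ *or* ½NADH + ½Fd²⁻ → H₂ | 0 |

Design choices where the biology left room:

* The WLP is lumped to one reaction per acetate with the carrier
  assignments of a formate-dehydrogenase-lacking acetogen: NADPH at the
  methylene-THF dehydrogenase, NADH at a simple (non-bifurcating,
  non-translocating) methylene-THF reductase, Fd²⁻ at CODH/ACS; the
  formyl-THF synthetase ATP cost cancels the downstream acetate-kinase gain,
  so the lump is ATP-neutral.
* Nfn is the canonical bifurcating transhydrogenase stoichiometry
  (1 NADH + 1 Fd²⁻ → 2 NADPH), reversible.
* Fumarate reductase is NADH-coupled by default (`fumarate_reductase_donor`
  is a scenario parameter; the in-vivo donor is unresolved because the
  assay used methylviologen).
* Glucose enters by plain EMP accounting (net 0 ATP to PEP, no PTS);
  PEP carboxykinase yields 1 ATP per oxaloacetate; the
  pyruvate-carboxylating routes are absent from the organism's genome and
  from the network.
* No biomass drain: the model targets resting-cell/idealized
  stoichiometries. Growing-cell yields do not close and are reported with
  residuals, never forced.

**Solving.** Exchange fluxes for the five measured products are pinned;
CO₂ and water exchange freely; every other species (internal metabolites,
NADH, NADPH, Fd²⁻, translocated H⁺) must balance. ATP is tracked, not
balanced. The resulting linear system is generically fully determined up to
the one redundancy implied by electron conservation. Numerically: the SVD
minimum-norm solution is accepted if it respects irreversibility; otherwise
bounded least squares (scipy `lsq_linear`), polished to the minimum-norm
feasible point by SLSQP when the residual is ~0. Infeasible measurements
(e.g. H₂ reported with no hydrogenase in the scenario, or growing-cell
yields) return the least-squares solution with per-node residuals and
`feasible=False`; nothing is silently adjusted. A `max_atp` objective
(linear programming) is available as an alternative tie-break for
genuinely underdetermined variants. Feasibility tolerance 10⁻⁶ on node
residuals; solved reference cases balance to < 10⁻⁹.

**ATP ledger.** `atp_slp` sums pyruvate kinase, PEP carboxykinase and
acetate kinase fluxes (the WLP lump is neutral);
`atp_chemiosmotic = v_Rnf · rnf_h_per_2e / h_per_atp` with defaults
2 H⁺/2e⁻ and 3.6 H⁺/ATP. A negative chemiosmotic term is meaningful: in the
strictly homoacetogenic conversion (glucose → 3 acetate) the ledger gives
SLP = 4 ATP/hexose while Rnf must run in reverse (−0.5 Fd²⁻, −0.28 ATP) to
supply the CODH with reduced ferredoxin.

**Reference yield set.** The bioenergetic scenario comparison uses
`REFERENCE_GLUCOSE_YIELDS` = acetate 1.15, succinate 0.90, lactate 0.05,
formate 0.40, H₂ 0.40 per glucose. Derivation: impose exact carbon and
electron closure plus zero-residual carrier balances in the HydM scenario
(Rnf = 0, so net ATP is purely substrate-level), and require the yields to
lie as close as possible to the measured washed-cell balance
(1.12/0.83/0.03/0.43/0.41). The solution is unique and round:
PK 1.1 + PEPCK 0.9 + ACK 1.05 → 3.05 ATP; switching to HydABC frees
0.2 Fd²⁻ for Rnf → +0.111 ATP (3.16). The measured yields themselves carry
a small infeasibility (≈0.02 on the acetyl-CoA/formate nodes) that the
solver reports as residuals — measurement noise, not model failure.

## Enzyme assays

Initial-rate convention: the earliest linear stretch (≥ 4 points,
r² ≥ 0.99) of the trace is fitted; Beer–Lambert converts |dA/dt| through
the extinction coefficient and path length (default 0.2 cm anoxic cuvette)
into mM/min, normalised by protein and by chromophores-per-turnover
(2 for methylviologen-linked assays: two one-electron radicals per
two-electron substrate reduction). Defaults: NADH 6.22 mM⁻¹cm⁻¹ at 340 nm,
methylviologen radical 13.9 mM⁻¹cm⁻¹ at 604 nm; the 430 nm ferredoxin assay
has no defensible universal Δε and requires a user-supplied value. The PFL
assay is chemical (formate formed over time; the fitted window must be
nondecreasing). Published absolute activities are context, not test
oracles: the raw traces behind them are unpublished, so the assay path is
validated by synthetic-trace recovery (exact at zero noise, mean within
10–15% at the simulated noise levels).

## Synthetic data

The generator emulates the statistical shape of the study's measurements,
and its defaults are the studied conditions:

* growth: OD = min(od₀·e^{μt}, od_max); substrate consumption and product
  formation strictly growth-associated (Luedeking–Piret, zero non-growth
  term), substrate exhausted at the plateau; presets carry the reported
  μ, final OD and yield sets for glucose (μ 0.69 h⁻¹), sorbitol (0.59),
  maltose (0.77) and their phosphinate-inhibited counterparts (formate
  yield 0, lactate dominant, μ 0.38–0.50). Final OD for glucose+phosphinate
  and maltose+phosphinate are not reported anywhere; the presets use 2.5
  and 4.0 as plausible inhibited values.
* resting cells: constant-rate substrate uptake, constant OD, optional
  piecewise-linear transient formate (rise to a peak, fall to the terminal
  yield) and a CO co-substrate channel.
* noise: multiplicative Gaussian with fixed CV (default 5% for growth
  presets, N = 3), because chromatographic error scales with signal; one
  seeded generator per simulation makes outputs byte-identical under a
  fixed seed.
* assay traces: exact Beer–Lambert inversion of a target specific
  activity, optional plateau at substrate exhaustion, additive noise.

Passing round-trip tests on these fixtures demonstrates internal
consistency of generator and analyzers — not robustness to lag phases,
biomass carbon, drift, or gas-phase equilibration, none of which are
simulated.

## Problem sizes and determinism

The test suite uses 200 simulated growth courses for the estimator-recovery
check (median |μ̂ − μ| < 0.03 h⁻¹ at 5% CV), 20-trace ensembles for assay
recovery, and 25–30 random small systems against the pseudoinverse oracle;
everything is seeded or derandomised (hypothesis profile) and completes in
well under a minute. The acceptance script's computation (homoacetogenic
reference) is deterministic; its `--seed` exists for interface uniformity.

## Known limitations

* No thermodynamics: flux directions are imposed, not derived from ΔG.
* The flux model is resting-cell idealized; growing cultures require a
  biomass reaction it deliberately lacks.
* Carbon recovery above 100% is convention-dependent (CO₂ exclusion) and
  should be reported together with the convention.
* The exponential-window heuristic assumes a single exponential phase;
  diauxic curves will fit whichever phase scores best.
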