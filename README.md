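# rhizoflux

Constraint-based modelling of multi-tissue plant metabolism and the
rhizobial nitrogen-fixing symbiosis.

Legumes host nitrogen-fixing rhizobia in root nodules: differentiated
bacteroids reduce atmospheric N₂ with the oxygen-sensitive, ATP- and
reductant-hungry nitrogenase, and the plant pays for it with organic
acids and a tightly regulated oxygen supply.  `rhizoflux` is a toolkit
for studying this intertwined metabolism with genome-scale-style
stoichiometric models: it covers model curation (mass/charge balance,
energy-cycle certification), flux balance analysis with quadratic flux
minimisation, flux-consistency and essentiality analysis, FASTCORE
tissue extraction, multi-tissue and plant–symbiont model composition,
and the classic in-silico experiments — nitrogen-source scans,
symbiosis growth comparisons, bacteroid oxygen-availability scans and
knockout variants.  It is aimed at systems-biology researchers who want
these analyses as reusable, tested library functions rather than
one-off scripts, and it ships curated synthetic mini-models (a
compartmentalised plant cell and a bacteroid) so the whole pipeline
runs end-to-end with no downloads.

## The model

A metabolic network is a stoichiometric matrix **S** (metabolites ×
reactions) with flux bounds.  Flux balance analysis assumes a metabolic
quasi steady state,

    S · v = 0,      lb ≤ v ≤ ub,

and optimises a linear objective, typically the biomass (growth) flux.
Because the optimal flux *distribution* is generally not unique, every
reported distribution comes from the quadratic flux minimisation

    min Σᵢ vᵢ²   subject to   S·v = 0,  bounds,  fixed targets,

whose strictly convex objective has a unique optimum, interpreted as
maximally efficient enzyme usage.  Scans fix a handful of fluxes per
grid point (growth rate, ammonium/nitrate uptake, bacteroid oxygen) and
tabulate the unique optimal exchanges.  LPs are solved with HiGHS
(scipy), the QP with OSQP; the engine is fully deterministic.  See
`docs/methods.md` for the complete methods note.

## Worked example

Nitrogen nutrition changes the charge budget of the root: ammonium
(NH₄⁺) uptake forces net acid export (soil acidification), nitrate
(NO₃⁻) the opposite, with bicarbonate release.  Scan the bundled
mini-plant at night over ammonium/nitrate mixtures at fixed growth:

```sh
$ rhizoflux scan-nitrogen --points 5
ammonium_fraction  starch_exchange  proton_exchange  hco3_exchange
0.0                -0.0831          0.1065           0.1215
0.25               -0.0820          0.1105           0.1180
0.5                -0.0809          0.1145           0.1145
0.75               -0.0798          0.1184           0.1109
1.0                -0.0787          0.1224           0.1074
```

The net acid export (H⁺ export − HCO₃⁻ export) moves from −0.015 on
pure nitrate through exactly 0 at the equimolar point to +0.015 on pure
ammonium — charge conservation ties it to the signed charge of the
nitrogen uptake — and the starch demand falls as ammonium replaces
nitrate (nitrate reduction burns 8 electrons per nitrogen).

The same night regime bounds how much starch carbon can end up in
biomass at all:

```sh
$ rhizoflux carbon-efficiency --nsource nh4
nitrogen source: nh4
conversion efficiency: 0.6508
respired fraction:     0.3492
carbon balance residual: -1.01e-12
```

(on nitrate the efficiency drops to 0.5973 — the extra reductant demand
is paid in respired starch).

On the symbiotic side, the two-tissue plant plus bacteroid grows at
1.407 g·gDW⁻¹·day⁻¹ with *zero* external nitrogen (the plain plant:
0), at the price of slightly lower growth when ammonium is plentiful
(`rhizoflux compare-symbiosis`).  Scanning the bacteroid's fixed oxygen
uptake at 80 % of maximal growth (`rhizoflux scan-oxygen`) reproduces
the canonical exchange pattern: below a minimum oxygen (0.246
mmol·gDW⁻¹·day⁻¹ here) no feasible state exists; at low oxygen the
bacteroid imports malate and dumps surplus reductant into alanine —
the only nitrogen-containing export — with extensive alanine/glutamate
cycling; with more oxygen it switches to succinate (one extra reductant
per carbon skeleton).  Knocking out alanine dehydrogenase
(`--variant aladh-ko`) forces nitrogen out as ammonia instead, keeps
alanine cycling one-for-one against glutamate, and raises the minimum
oxygen requirement by ~11 %.

As library calls:

```python
import numpy as np
from rhizoflux import fixtures as fx
from rhizoflux import apply_condition, nitrogen_source_scan

spec = fx.FixtureSpec()
plant = fx.build_mini_plant(spec)              # validates itself on build
night = apply_condition(plant, fx.night_condition())
scan = nitrogen_source_scan(
    night, total_n_flux=0.1 * spec.nitrogen_demand_per_gram,
    ammonium_fractions=np.linspace(0, 1, 21), growth=0.1,
    markers=fx.PLANT_SCAN_MARKERS)
print(scan.to_dataframe())
```

## Package layout

| module | contents |
| --- | --- |
| `rhizoflux.model` | metabolites, reactions, models, S-matrix assembly, mass/charge balance, validation |
| `rhizoflux.io` | SBML L3+FBC and tabular (TSV) model I/O, YAML condition/scan configs |
| `rhizoflux.engine` | FBA, quadratic flux minimisation, FVA, blocked-reaction detection (FASTCC), knockout screens, energy-cycle certification |
| `rhizoflux.fastcore` | expression-based core sets (GPR OR→max/AND→min) and FASTCORE extraction |
| `rhizoflux.compose` | tissue replication, inter-tissue linkers, combined biomass, symbiont attachment, conditions |
| `rhizoflux.experiments` | nitrogen/oxygen scans, symbiosis comparison, essentiality, carbon conversion |
| `rhizoflux.fixtures` | curated mini-plant and mini-bacteroid, random consistent networks |
| `rhizoflux.cli` | the `rhizoflux` command |

`fixtures/` holds the mini-models as reviewable TSV pairs (regenerate
with `rhizoflux make-fixtures`) and golden scan tables that regression-
lock the fixture behaviour.

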