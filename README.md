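# macpol

Mechanistic ODE simulation of dynamic macrophage M1–M2 polarization.

`macpol` implements a mass-action/Hill-kinetics simulation engine for
intracellular signaling networks, together with a curated reduced
seven-pathway macrophage reference network (IFNγ, TNFα, IL-1β, IL-4, IL-10,
VEGF receptor pathways plus oxygen sensing), stimulation/intervention
protocols, M1/M2 phenotype scoring, PRCC-based global sensitivity
screening, virtual-cell population analysis, and a calibration toolkit
(normalization conventions, least-squares fitting, bootstrap uncertainty,
synthetic-data generation).

State is expressed in copies per cell (dimensionless counts); time is in
hours. Reversible reactions are written as paired irreversible reactions.
Networks can be loaded from and written to a native JSON dialect or SBML
(Level 2/3 read, Level 3 Version 2 write); a published full-scale SBML
model can be loaded if supplied, but the package ships its own reduced
reference network (`src/macpol/data/reference_model.{json,xml}`) and does
not claim numerical identity with any external parameterization. The
nominal parameterization is desk-calibrated to reproduce documented
stimulus→target response directions and plausible time scales.

## Quick start (Python)

```python
from macpol import (build_reference_network, MarkerPanel, StimulationProtocol,
                    DoseEvent, simulate, score_trajectory)

doc = build_reference_network()
panel = MarkerPanel.from_dict(doc.annotations["marker_panel"])
proto = StimulationProtocol(events=[DoseEvent(0.0, "IFNG_ext", 10.0, "ng/mL")],
                            duration=48.0)
result = simulate(doc.network, proto)          # pre-equilibrates, then doses
traj = score_trajectory(result, panel, transform="log10")
print(traj.at(24.0))                           # log10 M1/M2 score at 24 h
```

## CLI

A single `macpol` entry point (each command writes a reproducibility
manifest `<out>.manifest.json` with seeds and input hashes):

```bash
macpol simulate --o2 2 --duration 48 --out traj.tsv      # hypoxia run
macpol map --out map.tsv                                 # 28 conditions x markers x {4,24,48} h
macpol scores --o2 2 --out scores.tsv                    # M1/M2 score trajectory
macpol classify --o2 2 --out class.json                  # trajectory class
macpol sensitivity --o2 2 --n 200 --seed 7 --out prcc.tsv
macpol vpop --n 100 --sigma 0.08 --seed 11 --o2 2 --out pop.tsv
macpol convert --in model.xml --out model.json           # SBML <-> native JSON
macpol make-fixtures --seed 1 --out fixtures.tsv         # synthetic datasets
macpol fit --model motif --data fixtures.tsv --free k_x:0.03:3 --out fit.json
macpol bootstrap --data fixtures.tsv --free k_x:0.03:3 --n-boot 10 --out boot.json
```

Example protocol YAMLs live in `examples/`.

## Package layout

| module | contents |
|---|---|
| `macpol.network` | species/reaction/parameter data model, rate laws, validation, conserved moieties |
| `macpol.engine` | compiled RHS + analytic Jacobian, pre-equilibration, event-driven stiff integration |
| `macpol.io` | native JSON and SBML read/write |
| `macpol.reference` | seven-pathway reference macrophage network, directional-response suite |
| `macpol.protocols` | doses (ng/mL → copies), oxygen scaling, interventions, HSS variants, in-vivo dilution |
| `macpol.scoring` | marker panels, fold changes, M1/M2 scores, polarization maps, trajectory/cell classification |
| `macpol.sensitivity` | Latin-hypercube sampling, PRCC with significance, sensitivity/intervention screens |
| `macpol.population` | virtual-cell generation, population simulation, phenotype fractions |
| `macpol.calibration` | normalization modes, weighted-SSE objective, multi-start fitting, bootstrap, synthetic datasets |
| `macpol.motifs` | small closed-form fixture networks used by tests and oracles |

## Conventions and defaults

- Doses are instantaneous boluses to extracellular species; `dose_to_copies`
  uses a default medium volume of 1e-6 mL per cell (≈10⁶ cells/mL culture),
  configurable per protocol. Shipped ligand molecular weights (Da):
  IFNγ 34 000 (active homodimer), TNFα 17 350 (monomer equivalents),
  IL-1β 17 400, IL-4 15 000, IL-10 37 000 (homodimer), VEGF165 38 700
  (homodimer) — textbook values, overridable per protocol.
- Oxygen enters the kinetics only through linear scaling of the
  PHD-mediated HIF-hydroxylation rate parameters (21 % → factor 1).
- M1/M2 score: geometric mean of marker fold changes per panel, ratio for
  M1/M2, normalized to 1 at t = 0; pluggable via `score_fn`.
- Trajectory classes use δ = 0.05 log10 units; single-cell phenotype labels
  use τ = 0.1 log10 units; both exposed as arguments.
- Virtual populations default to σ = 0.08 (log10) independent log-normal
  multipliers on all kinetic parameters, with resting-state acceptance
  within 20-fold of the reference baseline; by default every cell starts a
  protocol from the shared unpolarized baseline.
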