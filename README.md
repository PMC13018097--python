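# virowave

Models of oncolytic virotherapy with explicit viral dynamics, for tumours
with different motility rules:

- **abm** — a stochastic hybrid simulator: integer cancer-cell counts on a
  1D/2D lattice with probabilistic division, death, movement (undirected or
  pressure-driven), infection and lysis, coupled to a continuous viral
  concentration updated by an explicit balance equation forced by the
  sampled lysis counts.
- **pde** — explicit finite-difference solvers for the four continuum
  counterparts: reaction–diffusion (`U3`) and cross-diffusion (`P3`)
  systems with an explicit virus, and their quasi-steady two-species
  reductions (`U2`, `P2`), in 1D or radially symmetric 2D geometry.
  Cross-diffusion uses donor-cell upwinding on the shared pressure
  gradient; all transport is in conservative finite-volume form.
- **ode** — the non-spatial models, closed-form equilibria, linear
  stability, and a one-parameter Hopf-bifurcation scan in the viral burst
  size.
- **waves** — linear-spreading (pulled-front) speeds for the infection
  waves, front-density predictions, untreated-front speeds, and empirical
  front tracking on simulated trajectories.
- **outcome** — tumour/infection control probabilities: discrete fractions
  over seeded ensembles and their Poissonian counterparts from radial
  continuum solutions, plus the burst-size scan of maximal control
  probabilities.
- **core** — parameters, derived quantities (effective cell-to-cell
  infection rate, movement probability, matched pressure diffusivity),
  initial conditions, validation, and the configuration-file dialect.

## Command line

Every subcommand reads a flat INI-style config (bundled presets live in
`src/virowave/presets/`; resolve them with
`python -c "from virowave import preset_path; print(preset_path('table1'))"`).

```bash
virowave abm table1.cfg --seed 1 --replicates 5 --out runs/abm
virowave pde table1.cfg --model U3 --horizon 300 --out runs/pde
virowave wavespeed wavescan.cfg --out runs/waves   # c* vs q_v, three D_v
virowave ode-scan burstscan.cfg --out runs/ode     # bifurcation diagram
virowave tcp extinction2d.cfg --replicates 20 --out runs/tcp
virowave extinction-scan burstscan.cfg --out runs/scan
```

Each run writes its tabular artifacts (CSV) plus a `manifest.json` with the
fully resolved parameters, seeds and package version.

### Config dialect

Sections and keys (all optional, defaults are the reference values):

| section | keys |
|---|---|
| `[model]` | `p q q_v alpha beta D_U D_P D_v K movement dimension` |
| `[numerics]` | `tau delta dx dt L radial` |
| `[initial]` | `R_u R_v R_i V_0 u0_height i0_height` |
| `[run]` | `horizon record_every seed replicates model half_width alpha_values q_v_values D_v_values` |

Unknown keys are rejected by name. `movement` is `undirected` or
`pressure`; `dimension` is 1 or 2; list-valued keys take space- or
comma-separated numbers.

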