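# phsolv

Equilibrium analysis of solubility–pH profiles for ionizable drugs:

- a multi-species / multi-solid **speciation solver** (mass balances on the
  drug, phosphate and chloride, damped Newton on log concentrations,
  automatic solid-phase selection, self-consistent ionic-strength loop with
  Davies activity corrections and a neutral-drug salting-out term);
- **weighted nonlinear refinement** of intrinsic solubility, salt solubility
  products and self-aggregation constants from log S–pcH titration data,
  with goodness of fit and inverse-variance pooling across sets;
- **CMC estimation** from conductometric titrations by two-segment
  regression with bootstrap uncertainties;
- **solid-form assignment** of salt/base hydrates from observed C/H
  elemental percentages;
- a **synthetic-data generator** that forward-simulates titration sets and
  conductivity curves with the statistical structure the analysis assumes.

The bundled default model describes imipramine (a monoprotic base, pKa
9.52) in chloride and/or phosphate media, with hydrochloride and mono-/
di-basic phosphate salt solids, the free base solid, a cationic trimer and
heptamer, and a 1:1 cation–phosphoric-acid complex.  All constants are on
the concentration scale at a reference ionic strength of 0.15 mol/L.

## Library quick start

```python
import numpy as np
from phsolv import (build_default_model, MediumRecipe, simulate_logS_curve,
                    solve_equilibrium, compute_pHmax, refine, TitrationSet)

model = build_default_model()
recipe = MediumRecipe.from_weighed_solid(0.071, 1.0, "free_base",
                                         background_NaCl=1.70)
state = solve_equilibrium(recipe, model, pcH=3.0)
state.solids_present            # ('BHCl(s)',)
state.s_dissolved               # total dissolved drug, mol/L

curve = simulate_logS_curve(recipe, model, np.arange(2.6, 8.0, 0.1))
compute_pHmax(model, "B(s)", "BHCl(s)", {"Cl-": 1.70})   # 7.486
```

Synthetic data and refinement:

```python
from phsolv import builtin_design, make_titration_set
design = builtin_design("set5", seed=7)
tset = make_titration_set(design)
result = refine(tset, design.truth.updated(pKsp_BHCl=2.6),
                free=("pKsp_BHCl", "logK310", "logK750"))
result.estimates, result.sds, result.gof
```

## Command line

The `phsolv` entry point exposes `simulate`, `refine`, `pool`, `phmax`,
`cmc`, `synth` and `assign`:

```bash
phsolv simulate --set set5 --grid 2.6:8.0:0.1 --out curve.csv
phsolv synth --design set3 --seed 11 --out set3.csv
phsolv refine --obs set3.csv --set set3 --free pS0 --out refined.csv
phsolv pool --values 6.699,7.045,6.801 --sds 0.06,0.04,0.01
phsolv phmax --anchor Cl-=1.70
phsolv cmc cond.csv --boot 1000 --seed 7
phsolv assign --c 65.21 --h 7.65 --medium phosphate
```

Every command that writes an output file also writes a
`<out>.manifest.json` provenance record; all stochastic commands take
`--seed` and are bit-reproducible.  A custom constants/medium configuration
can be supplied with `--config` (YAML; see
`src/phsolv/data/imipramine_default.yaml` for the schema and the bundled
defaults).

## Layout

| module | contents |
| --- | --- |
| `phsolv.model_registry` | domain types, default drug model, validators |
| `phsolv.activity_ph` | ionic strength, Davies/salting-out activity model, constant rescaling, electrode map inversion |
| `phsolv.speciation` | equilibrium solver, solid-phase selection, log S curves, pHmax, reference curve |
| `phsolv.refinement` | weighted least squares, GOF, inverse-variance pooling |
| `phsolv.cmc_analysis` | segmented conductivity fit with bootstrap SD |
| `phsolv.solidstate` | formula parsing, elemental percentages, hydrate assignment |
| `phsolv.synthetic_data` | titration-set and conductivity-curve generators, bundled designs |
| `phsolv.cli_io` | file formats, configuration, CLI, manifests, plots |
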