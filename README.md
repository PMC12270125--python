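# qnmladder

Derive qualitative network models (QNMs) of graded complexity from a
mass-balanced food-web model, run matched press-perturbation scenarios
through both the quantitative parameter ensemble and the QNM ladder, and
score model-to-model agreement.

The pipeline has six stages:

1. **foodweb** — Ecopath-style snapshot (biomass, P/B, Q/B, diet matrix,
   catches, pedigrees) and the mass-balance solution: ecotrophic
   efficiencies plus per-pair mortality proportions.
2. **adjacency** — a consolidated strength per feeding pair
   (diet share − mortality share, in [−1, +1]); thresholding at
   0, 0.1, …, 0.5 yields a nested ladder of signed digraphs, each with a
   negative self-limiting loop on every node.
3. **qnm** — QPress-style analysis: sample community matrices with
   Uniform(0, 1] magnitudes, keep eigenvalue-stable draws, tally
   press-response signs (x = −A⁻¹p) over 1000 accepted samples.
4. **dynamics** — Ecosense-style quantitative counterpart: resample
   parameters from pedigree-width uniform priors, screen by a 50-year
   persistence run, then compare 100-year baselines against runs with a
   ten-year-ramped ±10% forced-biomass or forced-effort press (foraging-
   arena consumption, vulnerability 2; monthly RK4 with stiffness-based
   sub-stepping; ±2% cutoff for sign classes).
5. **compare** — 600/1000 majority-rule categories (positive, negative,
   neutral, mixed with optional lean), the ±1 / ±0.5 / 0 point scheme,
   and percent agreement between models.
6. **pipeline** — the full grid (scenario elements × directions ×
   [dynamic ensemble + six QNM rungs]) with tidy CSV outputs and a JSON
   run manifest.

`synthetic` generates balanced random webs with the right statistical
shape (Dirichlet diets, biomasses over orders of magnitude, one fleet,
one detritus pool), so everything is testable without external data.
Biomass accumulation, migration and imports are assumed zero.

## CLI

```sh
# balanced synthetic web as a CSV fixture
qnmladder generate-web --seed 7 --out webs/demo

# IN/OUT/ALL link counts across the threshold ladder
qnmladder table4 --web webs/demo

# full experiment from a YAML config
qnmladder run --config examples/config.yaml
```

Config schema (see `examples/config.yaml`): a `web` source (either
`fixture: <dir>` or `synthetic: {<WebSpec fields>}`), `scenario_elements`,
optional `directions`, `ladder_levels`, `n_sims`, `seed`, `out_dir`,
`run_dynamic`, `coupled_seeds`.

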