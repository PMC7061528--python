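# grn-landscape

Stochastic landscape analysis of a six-node cancer/EMT/stem-cell gene
regulatory circuit (P53, MDM2, ZEB, OCT4, miR-145, miR-200).

The model is simulated at single-binding-event resolution with an exact
Gillespie algorithm: every regulation is an explicit binding site whose
occupancy rescales the target's synthesis rate and sequesters the bound
multimer.  From pooled stationary statistics the package builds the
potential landscape `U = -ln P` over the (P53, ZEB, OCT4) marginal,
detects and labels attractor basins (normal, premalignant, cancer, SC,
CSC, lesion, hyperplasia), quantifies barrier heights via minimax-path
saddles, estimates mean first-passage times by direct first-passage
simulation, decomposes normal↔cancer transitions into route fluxes, and
scans regulation strengths for their effect on barrier topography.  A
synthetic-expression generator plus group-wise PCA / clustering stands in
for the bulk RNA-seq comparison.

## Layout

| module | role |
|--------|------|
| `grn_landscape.model` | network declaration, validation, rate laws, YAML config I/O |
| `grn_landscape.ssa` | exact SSA (reference path + numba kernels), ensembles, first-passage runs |
| `grn_landscape.cme` | truncated master-equation solver (testing oracle) |
| `grn_landscape.landscape` | `U = -ln P` grids, watershed basins, state labeling, projections |
| `grn_landscape.kinetics` | barrier matrix, MFPT estimates, barrier–time correlation, path flux |
| `grn_landscape.sensitivity` | one-at-a-time regulation-strength scans |
| `grn_landscape.synthexpr` | synthetic expression matrices, group-wise PCA, cluster/basin matching |
| `grn_landscape.pipeline` | end-to-end runs with caching and a provenance manifest |

## CLI

```bash
grn-landscape network validate                 # check the shipped default
grn-landscape network show                     # adjacency table (TSV)
grn-landscape simulate --t-max 100 --n-runs 4 --seed 1 --out traj.tsv
grn-landscape landscape --t-max 3000 --n-runs 20 --seed 1 --out landscape.h5
grn-landscape basins landscape.h5
grn-landscape barriers landscape.h5
grn-landscape mfpt --landscape landscape.h5 --from normal --to SC --n 8 --seed 1
grn-landscape flux --landscape landscape.h5 --direction reverse --seed 1
grn-landscape sensitivity --regulation 'miR200-|ZEB' --scales 0.8,1.0,1.5 --seed 1
grn-landscape synthdata --states 5 --n 40 --seed 1 --out expr.tsv
grn-landscape run configs/desk.yaml            # full pipeline, desk budget
```

`configs/paper.yaml` is the full-budget configuration (hours-scale);
`configs/desk.yaml` finishes in ~10 minutes on one CPU with the same basin
structure and noisier kinetic estimates.  The network file format is
documented in `docs/network_schema.md`.

## Reconstruction notes

The published model's per-site multimer orders, the 16th regulation and
the bimolecular volume normalization come from an unavailable supplement;
the shipped default network is a documented reconstruction (see
`docs/network_schema.md` and the per-edge orders in
`src/grn_landscape/data/default_network.yaml`).  All printed rate
parameters are used verbatim.  Basin labeling thresholds and the
nearest-signature option used by the pipeline are configurable
(`label_mode: exact` enforces strict signature matching).
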