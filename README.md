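# follisim

Multiscale simulation of CXCL13 chemokine gradients and B-cell migration in
the lymph-node primary follicle.

B cells searching for antigen navigate a dense network of CXCL13-secreting
stromal cells — CD21/35⁺ follicular dendritic cells (FDCs) in the follicle
core and CD21⁻ reticular cells (RCs) at the outer follicle and subcapsular
rim. Whether the guiding chemokine acts mostly as an ECM-immobilized, sharply
localized cue (model 1) or as a freely diffusing, near-homogeneous field
(model 2) changes how efficiently B cells scan the stromal network for
antigen. `follisim` is a tool for studying that question in silico, for
quantitative immunologists and systems biologists. It provides:

- **Network topology** (`follisim.topology`): clustering coefficients
  C_local and C_global, mean shortest path length L, and the small-world
  indices σ = (C/C_rand)/(L/L_rand) and ω = L_rand/L − C/C_latt against
  Erdős–Rényi G(n, m) and ring-lattice references, plus FDC-vs-RC
  degree/edge-length comparisons.
- **Network synthesis** (`follisim.synthesis`): a geometric generator that
  lays FDCs in a central core and RCs in the outer shell of a ~35 µm-thick
  follicle slab and wires neighbours within a connection radius; its defaults
  are calibrated so synthetic follicles match measured statistics
  (≈198 nodes, ≈1163 edges, C_local ≈ 0.60, C_global ≈ 0.57, L ≈ 4.17).
- **Chemokine field** (`follisim.field`): a finite-difference
  reaction–diffusion model ∂c/∂t = D∇²c + s − λc with optional reversible
  ECM immobilization, explicit time stepping and an exact sparse steady-state
  solver, with model-1 / model-2 parameterizations at equal total chemokine
  mass (D = 0.19 vs 1.6 µm² s⁻¹, the measured single-molecule medians).
- **B-cell agents** (`follisim.agents`): persistent random walks biased by
  receptor-level gradient sensing (differential CXCR5 occupancy across the
  cell body), three-pool receptor kinetics (free/bound/internalized), and
  stromal-contact logging.
- **Migration statistics** (`follisim.stats`): speed, meandering index,
  motility coefficient (MSD slope / 2·dim) and scanning rate (unique stromal
  nodes contacted · cell⁻¹ · h⁻¹).
- **Emulation + optimization** (`follisim.emulator`, `follisim.moea`):
  Latin-hypercube designs over the 13 simulation parameters, per-output
  feed-forward surrogates (13 inputs, three sigmoidal hidden layers, one
  output), and NSGA-II multiobjective search minimizing the error against
  measured migration statistics while maximizing scanning rate, with
  Vargha–Delaney A effect sizes and Pareto trade-off (conflict) analysis.
- **Spatial statistics** (`follisim.spatial`): Moran's I correlograms with
  permutation testing on binned intensity images and the decorrelation
  distance D_uncorrelated.
- **Single-molecule tracks** (`follisim.tracks`): per-track diffusion
  coefficients from short-lag MSD fits (four lags at 513 Hz), localization-
  noise handling, immobile/mobile fraction decomposition.

## Worked example

```python
from follisim import (SynthesisParams, synthesize_follicle_network,
                      topology_report, small_world_indices)
from follisim.experiments import scaled_down_config, run_model_comparison

net = synthesize_follicle_network(SynthesisParams(seed=7))
rep = topology_report(net)
sigma, omega = small_world_indices(net, n_null=20, seed=0)
print(rep.n_nodes, rep.n_edges)                      # 198 1206
print(rep.C_local, rep.C_global, rep.L)              # 0.583 0.560 4.269
print(sigma, omega)                                  # 5.40 -0.30

cmp = run_model_comparison(scaled_down_config(seed=1, replicates=50))
print(cmp["A_model1_vs_model2"])                     # 0.9968
print(cmp["scanning_rate"]["1"]["median"])           # 13.5 nodes/cell/h
print(cmp["scanning_rate"]["2"]["median"])           # 4.5 nodes/cell/h
```

The synthetic follicle reproduces the measured small-world topology: local
clustering ten times that of a matched random graph at only ~1.8× its path
length (σ ≈ 5.4; ω near 0 marks the small-world regime between random, +1,
and lattice, −1). In the model comparison, B cells on the immobilized
sharp-gradient field (model 1) scan a median 13.5 distinct stromal cells per
hour versus 4.5 on the equal-mass homogeneous field (model 2); the
Vargha–Delaney A of 0.997 far exceeds the 0.71 large-effect threshold —
local gradients act as guidance cues that funnel cells from stromal cell to
stromal cell, whereas a uniform chemokine bath provides no directional
information and chronically desensitizes CXCR5.

A command-line interface mirrors the library:

```sh
follisim synth --seed 3 --out follicle.graphml
follisim topology --in follicle.graphml --nulls 100 --seed 7 --out report.json
follisim field --net follicle.graphml --model 1 --out field.h5
follisim compare-models --seed 1 --replicates 50
follisim tracks --in tracks.csv --frame-rate 513 --out mobility.json
follisim autocorr --image intensity.csv --pixel-size 1.0 --perms 999 --seed 5
```

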