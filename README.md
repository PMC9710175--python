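# metapatch

Tools for studying ecological succession and the **competition–colonization
(CC) trade-off** in microbial metacommunities living in patchy, micron-scale
landscapes — the setting of microfluidic devices in which a fast-colonizing
species (an *E. coli*-like "fugitive") races a slower but competitively
superior species (a *P. aeruginosa*-like invader) across a linear chain of
85 habitat patches connected by narrow corridors.

The package has four coupled parts:

1. **Stochastic lattice model** (`metapatch.lattice`, `metapatch.phase`) —
   a spatially explicit interacting-particle model on a periodic 2D lattice.
   Each site is vacant (0), held by the superior competitor (1), by the fast
   colonizer (2), or by both, locked in an interference contest (mixed, `*`).
   The trade-off couples colonization rate β to interference-competitive
   weight ω through

   ω = e<sup>−αβ</sup>

   so a colonization difference Δβ = β₁ − β₂ biases the interference lottery
   against the colonizer by η = 1 / (1 + e<sup>−αΔβ</sup>).  Priority
   effects enter as a factor γ ∈ [0, 1] damping cross-colonization into
   occupied sites (γ = 1: none; γ = 0: full inhibition).  Phase scans over
   the (1 − Δβ) × γ plane label each cell *scramble*, *coexistence*,
   *interference* or *extinct*.
2. **Mean-field analogue** (`metapatch.meanfield`) — the classic
   hierarchical patch-occupancy ODE system, with the closed-form resident
   equilibrium 1 − δ/β and the invasion criterion
   β_col > β²_comp / δ checked against numerical integration.
3. **Occupancy pipeline** (`metapatch.pipeline`, `metapatch.geometry`) —
   converts two-channel fluorescence time-lapse stacks into per-patch
   occupancy tables: background correction, per-channel autofluorescence
   thresholds (mean + 3 SD of a cell-free control), strict binarization,
   and per-mask occupancy E_k(t), P_k(t) with the derived fractional
   occupancy Θ_k = P_k/(E_k + P_k), total occupancy Z_k, spatial averages
   Ē(t), P̄(t) and landscape-ensemble Θ(t).
4. **Community statistics & synthetic data** (`metapatch.stats`,
   `metapatch.synthetic`) — ecotope (patch/corridor, real or virtual)
   partitioning, per-ecotope Pearson-correlation distributions with a
   mixture-based bimodality verdict, community-state density maps over
   (1 − Θ, Z), hourly trajectory ensembles; plus a phenomenological
   succession generator (wave → growth → front → blockage) that emits exact
   ground truth and renders it into TIFF-ready image stacks so the entire
   measurement chain is testable without microscope data.

## Worked example

```python
import numpy as np
import metapatch as mp

# Interference lottery at a 20% colonization difference, trade-off strength 4
print(mp.lottery_bias(0.2, 4.0))          # 0.6899744811276125

# Lattice run at the interference-phase reference point
params = mp.TradeoffParams(alpha=4.0, delta_beta=0.2, gamma=0.8, delta=0.1)
config = mp.ModelConfig(width=50, height=50, burn_in=5000,
                        sample_steps=500, rng_seed=1)
traj = mp.simulate(params, config)
print(traj.mean_densities())              # (0.0000, 0.8727)
```

The lottery value 0.690 says the colonizer loses roughly 7 of 10 local
interference contests at Δβ = 0.2.  In the lattice run the colonizer is
driven extinct (⟨ρ_E⟩ = 0) while the competitor holds ~87% of sites —
the *interference* phase: with only a 20% damping of cross-colonization
(γ = 0.8), priority effects are too weak to shelter the colonizer.

Generating a synthetic landscape and recovering it through the imaging
pipeline:

```python
from metapatch import build_geometry, process_stack
from metapatch.synthetic import SyntheticParams, simulate_succession, render_images

geo = build_geometry("patchy", pixel_pitch=7.168)   # coarse, fast render
truth = simulate_succession(SyntheticParams(horizon=12.0), geo,
                            rng=np.random.default_rng(0))
stack, _ = render_images(truth, geo, rng=np.random.default_rng(1))
table = process_stack(stack, geo, background_radius=10)
print(np.abs(table.E - truth.E).mean())   # 0.0024
```

The mean absolute error of 0.0024 between measured and true occupancy is
dominated by pixel quantization — the thresholding recovers the rendered
pixels essentially exactly.

A command-line interface mirrors the library:

```bash
metapatch simulate   --seed 1 --lattice 50 --burn-in 5000 --out traj.csv
metapatch phase-scan --grid 11 --lattice 50 --out phases.csv
metapatch meanfield  --out meanfield.csv
metapatch synth      --kind patchy --landscapes 3 --seed 5 --out-dir synth/
metapatch occupancy  --images col.tif --images comp.tif --geometry geo.json --out occ.csv
metapatch stats      --tables occ.csv --ecotope corridor --out stats.csv
```

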