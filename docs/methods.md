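# Methods

## The stochastic lattice model

Sites of a `width × height` lattice with periodic boundaries hold one of
four states: vacant (0), superior competitor (1), fast colonizer (2), or
mixed (`*`, both species locked in an interference contest).  The update
scheme is asynchronous random-sequential: one **time step** is
`width·height` single-site update attempts at uniformly drawn sites.  An
attempt applies the kernel:

- **Vacant site.** Each species fires with probability β·f, where f is the
  fraction of the neighborhood (Chebyshev ball of radius r, default Moore
  r = 1, excluding the focal site; von Neumann available) singly occupied
  by that species.  Mixed neighbors contribute nothing: locked sites do not
  disperse.  If both fire in the same attempt, the winner is drawn
  proportional to the two firing weights (scramble lottery for vacancy).
- **Singly occupied site.** Dies with probability δ; otherwise it is
  invaded to the mixed state with probability γ·β_other·f_other.  γ is the
  priority-effect factor: earlier arrival reduces the opponent's effective
  cross-colonization.
- **Mixed site.** Resolves by the interference lottery: competitor with
  probability η, colonizer with 1 − η.  Mixed sites neither die nor emit
  colonizers while locked.

The trade-off curve ω = e^{−αβ} links colonization to interference
ability.  The lottery bias is the competitive-weight ratio
η = ω_comp / (ω_comp + ω_col) = 1/(1 + e^{−αΔβ}), which is 0.5 exactly at
Δβ = 0 for every α, increases with Δβ, and evaluates to 0.6900 at
Δβ = 0.2, α = 4.  The experimental companion value quoted for that setting
is 0.698; no variant of the weight form we examined (β², √β, rescaled α)
reproduces it, so the computed ratio is the default and `TradeoffParams.eta`
accepts an explicit override.

Defaults follow the reference protocol: α = 4, β_col ≡ 1, δ = 0.1,
100×100 lattice, 5 + 5 seeded sites, 10⁵ burn-in steps, 10³ sampling
steps.  Densities count mixed sites toward both species (switchable).
With δ > 0 on a finite lattice the all-vacant state is absorbing, so
"long-term" always means quasi-stationary averages over the sampling
window.

### Kernel-reconstruction knobs

The published description of the model leaves the lock duration, mixed-site
mortality and the symmetry of the γ damping open.  `ModelConfig` exposes
them:

- `lock_resolution` (default 1.0) — probability per selection that a mixed
  site resolves; smaller values give long interference locks.
- `mixed_mortality` (default False) — whether locked sites die at δ.
- `invasion_mode` (default `"symmetric"`) — `"shield_colonizer"` applies γ
  only to the competitor's invasion of colonizer-held sites, mirroring the
  experimental mechanism (colonizer aggregates jam corridors against the
  competitor specifically).

### Phase structure, and two reference points this kernel does not meet

`phase_scan` sweeps the (1 − Δβ) × γ plane, one quasi-stationary run per
cell, labels each cell by window-mean densities against the extinction
threshold ε (default 10⁻³, ≈10 sites on 100×100), and estimates critical
values (Δβ\*, Δβ\*\* on the γ = 1 row; γ_c on the near-neutral column) as
midpoints between differently labeled neighboring cells, quoting half the
grid spacing as resolution.

At desk scale (50×50, 2·10⁴ burn-in, 2·10³ sampling, α = 4, δ = 0.1,
r = 1) the kernel reproduces the interference reference point — at
(Δβ = 0.2, γ = 0.8) the competitor clears the colonizer from the lattice —
and the γ = 1 hierarchy ordering.  Two further reference behaviors are
**not** reproduced, and the corresponding tests are left failing rather
than weakened:

- *(Δβ = 0.2, γ = 0.3) coexistence.*  Along that transect the kernel shows
  founder control with a knife-edge at γ ≈ 0.17 (γ ≈ 0.6 under
  `shield_colonizer`): the colonizer wins below it, the competitor above
  it, with no wide band where both persist.  A mean-field computation shows
  why: both invasion conditions hinge on the same interference-flux bracket
  γ·β_comp·η − β_col·(1 − η), so the mutual-invasion band has width of
  order δ·Δβ — a few hundredths in γ — for *any* lottery bias.  Long
  interference locks and mixed-site mortality do not open it either.
- *Neutral balance at Δβ = 0, γ = 1.*  The symmetric model is voter-like;
  measured fixation times on 50×50 are below 2·10⁴ steps, so individual
  runs end with one species extinct and seed-averaged densities cannot
  balance to within 0.05 over five seeds.  The same marginality holds at
  100×100 over 10⁵ steps (consensus time ≈ N·ln N steps).

We conclude the original implementation must differ in a stabilizing
detail its published description does not pin down; the knobs above bound
the reconstruction space we explored.

## Mean-field patch-occupancy system

The hierarchical two-species system

dp_K/dt = β_comp·p_K(1 − p_K) − δ·p_K
dp_C/dt = β_col·p_C(1 − p_K − p_C) − δ·p_C − β_comp·p_K·p_C

is integrated with LSODA (rtol 10⁻⁸).  The resident equilibrium is
p_K\* = 1 − δ/β_comp and the colonizer invades iff β_col > β²_comp/δ;
δ = 0 leaves no vacancies and blocks invasion (a fixation warning is
raised).  At the lattice defaults (β_comp = 0.8, δ = 0.1) the criterion
requires β_col > 6.4, consistent with the interference outcome above.

## Occupancy pipeline

Frames are reduced to binary occupancy per channel:

1. **Background correction** — grayscale morphological opening with a flat
   square structuring element of side 2·radius + 1 (default radius 25 px,
   well above a cell footprint).  The opening is separable and O(n),
   tractable on full 14 000-pixel-long strips, and has the required
   envelope semantics: a uniform frame maps to zero, gradients are removed,
   compact peaks survive, and the operation is idempotent up to clipping.
2. **Threshold** — mean + k·SD (default k = 3) of a declared cell-free
   control sample (explicit pixel sample or the corrected first,
   pre-colonization frame).  An all-zero control yields threshold 0.
3. **Binarization** — a pixel is occupied iff strictly above the threshold.
4. **Mask occupancy** — occupied fraction of each patch/corridor ROI, in
   [0, 1] per channel by construction.

Derived quantities: Θ_k = P_k/(E_k + P_k) (missing — NaN, never 0 — when
E_k + P_k = 0, and excluded from averages), Z in both dialects (sum, range
[0, 2], and half-sum, range [0, 1]; the state maps use the half-sum),
spatial means over the 85 patches, and the landscape-ensemble
Θ(t) = ⟨P̄/(Ē + P̄)⟩ with empty landscape-time points excluded.  Channel →
species mapping is declared per stack, so green–red and red–green pairings
are both supported, and swapping the declaration swaps the E and P tables
exactly.

Geometry: patches are 100×100 μm, corridors 50×5 μm centered on the strip
axis, 85 motifs of 150 μm; the flat strip is 12750×100 μm.  The default
pixel pitch 0.896 μm reproduces the camera calibration (0.803 μm² pixels);
coarser pitches give scaled-down geometries used in tests (7.168 μm for
unit tests, 3.584 μm for the full-landscape round trip).  Virtual patch
and corridor masks tile the patchy footprint onto the flat strip so both
landscape kinds feed the same statistics.

## Community statistics

- **Ecotope partition**: one paired E/P series per (landscape, ecotope,
  index); counts are n_landscapes × 85 per kind (patch, corridor, virtual
  variants).
- **Pearson distributions**: standard correlation over the paired series,
  optionally windowed; zero-variance series yield missing values and are
  excluded.  Distributions are summarized by sample variance, adjusted
  Fisher–Pearson skewness, and a bimodality verdict from a 1- vs
  2-component Gaussian-mixture comparison: bimodal iff ΔBIC > 10 *and*
  Ashman's D > 2 *and* the minor component holds ≥ 1% of mass.  The two
  guard conditions keep skewed or heavy-tailed unimodal samples from
  qualifying; no dip-statistic alternative is provided (no suitable
  implementation among the package's dependencies).
- **State-density map**: 2D histogram (default 50×50 bins) of
  (1 − Θ, Z_half) per patch per landscape; empty patches are dropped, and
  bin counts conserve the retained sample count.
- **Trajectory ensemble**: hourly bins (⌊t/1 h⌋, half-open) of the
  landscape-mean colonizer share; at 10-min frames each hour collects six
  configurations per landscape (432 per bin for 72 landscapes, 20 736 over
  48 h before exclusions).

## Synthetic landscape generator

The generator is phenomenological — deliberately independent of the
lattice model — so pipeline validation does not circularly depend on the
model implementation.  Per landscape:

- the colonizer wave reaches patch k at k/wave_speed (12 patches/h: the
  chain is crossed in ~7 h) leaving occupancy 0.05, then grows
  logistically at 0.15 h⁻¹ toward carrying occupancy 0.8 (≈35% local
  occupancy ~15 h after inoculation);
- the competitor front enters after 12 h and advances at 10 patches/h,
  growing at 0.8 h⁻¹ toward 0.9 (shifted growth phases);
- each corridor is blocked with probability 0.03 by a colonizer aggregate
  that fills at 1.0 h⁻¹ toward 0.9; the front, on reaching a blocked
  corridor, breaks through after an exponential delay (mean 2 h) or never
  (20% of blockages), which fragments the landscape;
- succession: after the front arrives, colonizer occupancy decays at
  1.0 h⁻¹ toward a residual coexistence floor of 0.25 × carrying;
- unblocked corridors carry stochastic wave traffic (passage fraction 0.5
  of the adjacent patches, relative noise SD 1.0); occupancy jitter
  (SD 0.01) perturbs occupied ecotopes only — true zeros stay zero;
- rendering: per frame and channel, Gaussian autofluorescence background
  (mean 100, SD 5 a.u.) everywhere and +400 a.u. on
  round(occupancy·n_pixels) uniformly placed pixels per ROI.  The
  quantized occupancies are returned alongside the stack: they are the
  exact recoverable truth, and the pipeline recovers them with zero error
  in the noiseless limit and MAE ≪ 0.02 at default noise.

These defaults were chosen once, from the narrative timescales, and give:
ensemble Θ(t) rising to ~0.65–0.7 with a partial late relaxation when
blockage is enabled (monotone non-decreasing without it); a corridor
Pearson distribution whose main mode (noisy traffic, r ≈ −0.33) acquires a
clearly separated second mode exactly when blockage occurs (jammed
corridors hold an anti-phased colonizer plateau); and the three corner
states of the long-term community-state map under the matching regimes
(full succession → (0, 0.5); early permanent fragmentation → (1, ~0.45);
growth-free colonizer alone → (1, ε)).

What the generator does **not** emulate: sub-patch spatial structure,
traveling-wave mechanics (diffraction, reflection), cell-scale intensity
variation, photobleaching or drift.  Passing tests therefore validate the
measurement chain and the statistics layer, not any claim about real
microscopy data.

## Numerical and I/O choices

- Single seeded `numpy.random.Generator` per run, passed into the
  numba-compiled kernels; identical seeds give bit-identical grids,
  stacks and tables.  Phase scans spawn one child seed per grid cell.
- Tables are UTF-8 CSV with headers, `%.17g` floats and
  `float_precision="round_trip"` on read, so round trips are exact and
  missing Θ/r values survive as empty fields.
- Geometries serialize to JSON (ROI rectangles) or integer-coded label
  images; image stacks to multi-page TIFF (one file per channel).
- Scaled-down problem sizes used by the test suite: 50×50 lattice with
  2·10⁴ burn-in for phase points; 7.168 μm pitch for generator statistics
  (24-landscape ensembles); 3.584 μm pitch for the 85-patch, 288-frame
  pipeline round trip.

## Known limitations

- The lattice kernel is a reconstruction; see the phase-structure section
  for the two reference behaviors it does not reproduce and the bounded
  space of variants explored.
- The bimodality verdict depends on mixture-fit regularity; extremely
  small minor modes (<1% of series) can escape it.
- The corridor-traffic model is statistical, not mechanistic: corridor
  Pearson modes are designed signatures, and only their presence/absence
  logic (blockage ⇒ second mode) should be interpreted.
- Virtual masks assume the flat strip is pixel-aligned with the patchy
  motif grid; sub-pixel registration of real devices is out of scope.
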