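# Methods

## Model

`nscmigrate` simulates therapeutic neural stem cells (NSCs) as
independent agents on a voxel grid derived from volumetric image data.
Three mechanisms drive movement:

1. **Tract-following.** The structure tensor of the image — the
   Gaussian-smoothed outer product of the central-difference intensity
   gradient — supplies a per-voxel eigen-system.  Anisotropy is the
   coherence `((λ1−λ2)/(λ1+λ2))²` in 2-D and the fractional anisotropy
   of the three eigenvalues in 3-D; voxels with anisotropy `≥ ε_M`
   (inclusive) are white matter.  An agent on white matter steps a
   distance `d_w ψ_i` along the unit principal eigenvector, with the
   sign chosen to be consistent with its previous displacement
   (inertia); an exact zero inner product — including the first step —
   is broken by a fair coin.  Precomputed tensor fields (e.g. from
   DTI) can be supplied instead of an image, in which case the same
   eigen-system machinery applies.
2. **Grey-matter random walk.** Off the tracts an agent steps a fixed
   distance `d_g` in a direction drawn uniformly on the unit circle or
   sphere (Gaussian-normalize construction).
3. **Chemotaxis.** Tumors carry a static analytic chemoattractant
   profile `C(x) = (1 + Σ (x_k−c_k)²/σ_k²)^(−p)`; where the summed
   concentration is at least `ε_c`, the displacement gains
   `λ_c η_i ∇C(x)` with the analytic gradient.  The detection gate
   uses `C` itself, not `η_i C`: heterogeneous sensitivity scales the
   response, not the ability to sense.  Concentration is
   time-independent — uPA diffusion is assumed much slower than
   migration — and multiple sites combine by summation (physically
   additive secretion; a per-site maximum is available).

Arrival is first entry into a tumor's arrival region — an axis-aligned
closed box of half-widths 100 × 100 × 400 µm by default (a
200 × 200 × 800 µm tumor), or a disc of 100 µm radius in 2-D.  Arrived
agents are frozen ("stick" to the site) unless absorption is disabled;
arrival counts are cumulative either way.

Cell death, proliferation, cell–cell interaction, receptor dynamics
and tumor growth are deliberately outside the model.  All injected
cells survive, so absolute arrival percentages are upper bounds: only
a 10–20% post-injection survival fraction is typically reported in
vivo.

## Population stochasticity

Each agent draws two fixed traits at injection:

* speed factor `ψ ~ Beta(1, β_w)`, multiplied by `(1+β_w)/2`.  The
  rescaling pins the population mean at 1/2 for every `β_w ≥ 1`, so
  `β_w = 1` stays exactly uniform on [0, 1] while larger `β_w` lowers
  the median and creates a minority of fast cells with `ψ > 1` —
  migration speed heterogeneity with a conserved average.
* chemosensitivity factor `η ~ Beta(α_c, 1)` in [0, 1]; `α_c = 1` is
  uniform, large `α_c` approaches the deterministic limit `η = 1`.

Traits are per-cell, not per-step: the stochasticity models
heterogeneity within the population, not temporal noise.

## Parameters

| name | meaning | default | unit |
|------|---------|---------|------|
| `d_w` | max white-matter step | 2.75 (mid of 0.5–5) | px/step |
| `d_g` | grey-matter step | 2.55 (mid of 0.1–5) | px/step |
| `lambda_c` | chemosensitivity | 6.5 (mid of 3–10) | px/step |
| `beta_w` | speed-spread shape | 2.5 (mid of 1–4) | – |
| `alpha_c` | sensitivity shape | 3.0 (mid of 1–5) | – |
| `epsilon_M` | white-matter threshold | 0.4 | – |
| `epsilon_c` | detection threshold | 0.05 | – |
| `dt` | time step | 1/1000 | day |
| `n_steps` | horizon | 30 000 (30 days) | steps |
| `n_agents` | population | 1000 | cells |

Defaults are midpoints of the physiologically accepted ranges; the
anisotropy threshold 0.4 is the standard white-matter cut.  Step sizes
are pixels per step throughout; multiplying by `pixel_size / dt`
converts to µm/day (e.g. `d_w = 5` at 1.444 µm/px is 7.22 mm/day of
maximal tract speed).  `Δt` is bookkeeping only — dynamics are
per-step events; halving `Δt` without rescaling step sizes doubles
speed in physical units.

The verbal reading of `σ` as "the distance at which the substance has
halved" is exact only for `p = 1` (where `C(σ) = 1/2`); for other
exponents the formula is authoritative and `σ` is simply the decay
length scale.  Defaults: `p = 1`, `σ` twice the arrival extent,
`ε_c = 0.05`.

## Numerical choices

* **Lookup.** Agent positions are continuous in pixel units; masks and
  directions are read at the nearest voxel (half-up rounding).
  Interpolating a binary mask is ill-defined; trilinear interpolation
  of the direction (renormalized) is available as an option.
* **Smoothing.** Tensor components are smoothed with a Gaussian of 2 px
  by default; 0 disables smoothing.  Eigenvalues are clipped at zero
  (they are non-negative up to rounding, as the tensor is a smoothed
  outer product); voxels whose leading eigenvalue is below 1e−8 of the
  field maximum are numerically flat and get anisotropy 0 — without
  this floor, smoothing residue at ~1e−10 would classify empty regions
  as perfectly anisotropic.
* **Eigen ties** (`λ1 = λ2`): the eigensolver's leading column is
  used; such voxels are typically sub-threshold anyway.
* **Boundary.** A proposed step leaving the brain mask is rejected:
  white-matter steps flip their tract sign once (bounce), grey-matter
  steps resample the direction up to 10 times; failing that the agent
  stays put for the step.
* **Reproducibility.** One `numpy` generator seeded from the config
  drives every draw, agents update in index order, and trajectory
  files are written with `%.17g` (and re-read with round-trip float
  parsing), so a `(config, seed)` pair reproduces a run bit for bit.
* An optional isotropic Gaussian perturbation of white-matter steps
  (`wm_noise_sd`, default off) implements the noise term sometimes
  added to tract-following.

## Synthetic phantoms

Real diffusion-tensor atlases are large external data sets; the
`phantoms` module generates images with the one feature the simulator
needs — a connected high-anisotropy tract inside a low-anisotropy
brain mask — so the full image → tensor → classification → simulation
path is exercised end to end.

Tracts are *textured* bands: the intensity oscillates sinusoidally
along the tract axis inside a cosine-tapered band.  This makes the
dominant image gradient — and hence the principal eigenvector — point
along the tract, matching the diffusion-tensor convention that `e1` is
the fibre direction (a plain smooth ridge would put the dominant
gradient across the tract).  A small background noise floor (2% of
contrast) is essential: without it the faint envelope gradients at the
band skirt form spurious high-coherence shells oriented across the
tract.  Straight tracts end inside the brain with a smooth taper and
carry periodic sub-threshold gaps (4 px every 28 px by default),
mimicking the crossings and irregularities of real tracts; a porous
"speckle" mode makes thick bands with internal coherence holes.
Curved tracts are closed rings (tangent alignment within a few
degrees), and a crossing phantom has the mixed-orientation
low-coherence centre that real fibre crossings show.  A direct-tensor
phantom covers the precomputed-tensor input path.

Every generated phantom is verified before use: the tract centreline
(between gaps) must classify as white matter, the far background must
not (≤ 0.5% of voxels), and `uniform_grey` must contain none; a failed
check regenerates with doubled contrast and halved noise.

Packaged scenarios place tumors on a 160 × 160 (2-D) or 96 × 96 × 48
(3-D) straight-tract phantom at 13.5 µm/px: `near_tumor` just off the
tract downstream of the on-tract injection, `far_tumor` distant from
both tract and injection, `bilateral_tumors` mirrored about the
midline (reachable symmetrically from the peripheral injection), and a
`no_tumor` control.  Scenario defaults — `d_w = 5`, `d_g = 0.5`,
`λ_c = 6`, `β_w = 1`, `α_c = 3`, 1000 agents, 3000 steps (3 days) —
use the canonical fast-tract/slow-grey contrast with mid-range
chemotaxis; the chemoattractant decay length is widened to ~50 px so
the attractant is detectable across the small phantom brain.  The two
injection presets correspond to intracerebral-like (on-tract) and
intranasal-like (peripheral, off-tract) administration.

**What the phantoms do not emulate.**  They are not mouse anatomy: no
corpus callosum geometry, no dense multi-tract network, and — 
decisively — not the scale of a real atlas (thousands of pixels
across).  Passing phantom tests shows the mechanisms are implemented
correctly (tract following, chemotactic capture, dose–response,
reproducibility), not that anatomy-specific arrival percentages are
reproduced.

## A known qualitative limit of desk-scale phantoms

On real brain data, slowing the grey-matter speed (`d_g = 0.5` vs
`d_g = d_w = 5`) both shortens the median migration distance and keeps
a larger share of the population on white matter.  The median-distance
half of that contrast reproduces robustly on the phantoms.  The
white-matter-occupancy half does not, and the reason is structural: in
this update rule the time to *find* (and re-find) a tract scales as
`1/d_g²`, while the probability of sticking per encounter is at most
~2× better for slow cells, so on any closed, tract-sparse domain small
enough to simulate, fast grey walkers always accumulate on the tract
at least as strongly as slow ones.  Every escape channel that makes
`d_g` matter (tract ends, coherence gaps, curvature, white-step noise)
drains slow riders equally, because slow cells re-enter at the band
margin where they are promptly re-expelled, whereas fast cells re-enter
deep.  The real-brain behaviour lives in a regime the phantoms cannot
reach: an enormous domain far from capture equilibrium with a dense,
curved tract network.  The corresponding check in the test suite is
kept at its honest configuration and documents this expected failure;
treat phantom white-matter-occupancy comparisons across `d_g` values
with caution.

## Problem sizes

The test suite and the acceptance script run everything at reduced but
statistically meaningful sizes, chosen as the package's own defaults:
distribution checks at 10⁵ draws; the random-walk law with 10⁴ agents
for 500 steps on a 600² grid; the chemosensitivity dose response with
10 replicate populations of 1000 agents per `λ_c` level (3 simulated
days); scenario comparisons with 3 seeds.  The full 30-day default
horizon is available but not exercised in the automated checks.

## Limitations

* Independent agents: no crowding, no contact inhibition, no
  leader–follower behaviour.
* The chemoattractant field is static and analytic; no
  production–diffusion PDE, no receptor saturation.
* Nearest-voxel tissue lookup makes the effective tract boundary
  blocky at sub-pixel scales.
* Absolute arrival percentages ignore post-injection death and are
  upper bounds.
* Phantom geometry, not anatomy (see above).
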