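# nscmigrate

Agent-based simulation of therapeutic neural stem cell (NSC) migration
in anisotropic brain tissue, with tumor-directed chemotaxis and
population stochasticity.

Therapeutic NSCs injected into (or near) the brain home in on gliomas:
they migrate preferentially along white-matter tracts and climb
gradients of tumor-secreted chemoattractants such as urokinase
plasminogen activator (uPA).  How many cells reach a tumor depends
strongly on where they are administered (intracerebral vs intranasal
routes), where the tumor sits relative to the tracts, and how
heterogeneous the cell population is.  `nscmigrate` is a small, fully
reproducible simulator for exploring these questions on volumetric
image data or on built-in synthetic tissue phantoms, aimed at
mathematical-oncology modellers.

## Model

Tissue anisotropy is derived from a scalar image `I(x)` through the
structure tensor — the Gaussian-smoothed outer product of the intensity
gradient.  With eigenvalues `λ1 ≥ λ2 (≥ λ3)` and principal eigenvector
`e1`, the local anisotropy is the coherence `((λ1−λ2)/(λ1+λ2))²` in
2-D or the fractional anisotropy

    FA = sqrt(3/2) · ‖λ − λ̄‖ / ‖λ‖

in 3-D.  A voxel is white matter when the anisotropy is at least
`ε_M` (default 0.4).  Precomputed (e.g. DTI) tensor fields are accepted
directly.

Each of `N` agents moves once per time step `Δt` (default 1/1000 day):

    v = ± d_w ψ_i M_ev(x)   on white matter   (along the tract, the
                             sign chosen by inertia: consistent with
                             the previous displacement)
    v =   d_g ξ              on grey matter   (ξ uniform on the unit
                             circle / sphere)
    v ← v + λ_c η_i ∇C(x)    wherever C(x) ≥ ε_c

The chemoattractant concentration around a tumor at `c` is the static
analytic profile `C(x) = (1 + Σ_k (x_k−c_k)²/σ_k²)^(−p)`, summed over
sites.  Population heterogeneity enters through per-cell traits drawn
once at injection: a speed factor `ψ ~ Beta(1, β_w)` rescaled by
`(1+β_w)/2` (mean 1/2 for every `β_w`; exactly uniform at `β_w = 1`)
and a chemosensitivity factor `η ~ Beta(α_c, 1)`.  Agents entering a
tumor's arrival region (a 200 × 200 × 800 µm box by default) stick
there.  All step sizes are in pixels per step; reports convert to µm
via the pixel size.

## Worked example

Simulate 1,000 NSCs injected onto a white-matter tract of a synthetic
2-D brain phantom, with a tumor just off the tract:

```python
import numpy as np
from nscmigrate import run
from nscmigrate.metrics import (arrival_percentage,
                                percent_on_white_matter,
                                shortest_path_agent)
from nscmigrate.phantoms import make_scenario

scen = make_scenario("near_tumor", dim=2, rng=np.random.default_rng(11))
record = run(scen.config.replace(seed=42), scen.tissue, scen.chemo)

arr = arrival_percentage(record)
wm = percent_on_white_matter(record)
agent, _ = shortest_path_agent(record, site=0)
day = wm["time_days"]
print(f"arrived at the tumor by day 3: {arr['pct_arrived'].iloc[-1]:.1f}%")
print(f"on white matter at day 0.5:    {wm.loc[(day - 0.5).abs().idxmin(), 'pct_on_wm']:.1f}%")
print(f"shortest path to the tumor: agent #{agent}, {record.path_at_entry[agent, 0]:.0f} um")
```

prints

```
arrived at the tumor by day 3: 93.6%
on white matter at day 0.5:    9.2%
shortest path to the tumor: agent #408, 1989 um
```

93.6% of the dose reaches this well-placed tumor within three
simulated days; occupancy of the tract falls as cells are absorbed at
the (off-tract) tumor; the best-routed cell travelled just under 2 mm.
Identical `(config, seed)` pairs reproduce every number bit for bit.

The same workflow runs from the shell:

```bash
nscmigrate make-phantom --scenario near_tumor --shape 160,160 --seed 2 --out scen/
nscmigrate run --config scen/scenario.yaml --seed 42 --out out/
nscmigrate metrics --record out/trajectories.csv --out out2/   # identical metrics
nscmigrate field --input scen/phantom.npz --out maps/          # anisotropy + WM maps
```

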