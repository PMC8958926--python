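"""Agent-based migration engine.

Each agent (a therapeutic neural stem cell) advances once per time step
``dt`` (default 1/1000 day).  On white matter it moves a distance
``d_w * psi_i`` along the local principal direction, choosing the sign
consistent with its previous displacement (inertia); on grey matter it
takes an isotropic step of length ``d_g``.  Wherever the
chemoattractant concentration exceeds ``epsilon_c`` the displacement
``lambda_c * eta_i * grad C`` is appended.  Step sizes are in pixels
per step; multiply by ``pixel_size / dt`` for micrometres per day.

Population stochasticity: each agent carries a fixed speed factor
``psi_i`` drawn from a rescaled Beta(1, beta_w) (mean 1/2 for every
``beta_w``; exactly uniform on [0, 1] at ``beta_w = 1``) and a fixed
chemosensitivity factor ``eta_i ~ Beta(alpha_c, 1)``.

All randomness flows through one ``numpy.random.Generator`` seeded from
the config, and agents update in index order, so a (config, seed) pair
reproduces a run bit for bit.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as _dc_field

import numpy as np

from . import chemo as _chemo
from . import field as _field

__all__ = [
    "SimulationConfig",
    "AgentPopulation",
    "SimulationRecord",
    "sample_speed_factor",
    "sample_sensitivity_factor",
    "random_unit_vector",
    "initialize",
    "migration_step",
    "run",
]


@dataclass
class SimulationConfig:
    """Simulation parameters.

    Step sizes (``d_w``, ``d_g``, ``lambda_c``) are pixels per step;
    defaults are the midpoints of the accepted physiological ranges
    (d_w in [0.5, 5], d_g in [0.1, 5], lambda_c in [3, 10],
    beta_w in [1, 4], alpha_c in [1, 5]) with the white-matter
    anisotropy threshold fixed at 0.4.
    """

    d_w: float = 2.75
    d_g: float = 2.55
    lambda_c: float = 6.5
    beta_w: float = 2.5
    alpha_c: float = 3.0
    epsilon_M: float = 0.4
    epsilon_c: float = 0.05
    dt: float = 1.0 / 1000.0
    n_steps: int = 30_000
    n_agents: int = 1000
    injection_center: tuple | None = None
    injection_radius: float = 0.0
    seed: int = 0
    chemotaxis_absorb: bool = True
    wm_noise_sd: float = 0.0
    snapshot_stride: int | None = None
    max_reject_retries: int = 10

    def validate(self) -> None:
        checks = [
            ("d_w", self.d_w >= 0, ">= 0"),
            ("d_g", self.d_g >= 0, ">= 0"),
            ("lambda_c", self.lambda_c >= 0, ">= 0"),
            ("beta_w", self.beta_w >= 1, ">= 1"),
            ("alpha_c", self.alpha_c >= 1, ">= 1"),
            ("epsilon_M", 0 <= self.epsilon_M <= 1, "in [0, 1]"),
            ("epsilon_c", 0 < self.epsilon_c < 1, "in (0, 1)"),
            ("dt", self.dt > 0, "> 0"),
            ("n_steps", self.n_steps >= 0, ">= 0"),
            ("n_agents", self.n_agents >= 1, ">= 1"),
            ("injection_radius", self.injection_radius >= 0, ">= 0"),
            ("wm_noise_sd", self.wm_noise_sd >= 0, ">= 0"),
        ]
        for key, ok, msg in checks:
            if not ok:
                raise ValueError(
                    f"{key}: must be {msg} (got {getattr(self, key)!r})")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["injection_center"] is not None:
            d["injection_center"] = [float(v) for v in d["injection_center"]]
        return d


@dataclass
class AgentPopulation:
    """State of the N agents.

    ``arrived_step[i]`` is the step of first entry into any arrival
    region (-1 if never) and ``arrived_site[i]`` the site index;
    ``first_entry_step[i, s]`` tracks per-site first entries.
    ``path_length`` is the cumulative travelled distance in
    micrometres.
    """

    pos: np.ndarray                # (N, d) pixels
    prev_pos: np.ndarray           # (N, d)
    speed_factor: np.ndarray       # (N,) psi
    sens_factor: np.ndarray        # (N,) eta
    arrived_step: np.ndarray       # (N,) int, -1 = not arrived
    arrived_site: np.ndarray       # (N,) int, -1 = none
    path_length: np.ndarray        # (N,) um
    first_entry_step: np.ndarray   # (N, n_sites) int
    path_at_entry: np.ndarray      # (N, n_sites) um at first entry

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    @property
    def arrived(self) -> np.ndarray:
        return self.arrived_step >= 0


@dataclass
class SimulationRecord:
    """Everything needed to recompute the readouts of a run."""

    config: dict
    seed: int
    pixel_size: float
    injection_center: np.ndarray
    snapshot_steps: np.ndarray       # (S,)
    snapshots: np.ndarray            # (S, N, d) pixels
    on_wm_snapshots: np.ndarray      # (S, N) bool
    wm_count: np.ndarray             # (n_steps + 1,)
    arrival_counts: np.ndarray       # (n_steps + 1, n_sites) cumulative
    arrived_step: np.ndarray         # (N,)
    arrived_site: np.ndarray         # (N,)
    first_entry_step: np.ndarray     # (N, n_sites)
    path_at_entry: np.ndarray        # (N, n_sites) um
    path_length: np.ndarray          # (N,) um final
    speed_factor: np.ndarray         # (N,)
    sens_factor: np.ndarray          # (N,)

    @property
    def n_agents(self) -> int:
        return self.snapshots.shape[1]

    @property
    def n_steps(self) -> int:
        return len(self.wm_count) - 1

    @property
    def dt(self) -> float:
        return float(self.config.get("dt", 1e-3))

    def to_dataframe(self):
        """Long-format trajectory table (step, agent_id, coords, flags)."""
        import pandas as pd

        S, N, d = self.snapshots.shape
        cols = "xyz"[:d]
        rec = {
            "step": np.repeat(self.snapshot_steps, N),
            "agent_id": np.tile(np.arange(N), S),
        }
        for k, c in enumerate(cols):
            rec[c] = self.snapshots[:, :, k].ravel()
        rec["on_wm"] = self.on_wm_snapshots.ravel().astype(int)
        arrived_site = np.tile(self.arrived_site, S)
        arrived_step = np.tile(self.arrived_step, S)
        step_col = rec["step"]
        shown = (arrived_step >= 0) & (arrived_step <= step_col)
        rec["arrived_site"] = np.where(shown, arrived_site, -1)
        return pd.DataFrame(rec)


def sample_speed_factor(beta_w: float, n: int, rng: np.random.Generator
                        ) -> np.ndarray:
    """Per-agent speed factors: rescaled Beta(1, beta_w) draws.

    Draws are multiplied by ``(1 + beta_w) / 2`` so the population mean
    is 1/2 for every ``beta_w``; ``beta_w = 1`` stays exactly uniform
    on [0, 1], while larger ``beta_w`` lowers the median and produces
    fast outliers above 1.
    """
    if beta_w < 1:
        raise ValueError(f"beta_w: must be >= 1 (got {beta_w!r})")
    return rng.beta(1.0, beta_w, size=n) * (1.0 + beta_w) / 2.0


def sample_sensitivity_factor(alpha_c: float, n: int,
                              rng: np.random.Generator) -> np.ndarray:
    """Per-agent chemosensitivity factors ``eta ~ Beta(alpha_c, 1)``.

    ``alpha_c = 1`` spreads sensitivity uniformly over [0, 1]; large
    ``alpha_c`` concentrates it at 1 (nearly deterministic).
    """
    if alpha_c < 1:
        raise ValueError(f"alpha_c: must be >= 1 (got {alpha_c!r})")
    return rng.beta(alpha_c, 1.0, size=n)


def random_unit_vector(dim: int, rng: np.random.Generator,
                       n: int | None = None) -> np.ndarray:
    """Uniform random directions on the unit circle / sphere."""
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    size = 1 if n is None else n
    v = rng.standard_normal((size, dim))
    norm = np.linalg.norm(v, axis=1, keepdims=True)
    # a numerically-zero Gaussian draw is astronomically unlikely; redraw
    while np.any(norm < 1e-12):  # pragma: no cover
        bad = norm[:, 0] < 1e-12
        v[bad] = rng.standard_normal((int(bad.sum()), dim))
        norm = np.linalg.norm(v, axis=1, keepdims=True)
    v /= norm
    return v[0] if n is None else v


def initialize(config: SimulationConfig, tissue: _field.TissueField,
               rng: np.random.Generator | None = None,
               n_sites: int = 0) -> AgentPopulation:
    """Place agents uniformly in the injection ball, inside the brain.

    Positions are rejection-sampled from the ball of
    ``injection_radius`` around ``injection_center`` intersected with
    the brain mask; per-agent traits psi and eta are drawn once.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d = tissue.ndim
    if config.injection_center is None:
        raise ValueError("injection_center: must be set")
    center = np.asarray(config.injection_center, dtype=float)
    if center.shape != (d,):
        raise ValueError(
            f"injection_center: expected {d} coordinates, got {center.shape}")
    n = config.n_agents
    radius = config.injection_radius

    if radius == 0:
        _, _, inb = _field.lookup(tissue, center[None, :])
        if not inb[0]:
            raise ValueError("injection site lies outside the brain mask")
        pos = np.tile(center, (n, 1))
    else:
        pos = np.empty((n, d))
        have = 0
        attempts = 0
        while have < n:
            m = max(n - have, 256)
            u = rng.random(m) ** (1.0 / d)
            cand = center + random_unit_vector(d, rng, m) * (radius * u)[:, None]
            _, _, inb = _field.lookup(tissue, cand)
            cand = cand[inb]
            take = min(len(cand), n - have)
            pos[have:have + take] = cand[:take]
            have += take
            attempts += 1
            if attempts > 1000 and have == 0:
                raise ValueError(
                    "injection region entirely outside the brain mask")
    psi = sample_speed_factor(config.beta_w, n, rng)
    eta = sample_sensitivity_factor(config.alpha_c, n, rng)
    return AgentPopulation(
        pos=pos,
        prev_pos=pos.copy(),
        speed_factor=psi,
        sens_factor=eta,
        arrived_step=np.full(n, -1, dtype=np.int64),
        arrived_site=np.full(n, -1, dtype=np.int64),
        path_length=np.zeros(n),
        first_entry_step=np.full((n, max(n_sites, 0)), -1, dtype=np.int64),
        path_at_entry=np.full((n, max(n_sites, 0)), np.nan),
    )


def _step_parts(pos, prev_pos, psi, eta, tissue, cf, config, rng):
    """Proposed displacement split into directed/random/chemo parts.

    Returns (base, chemo_term, is_white, sign) where base is the
    tissue-driven displacement and sign the chosen tract orientation
    (0 for grey agents).
    """
    n, d = pos.shape
    is_white, mev, _ = _field.lookup(tissue, pos)
    base = np.zeros((n, d))
    sign = np.zeros(n)

    if np.any(is_white):
        ip = np.einsum("ij,ij->i", (pos - prev_pos)[is_white], mev[is_white])
        s = np.sign(ip)
        ties = s == 0
        if np.any(ties):
            s[ties] = rng.integers(0, 2, size=int(ties.sum())) * 2.0 - 1.0
        step_w = (s * config.d_w * psi[is_white])[:, None] * mev[is_white]
        if config.wm_noise_sd > 0:
            step_w = step_w + config.wm_noise_sd * rng.standard_normal(
                step_w.shape)
        base[is_white] = step_w
        sign[is_white] = s

    grey = ~is_white
    if np.any(grey):
        xi = random_unit_vector(d, rng, int(grey.sum()))
        base[grey] = config.d_g * xi

    chemo_term = np.zeros((n, d))
    if cf is not None and cf.n_sites > 0 and config.lambda_c > 0:
        c = _chemo.concentration(cf, pos)
        sensing = np.atleast_1d(c) >= config.epsilon_c
        if np.any(sensing):
            g = _chemo.gradient(cf, pos[sensing])
            chemo_term[sensing] = (config.lambda_c
                                   * eta[sensing, None]) * g
    return base, chemo_term, is_white, sign


def migration_step(pos, prev_pos, psi, eta, tissue, cf, config, rng
                   ) -> np.ndarray:
    """Proposed per-agent displacement for one time step.

    White-matter agents move ``sign * d_w * psi`` along the principal
    direction with the sign set by inertia (random on ties); grey-
    matter agents take ``d_g`` times a random unit vector; the
    chemotactic term ``lambda_c * eta * grad C`` is added wherever
    ``C >= epsilon_c``.  Boundary handling is applied by :func:`run`.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    prev_pos = np.atleast_2d(np.asarray(prev_pos, dtype=float))
    psi = np.atleast_1d(np.asarray(psi, dtype=float))
    eta = np.atleast_1d(np.asarray(eta, dtype=float))
    base, chemo_term, _, _ = _step_parts(
        pos, prev_pos, psi, eta, tissue, cf, config, rng)
    return base + chemo_term


def _advance(pop: AgentPopulation, tissue, cf, config, rng,
             active: np.ndarray) -> None:
    """One in-place update of all active agents with boundary rejection.

    A proposed step leaving the brain mask is retried: white-matter
    steps flip their tract sign once, grey-matter steps resample the
    random direction up to ``max_reject_retries`` times; if still
    outside, the agent stays put for this step.
    """
    if not np.any(active):
        pop.prev_pos[...] = pop.pos
        return
    idx = np.flatnonzero(active)
    pos = pop.pos[idx]
    base, chemo_term, is_white, _ = _step_parts(
        pos, pop.prev_pos[idx], pop.speed_factor[idx],
        pop.sens_factor[idx], tissue, cf, config, rng)
    disp = base + chemo_term
    new = pos + disp
    _, _, ok = _field.lookup(tissue, new)

    bad_white = ~ok & is_white
    if np.any(bad_white):
        flipped = pos[bad_white] - base[bad_white] + chemo_term[bad_white]
        _, _, ok_f = _field.lookup(tissue, flipped)
        new[bad_white] = np.where(ok_f[:, None], flipped, pos[bad_white])
        ok[bad_white] = True  # resolved: either flipped or stayed

    bad_grey = ~ok & ~is_white
    retry = np.flatnonzero(bad_grey)
    tries = 0
    while retry.size and tries < config.max_reject_retries:
        xi = random_unit_vector(pos.shape[1], rng, retry.size)
        cand = pos[retry] + config.d_g * xi + chemo_term[retry]
        _, _, ok_r = _field.lookup(tissue, cand)
        new[retry[ok_r]] = cand[ok_r]
        retry = retry[~ok_r]
        tries += 1
    if retry.size:
        new[retry] = pos[retry]  # stay put

    pop.prev_pos[idx] = pop.pos[idx]
    pop.pos[idx] = new
    seg = np.linalg.norm(new - pos, axis=1) * tissue.pixel_size
    pop.path_length[idx] += seg


def _record_arrivals(pop: AgentPopulation, cf, pixel_size: float,
                     step: int) -> None:
    if cf is None or cf.n_sites == 0:
        return
    inside = _chemo.in_tumor_sites(cf, pop.pos, pixel_size)
    fresh = inside & (pop.first_entry_step < 0)
    if np.any(fresh):
        ai, si = np.nonzero(fresh)
        pop.first_entry_step[ai, si] = step
        pop.path_at_entry[ai, si] = pop.path_length[ai]
        newly = (pop.arrived_step < 0) & fresh.any(axis=1)
        if np.any(newly):
            pop.arrived_step[newly] = step
            pop.arrived_site[newly] = np.argmax(fresh[newly], axis=1)


def run(config: SimulationConfig, tissue: _field.TissueField,
        cf: _chemo.ChemoField | None = None) -> SimulationRecord:
    """Run the full seeded simulation loop.

    Agents are initialized in the injection region, stepped
    ``n_steps`` times, and (by default) frozen once they enter a tumor
    arrival region.  Snapshots and per-step series are recorded;
    identical (config, seed) pairs give bit-identical records.
    """
    config.validate()
    if cf is not None and cf.n_sites > 0 and cf.ndim != tissue.ndim:
        raise ValueError(
            f"dimension mismatch: tissue is {tissue.ndim}-D, "
            f"chemo field is {cf.ndim}-D")
    rng = np.random.default_rng(config.seed)
    n_sites = cf.n_sites if cf is not None else 0
    pop = initialize(config, tissue, rng, n_sites=n_sites)
    n, d = pop.pos.shape
    n_steps = config.n_steps
    stride = config.snapshot_stride or max(1, n_steps // 120)

    snap_steps = sorted(set(range(0, n_steps + 1, stride)) | {n_steps})
    snap_set = {s: k for k, s in enumerate(snap_steps)}
    snapshots = np.empty((len(snap_steps), n, d))
    on_wm_snap = np.zeros((len(snap_steps), n), dtype=bool)
    wm_count = np.zeros(n_steps + 1, dtype=np.int64)
    arrival_counts = np.zeros((n_steps + 1, n_sites), dtype=np.int64)

    _record_arrivals(pop, cf, tissue.pixel_size, 0)

    def _bookkeep(step: int) -> None:
        on_wm, _, _ = _field.lookup(tissue, pop.pos)
        wm_count[step] = int(on_wm.sum())
        if n_sites:
            arrival_counts[step] = (pop.first_entry_step >= 0).sum(axis=0)
        if step in snap_set:
            k = snap_set[step]
            snapshots[k] = pop.pos
            on_wm_snap[k] = on_wm

    _bookkeep(0)
    for step in range(1, n_steps + 1):
        if config.chemotaxis_absorb:
            active = pop.arrived_step < 0
        else:
            active = np.ones(n, dtype=bool)
        _advance(pop, tissue, cf, config, rng, active)
        _record_arrivals(pop, cf, tissue.pixel_size, step)
        _bookkeep(step)

    return SimulationRecord(
        config=config.to_dict(),
        seed=config.seed,
        pixel_size=tissue.pixel_size,
        injection_center=np.asarray(config.injection_center, dtype=float),
        snapshot_steps=np.asarray(snap_steps, dtype=np.int64),
        snapshots=snapshots,
        on_wm_snapshots=on_wm_snap,
        wm_count=wm_count,
        arrival_counts=arrival_counts,
        arrived_step=pop.arrived_step.copy(),
        arrived_site=pop.arrived_site.copy(),
        first_entry_step=pop.first_entry_step.copy(),
        path_at_entry=pop.path_at_entry.copy(),
        path_length=pop.path_length.copy(),
        speed_factor=pop.speed_factor.copy(),
        sens_factor=pop.sens_factor.copy(),
    )
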