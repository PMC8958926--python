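"""Analytic chemoattractant field around tumor sites.

Glioma overexpress urokinase plasminogen activator (uPA), which
therapeutic neural stem cells sense and climb.  The concentration
around a tumor centred at ``c`` is modelled as the static rational
profile::

    C(x) = (1 + (x-cx)^2/sx^2 + (y-cy)^2/sy^2 + (z-cz)^2/sz^2) ** -p

so ``C = 1`` at the centre and decays algebraically with half-decay
distances ``(sx, sy, sz)`` (exact halving at one sigma when p = 1) and
decay exponent ``p``.  Fields from several sites are combined by
summation (configurable to per-site maximum).  The gradient is
analytic, so chemotaxis needs no grid discretisation of C.
"""

from __future__ import annotations

from dataclasses import dataclass, field as _dc_field

import numpy as np

__all__ = ["TumorSite", "ChemoField", "concentration", "gradient",
           "in_tumor", "in_tumor_sites"]

#: default arrival-region half-widths, micrometres (a 200 x 200 x 800 box)
DEFAULT_EXTENT_UM = (100.0, 100.0, 400.0)


@dataclass
class TumorSite:
    """A tumor: chemoattractant source plus an arrival region.

    ``center`` and ``half_decay`` are in pixels; ``extent_um`` are the
    axis-aligned half-widths (micrometres) of the box in which an agent
    counts as arrived.  In 2-D an ``arrival_radius_um`` disc is used
    instead when set (default 100 um).
    """

    center: np.ndarray
    half_decay: np.ndarray | None = None
    decay_power: float = 1.0
    extent_um: np.ndarray | None = None
    arrival_radius_um: float | None = None

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        d = self.center.shape[0]
        if d not in (2, 3):
            raise ValueError("tumor center must be 2-D or 3-D")
        if self.extent_um is None:
            self.extent_um = np.asarray(DEFAULT_EXTENT_UM[:d])
        else:
            self.extent_um = np.asarray(self.extent_um, dtype=float)[:d]
        if self.half_decay is None:
            # default: twice the arrival extent, converted by the caller
            self.half_decay = 2.0 * self.extent_um.copy()
        else:
            self.half_decay = np.broadcast_to(
                np.asarray(self.half_decay, dtype=float), (d,)).copy()
        if np.any(self.half_decay <= 0):
            raise ValueError("half_decay must be positive")
        if self.decay_power <= 0:
            raise ValueError("decay_power must be positive")
        if np.any(self.extent_um <= 0):
            raise ValueError("extent_um must be positive")
        if d == 2 and self.arrival_radius_um is None:
            self.arrival_radius_um = 100.0

    @property
    def ndim(self) -> int:
        return self.center.shape[0]


@dataclass
class ChemoField:
    """Collection of tumor sites with the detection threshold."""

    sites: list[TumorSite] = _dc_field(default_factory=list)
    epsilon_c: float = 0.05
    combine: str = "sum"

    def __post_init__(self) -> None:
        if not 0.0 < self.epsilon_c < 1.0:
            raise ValueError("epsilon_c must be in (0, 1)")
        if self.combine not in ("sum", "max"):
            raise ValueError("combine must be 'sum' or 'max'")
        dims = {s.ndim for s in self.sites}
        if len(dims) > 1:
            raise ValueError("all tumor sites must share dimensionality")

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def ndim(self) -> int | None:
        return self.sites[0].ndim if self.sites else None


def _site_u(site: TumorSite, pos: np.ndarray) -> np.ndarray:
    diff = (pos - site.center) / site.half_decay
    return 1.0 + np.sum(diff * diff, axis=-1)


def concentration(cf: ChemoField, pos) -> float | np.ndarray:
    """Chemoattractant concentration at one or more positions."""
    pos = np.asarray(pos, dtype=float)
    single = pos.ndim == 1
    pos2 = np.atleast_2d(pos)
    if not cf.sites:
        out = np.zeros(pos2.shape[0])
        return float(out[0]) if single else out
    per_site = np.stack([_site_u(s, pos2) ** (-s.decay_power)
                         for s in cf.sites], axis=0)
    out = per_site.sum(axis=0) if cf.combine == "sum" else per_site.max(axis=0)
    return float(out[0]) if single else out


def gradient(cf: ChemoField, pos) -> np.ndarray:
    """Analytic gradient of the concentration field.

    For each site ``grad C = -2 p u**-(p+1) (x - c) / sigma**2``, which
    points toward the centre; combined consistently with
    ``ChemoField.combine``.
    """
    pos = np.asarray(pos, dtype=float)
    single = pos.ndim == 1
    pos2 = np.atleast_2d(pos)
    d = pos2.shape[1]
    if not cf.sites:
        out = np.zeros((pos2.shape[0], d))
        return out[0] if single else out
    grads = []
    concs = []
    for s in cf.sites:
        u = _site_u(s, pos2)
        concs.append(u ** (-s.decay_power))
        coef = -2.0 * s.decay_power * u ** (-(s.decay_power + 1.0))
        grads.append(coef[:, None] * (pos2 - s.center) / s.half_decay ** 2)
    grads = np.stack(grads, axis=0)
    if cf.combine == "sum":
        out = grads.sum(axis=0)
    else:
        winner = np.argmax(np.stack(concs, axis=0), axis=0)
        out = np.take_along_axis(grads, winner[None, :, None], axis=0)[0]
    return out[0] if single else out


def in_tumor_sites(cf: ChemoField, pos, pixel_size: float) -> np.ndarray:
    """Boolean (N, n_sites) membership of positions in arrival regions.

    3-D sites use the closed axis-aligned extent box; 2-D sites with an
    ``arrival_radius_um`` use a closed disc.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    n = pos.shape[0]
    out = np.zeros((n, cf.n_sites), dtype=bool)
    for k, s in enumerate(cf.sites):
        delta_um = np.abs(pos - s.center) * pixel_size
        if s.ndim == 2 and s.arrival_radius_um is not None:
            out[:, k] = np.sum(delta_um ** 2, axis=-1) <= s.arrival_radius_um ** 2
        else:
            out[:, k] = np.all(delta_um <= s.extent_um, axis=-1)
    return out


def in_tumor(cf: ChemoField, pos, pixel_size: float) -> bool | np.ndarray:
    """True where a position lies inside any site's arrival region."""
    single = np.asarray(pos).ndim == 1
    hit = in_tumor_sites(cf, pos, pixel_size).any(axis=1)
    return bool(hit[0]) if single else hit
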