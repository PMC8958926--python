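"""Synthetic tissue phantoms and packaged test scenarios.

Real mouse diffusion-tensor atlases are large external datasets; these
phantoms emulate the single feature of them that the simulator relies
on: a connected high-anisotropy tract embedded in low-anisotropy
tissue inside a brain mask.

Tracts are generated as *textured* bands: the intensity oscillates
sinusoidally along the tract axis inside a Gaussian-profiled band, so
the image gradient -- and hence the principal eigenvector of the
structure tensor -- points along the tract.  (For a plain smooth ridge
the dominant gradient would be perpendicular to it; the sinusoidal
texture is what makes the intensity-image path reproduce the
diffusion-tensor convention that ``e1`` is the fibre direction.)
Every phantom is verified after generation: the tract centreline must
classify as white matter and the background must not; if the check
fails the phantom is regenerated with stronger contrast and less
noise.

A direct-tensor phantom is also provided to exercise the precomputed-
tensor input path.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import field as _field
from .chemo import ChemoField, TumorSite
from .engine import SimulationConfig

__all__ = ["PhantomSpec", "Scenario", "make_phantom", "make_tensor_phantom",
           "make_scenario", "SCENARIO_NAMES"]

KINDS = ("uniform_grey", "straight_tract", "curved_tract", "two_tract_cross")
SCENARIO_NAMES = ("near_tumor", "far_tumor", "bilateral_tumors", "no_tumor")


@dataclass
class PhantomSpec:
    """Recipe for a synthetic tissue image.

    ``tract_width`` is the full width of the band in pixels,
    ``contrast`` the texture amplitude relative to a unit background,
    ``noise_sd`` the s.d. of additive background noise and
    ``texture_period`` the wavelength (pixels) of the along-tract
    intensity oscillation.  ``brain_axes`` are the semi-axes of the
    elliptical / ellipsoidal brain mask (default 0.47 * shape).
    """

    shape: tuple
    kind: str = "straight_tract"
    tract_width: float = 6.0
    contrast: float = 1.0
    #: background intensity noise; by default 2% of contrast for tract
    #: kinds (it suppresses spurious coherence at the band skirt, where
    #: the envelope gradient would otherwise mimic a perpendicular
    #: tract) and 0 for uniform_grey
    noise_sd: float | None = None
    texture_period: float = 8.0
    brain_axes: tuple | None = None
    pixel_size: float = 13.5
    smoothing_sigma: float = 2.0
    epsilon_M: float = 0.4
    #: tract half-length as a fraction of the first brain semi-axis;
    #: straight tracts end inside the brain (as real tracts do), so
    #: agents reaching an end spill into grey matter
    tract_extent: float = 0.62
    #: spacing and width (pixels) of periodic sub-threshold gaps along
    #: straight tracts, mimicking the crossings and irregularities of
    #: real tracts where coherence dips below the white-matter
    #: threshold.  Gaps are what make grey-matter speed matter for
    #: tract retention: slow cells crawl across and resume riding,
    #: fast cells catapult off.  None disables gaps.
    gap_spacing: float | None = 28.0
    gap_width: float = 4.0
    #: in-band noise relative to contrast; > 0 makes a straight tract
    #: porous (speckled sub-threshold holes inside a thick band, like
    #: the internal coherence variation of a real commissural bundle)
    speckle_sd: float = 0.0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) not in (2, 3):
            raise ValueError("shape must be 2-D or 3-D")
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")
        if self.kind != "uniform_grey" and min(self.shape) < 32:
            raise ValueError("tract phantoms need >= 32 voxels per axis")
        if self.noise_sd is None:
            self.noise_sd = 0.0 if self.kind == "uniform_grey" \
                else 0.02 * self.contrast
        if self.brain_axes is None:
            self.brain_axes = tuple(0.47 * s for s in self.shape)
        if self.tract_width >= 2 * min(self.brain_axes):
            raise ValueError("tract is wider than the brain mask")
        if (self.gap_spacing is not None
                and self.tract_extent * self.brain_axes[0]
                < 1.2 * self.gap_spacing):
            # tract too short to host gaps and still verify a clean
            # centreline between them
            self.gap_spacing = None

    @property
    def ndim(self) -> int:
        return len(self.shape)


@dataclass
class Scenario:
    """A ready-to-run bundle: image, derived tissue, chemo field, config."""

    name: str
    volume: _field.ImageVolume
    tissue: _field.TissueField
    chemo: ChemoField
    config: SimulationConfig


def _grids(shape):
    return np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                       indexing="ij")


def _ellipsoid_mask(shape, axes) -> np.ndarray:
    center = [(s - 1) / 2.0 for s in shape]
    acc = np.zeros(shape)
    for g, c, a in zip(_grids(shape), center, axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _band_envelope(dist, width):
    # cosine taper with compact support: 1 on the centreline, 0 beyond
    # |dist| = width, so the textured band has a crisp outer edge
    u = np.clip(np.abs(dist) / width, 0.0, 1.0)
    return np.cos(0.5 * np.pi * u) ** 2


def _gap_profile(coord, spec: PhantomSpec):
    """Periodic dips to 0 along the tract (1 inside a gap centre)."""
    if spec.gap_spacing is None:
        return np.zeros_like(np.asarray(coord, dtype=float))
    sp = spec.gap_spacing
    # gaps at odd multiples of sp/2 from the tract midpoint, so the
    # midpoint itself stays clean; u = distance to nearest gap centre
    u = np.abs((np.asarray(coord, dtype=float) % sp) - sp / 2.0)
    return _band_envelope(u, spec.gap_width)


def _taper_len(spec: PhantomSpec, axis: int = 0) -> float:
    half_len = spec.tract_extent * spec.brain_axes[axis]
    return min(2.0 * spec.tract_width, 0.3 * half_len)


def _end_taper(coord, spec: PhantomSpec, axis: int = 0):
    """Smooth cutoff at the tract ends, inside the brain mask."""
    half_len = spec.tract_extent * spec.brain_axes[axis]
    taper = _taper_len(spec, axis)
    over = np.clip(np.abs(coord) - (half_len - taper), 0.0, None)
    return _band_envelope(over, taper)


def _render(spec: PhantomSpec, contrast: float, noise_sd: float,
            rng: np.random.Generator) -> np.ndarray:
    shape = spec.shape
    g = _grids(shape)
    center = [(s - 1) / 2.0 for s in shape]
    k = 2.0 * np.pi / spec.texture_period
    img = np.full(shape, 0.5)

    if spec.kind == "uniform_grey":
        pass
    elif spec.kind == "straight_tract":
        # band along axis 0 through the grid centre, tapering off at
        # the tract ends inside the brain, interrupted by noise-filled
        # gaps that classify as grey matter
        d2 = sum((gi - ci) ** 2 for gi, ci in zip(g[1:], center[1:]))
        band = _band_envelope(np.sqrt(d2), spec.tract_width) * _end_taper(
            g[0] - center[0], spec)
        # gaps notch only the band core, leaving thin coherent walls:
        # a slow cell crawling through the notch is recaptured by the
        # walls, a fast cell jumps clear over them
        dip = _gap_profile(g[0] - center[0], spec) * _band_envelope(
            np.sqrt(d2), 0.45 * spec.tract_width)
        img = img + contrast * np.sin(k * g[0]) * band * (1.0 - dip)
        if spec.gap_spacing is not None:
            img = img + 0.35 * contrast * band * dip * rng.standard_normal(
                shape)
        if spec.speckle_sd > 0:
            img = img + spec.speckle_sd * contrast * band \
                * rng.standard_normal(shape)
    elif spec.kind == "curved_tract":
        # annular tract in the (x, y) plane at radius 0.55 * min axes
        r0 = 0.55 * min(spec.brain_axes[0], spec.brain_axes[1])
        rho = np.sqrt((g[0] - center[0]) ** 2 + (g[1] - center[1]) ** 2)
        theta = np.arctan2(g[1] - center[1], g[0] - center[0])
        band = _band_envelope(rho - r0, spec.tract_width)
        if spec.ndim == 3:
            band = band * _band_envelope(g[2] - center[2], spec.tract_width)
        # integer wavenumber along the circumference keeps the seam smooth
        m = max(1, int(round(k * r0)))
        img = img + contrast * np.sin(m * theta) * band
    elif spec.kind == "two_tract_cross":
        d2a = sum((gi - ci) ** 2 for gi, ci in zip(g[1:], center[1:]))
        d2b = (g[0] - center[0]) ** 2
        if spec.ndim == 3:
            d2b = d2b + (g[2] - center[2]) ** 2
        img = img + contrast * (
            np.sin(k * g[0]) * _band_envelope(np.sqrt(d2a), spec.tract_width)
            * _end_taper(g[0] - center[0], spec)
            + np.sin(k * g[1]) * _band_envelope(np.sqrt(d2b), spec.tract_width)
            * _end_taper(g[1] - center[1], spec, axis=1))
    if noise_sd > 0:
        img = img + noise_sd * rng.standard_normal(shape)
    return img


def _centerline_index(spec: PhantomSpec):
    """Index arrays of centreline voxels (margin-trimmed) and the
    expected local tangent per voxel."""
    shape = spec.shape
    center = [int(round((s - 1) / 2.0)) for s in shape]
    margin = int(3 * spec.smoothing_sigma + spec.texture_period)
    if spec.kind in ("straight_tract", "two_tract_cross"):
        half_len = spec.tract_extent * spec.brain_axes[0] \
            - _taper_len(spec) - 3 * spec.smoothing_sigma
        lo = int(np.ceil(center[0] - half_len))
        hi = int(center[0] + half_len)
        xs = np.arange(max(lo, margin), min(hi, shape[0] - margin))
        if spec.kind == "two_tract_cross":
            # the crossing itself has mixed orientation (low coherence,
            # as at real fibre crossings) -- skip its neighbourhood
            gap = 2 * spec.tract_width + spec.texture_period
            xs = xs[np.abs(xs - center[0]) > gap]
        if spec.gap_spacing is not None:
            # gaps classify as grey by design; check between them
            u = np.abs(((xs - center[0]) % spec.gap_spacing)
                       - spec.gap_spacing / 2.0)
            xs = xs[u > spec.gap_width + 2 * spec.smoothing_sigma]
        pts = np.stack([xs] + [np.full_like(xs, c) for c in center[1:]],
                       axis=1)
        tangents = np.zeros((len(xs), spec.ndim))
        tangents[:, 0] = 1.0
        return pts, tangents
    if spec.kind == "curved_tract":
        r0 = 0.55 * min(spec.brain_axes[0], spec.brain_axes[1])
        thetas = np.linspace(0, 2 * np.pi, 180, endpoint=False)
        x = center[0] + r0 * np.cos(thetas)
        y = center[1] + r0 * np.sin(thetas)
        cols = [np.round(x).astype(int), np.round(y).astype(int)]
        if spec.ndim == 3:
            cols.append(np.full(len(thetas), center[2], dtype=int))
        pts = np.stack(cols, axis=1)
        tan = np.stack([-np.sin(thetas), np.cos(thetas)]
                       + ([np.zeros(len(thetas))] if spec.ndim == 3 else []),
                       axis=1)
        return pts, tan
    return np.empty((0, spec.ndim), dtype=int), np.empty((0, spec.ndim))


def _verify(spec: PhantomSpec, vol: _field.ImageVolume
            ) -> tuple[bool, _field.TissueField]:
    tf = _field.structure_tensor(vol, spec.smoothing_sigma)
    tissue = _field.classify_tissue(tf, spec.epsilon_M, spec.pixel_size,
                                    vol.brain_mask)
    if spec.kind == "uniform_grey":
        return not np.any(tissue.wm_mask), tissue
    pts, _ = _centerline_index(spec)
    inside = vol.brain_mask[tuple(pts.T)]
    pts = pts[inside]
    if len(pts) == 0:
        return False, tissue
    on_line = tissue.anisotropy[tuple(pts.T)]
    if spec.speckle_sd > 0:
        # porous tract: the centreline is white matter only in patches
        if not (on_line >= spec.epsilon_M).mean() >= 0.3:
            return False, tissue
    elif not np.all(on_line >= spec.epsilon_M):
        return False, tissue
    # background: brain voxels farther than 2 tract widths from any WM voxel
    from scipy import ndimage as ndi
    near_tract = ndi.binary_dilation(
        tissue.wm_mask, iterations=int(2 * spec.tract_width))
    bg = vol.brain_mask & ~near_tract
    if bg.sum() == 0:
        return False, tissue
    frac_bad = np.count_nonzero(
        tissue.anisotropy[bg] >= spec.epsilon_M) / bg.sum()
    return frac_bad < 0.005, tissue


def make_phantom(spec: PhantomSpec,
                 rng: np.random.Generator | None = None
                 ) -> _field.ImageVolume:
    """Generate a verified synthetic tissue image."""
    vol, _ = make_phantom_with_tissue(spec, rng)
    return vol


def make_phantom_with_tissue(spec: PhantomSpec,
                             rng: np.random.Generator | None = None
                             ) -> tuple[_field.ImageVolume, _field.TissueField]:
    """Generate a phantom and the tissue field used to verify it."""
    if rng is None:
        rng = np.random.default_rng(0)
    mask = _ellipsoid_mask(spec.shape, spec.brain_axes)
    contrast, noise = spec.contrast, spec.noise_sd
    for _attempt in range(4):
        img = _render(spec, contrast, noise, rng)
        vol = _field.ImageVolume(img, spec.pixel_size, mask)
        ok, tissue = _verify(spec, vol)
        if ok:
            return vol, tissue
        contrast *= 2.0
        noise /= 2.0
    raise RuntimeError(
        f"could not generate a valid {spec.kind} phantom for shape "
        f"{spec.shape}; try a wider tract or lower noise")


def make_tensor_phantom(spec: PhantomSpec) -> _field.TensorField:
    """Direct per-voxel tensor phantom (precomputed-tensor input path).

    Builds tensors with eigenvalues (1, 0.1[, 0.1]) oriented along the
    tract inside the band and isotropic 0.1 outside.
    """
    if spec.kind != "straight_tract":
        raise ValueError("tensor phantom supports straight_tract only")
    shape, d = spec.shape, spec.ndim
    g = _grids(shape)
    center = [(s - 1) / 2.0 for s in shape]
    d2 = sum((gi - ci) ** 2 for gi, ci in zip(g[1:], center[1:]))
    in_band = np.sqrt(d2) <= spec.tract_width / 2.0
    tensors = np.zeros(shape + (d, d))
    iso = 0.1 * np.eye(d)
    tensors[...] = iso
    aniso = iso.copy()
    aniso[0, 0] = 1.0
    tensors[in_band] = aniso
    return _field.tensor_field_from_tensors(tensors)


def _scenario_layout(dim: int) -> dict:
    """Geometry (pixels) of the packaged scenarios."""
    if dim == 2:
        return {
            "shape": (160, 160),
            "on_tract": ((45.0, 80.0), 10.0),
            "periphery": ((80.0, 25.0), 8.0),
            "near": (115.0, 95.0),
            "far": (125.0, 40.0),
            # opposite hemispheres: mirrored in x about the midline, so
            # both are reachable from the midline periphery injection
            "bilateral": [(115.0, 95.0), (45.0, 95.0)],
            "sigma": 50.0,
        }
    return {
        "shape": (96, 96, 48),
        "on_tract": ((28.0, 48.0, 24.0), 6.0),
        "periphery": ((48.0, 12.0, 24.0), 5.0),
        "near": (70.0, 60.0, 24.0),
        "far": (75.0, 20.0, 24.0),
        "bilateral": [(70.0, 60.0, 24.0), (26.0, 60.0, 24.0)],
        "sigma": 40.0,
    }


def make_scenario(name: str, dim: int = 2,
                  rng: np.random.Generator | None = None,
                  injection: str = "on_tract") -> Scenario:
    """Build a packaged phantom scenario.

    ``near_tumor``: one tumor just off the tract, downstream of the
    on-tract injection (the easy target); ``far_tumor``: one tumor far
    from tract and injection (the hard target); ``bilateral_tumors``:
    two tumors on opposite sides of the tract; ``no_tumor``: control.
    ``injection`` picks the preset: ``on_tract`` (intracerebral-like)
    or ``periphery`` (intranasal-like).
    """
    if name not in SCENARIO_NAMES:
        raise ValueError(f"unknown scenario {name!r}; one of {SCENARIO_NAMES}")
    if dim not in (2, 3):
        raise ValueError("dim must be 2 or 3")
    if injection not in ("on_tract", "periphery"):
        raise ValueError("injection must be 'on_tract' or 'periphery'")
    if rng is None:
        rng = np.random.default_rng(0)
    lay = _scenario_layout(dim)
    spec = PhantomSpec(shape=lay["shape"], kind="straight_tract")
    vol, tissue = make_phantom_with_tissue(spec, rng)

    sigma = lay["sigma"]
    if name == "near_tumor":
        centers = [lay["near"]]
    elif name == "far_tumor":
        centers = [lay["far"]]
    elif name == "bilateral_tumors":
        centers = lay["bilateral"]
    else:
        centers = []
    sites = [TumorSite(center=np.asarray(c), half_decay=sigma)
             for c in centers]
    cf = ChemoField(sites=sites, epsilon_c=0.05)

    inj_center, inj_radius = lay[injection]
    config = SimulationConfig(
        d_w=5.0, d_g=0.5, lambda_c=6.0, beta_w=1.0, alpha_c=3.0,
        epsilon_M=spec.epsilon_M, epsilon_c=cf.epsilon_c,
        n_steps=3000, n_agents=1000,
        injection_center=inj_center, injection_radius=inj_radius,
        seed=int(rng.integers(0, 2 ** 31 - 1)),
    )
    return Scenario(name=name, volume=vol, tissue=tissue, chemo=cf,
                    config=config)
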