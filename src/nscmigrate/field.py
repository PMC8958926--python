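"""Tissue anisotropy fields from volumetric image data.

The local orientation and degree of anisotropy of brain tissue are
estimated with structure-tensor analysis: at every voxel the outer
product of the spatial intensity gradient is Gaussian-smoothed, and the
eigen-system of the resulting symmetric matrix encodes the dominant
orientation (principal eigenvector ``e1``) and how directionally
ordered the neighbourhood is.  In 2-D the anisotropy is quantified by
the *coherence* ``((l1 - l2) / (l1 + l2))**2`` and in 3-D by the
*fractional anisotropy* of the three eigenvalues.  Voxels whose
anisotropy exceeds a threshold ``epsilon_M`` are classified as white
matter; agents on white matter migrate along the principal direction,
agents on grey matter perform an isotropic random walk.

Coordinate convention: arrays are indexed ``data[x, y]`` /
``data[x, y, z]``; agent positions are continuous, in pixel units, with
voxel centres at integer coordinates.  Conversion to micrometres only
happens at reporting time through ``pixel_size``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as _dc_field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "ImageVolume",
    "TensorField",
    "TissueField",
    "structure_tensor",
    "tensor_field_from_tensors",
    "coherence_2d",
    "fractional_anisotropy",
    "angle_2d",
    "classify_tissue",
    "sample_field_at",
]


@dataclass
class ImageVolume:
    """A scalar intensity grid with physical pixel size and brain mask.

    Parameters
    ----------
    data:
        2-D (X, Y) or 3-D (X, Y, Z) array of intensities.
    pixel_size:
        Edge length of one voxel in micrometres.
    brain_mask:
        Boolean array, same shape as ``data``; True inside tissue.
        Defaults to all-True.
    """

    data: np.ndarray
    pixel_size: float = 1.0
    brain_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim not in (2, 3):
            raise ValueError(
                f"image must be 2-D or 3-D, got {self.data.ndim}-D"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.data.shape, dtype=bool)
        else:
            self.brain_mask = np.asarray(self.brain_mask, dtype=bool)
            if self.brain_mask.shape != self.data.shape:
                raise ValueError(
                    "brain_mask shape "
                    f"{self.brain_mask.shape} != data shape {self.data.shape}"
                )

    @property
    def ndim(self) -> int:
        return self.data.ndim


@dataclass
class TensorField:
    """Per-voxel symmetric tensors with their sorted eigen-system.

    ``eigenvalues`` are sorted descending (l1 >= l2 [>= l3] >= 0) and
    ``principal_evec`` is the unit eigenvector of the largest
    eigenvalue.
    """

    tensors: np.ndarray          # (..., d, d)
    eigenvalues: np.ndarray      # (..., d) descending
    principal_evec: np.ndarray   # (..., d) unit where l1 > 0
    smoothing_sigma: float = 0.0

    @property
    def ndim(self) -> int:
        return self.tensors.shape[-1]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.tensors.shape[:-2]


@dataclass
class TissueField:
    """White/grey classification plus the migration direction field."""

    anisotropy: np.ndarray          # M_coh in [0, 1]
    wm_mask: np.ndarray             # anisotropy >= epsilon_M (inside brain)
    direction: np.ndarray           # (..., d) unit principal direction
    epsilon_M: float
    pixel_size: float = 1.0
    brain_mask: np.ndarray = _dc_field(default=None)  # type: ignore[assignment]
    angle: np.ndarray | None = None  # 2-D only

    def __post_init__(self) -> None:
        if self.brain_mask is None:
            self.brain_mask = np.ones(self.anisotropy.shape, dtype=bool)

    @property
    def ndim(self) -> int:
        return self.anisotropy.ndim

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.anisotropy.shape


def _eigsort(tensors: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decompose a stack of symmetric matrices, sorted descending."""
    evals, evecs = np.linalg.eigh(tensors)
    evals = evals[..., ::-1]
    evecs = evecs[..., ::-1]
    floor = np.min(evals) if evals.size else 0.0
    if floor < -1e-8:
        logger.warning("eigenvalues below -1e-8 clipped to 0 (min %g)", floor)
    evals = np.clip(evals, 0.0, None)
    principal = np.ascontiguousarray(evecs[..., :, 0])
    return evals, principal


def structure_tensor(img: ImageVolume, smoothing_sigma: float = 2.0) -> TensorField:
    """Compute the Gaussian-smoothed structure tensor of an image.

    At each voxel the tensor is the outer product of the central-
    difference intensity gradient, with every component smoothed by a
    Gaussian of width ``smoothing_sigma`` pixels (0 disables smoothing).
    """
    data = img.data
    if data.ndim not in (2, 3):
        raise ValueError(f"image must be 2-D or 3-D, got {data.ndim}-D")
    if not np.all(np.isfinite(data)):
        raise ValueError("image intensities must be finite")
    if smoothing_sigma < 0:
        raise ValueError("smoothing_sigma must be >= 0")

    grads = np.gradient(data)  # one array per axis
    d = data.ndim
    tensors = np.empty(data.shape + (d, d), dtype=float)
    for i in range(d):
        for j in range(i, d):
            comp = grads[i] * grads[j]
            if smoothing_sigma > 0:
                comp = ndimage.gaussian_filter(comp, smoothing_sigma)
            tensors[..., i, j] = comp
            if i != j:
                tensors[..., j, i] = comp
    evals, principal = _eigsort(tensors)
    return TensorField(tensors, evals, principal, smoothing_sigma)


def tensor_field_from_tensors(tensors: np.ndarray,
                              smoothing_sigma: float = 0.0) -> TensorField:
    """Wrap a precomputed per-voxel tensor field (e.g. from DTI).

    ``tensors`` has shape (grid..., d, d) with d = 2 or 3 and must be
    symmetric.
    """
    tensors = np.asarray(tensors, dtype=float)
    d = tensors.shape[-1]
    if tensors.ndim < 3 or tensors.shape[-2] != d or d not in (2, 3):
        raise ValueError("expected shape (grid..., d, d) with d in (2, 3)")
    if not np.allclose(tensors, np.swapaxes(tensors, -1, -2), atol=1e-8):
        raise ValueError("tensors must be symmetric")
    evals, principal = _eigsort(tensors)
    return TensorField(tensors, evals, principal, smoothing_sigma)


def coherence_2d(lam1, lam2):
    """2-D anisotropy measure ``((l1 - l2) / (l1 + l2))**2`` in [0, 1].

    Defined for sorted non-negative eigenvalues; where both are zero
    (flat/isotropic region) the coherence is taken as 0.
    """
    lam1 = np.asarray(lam1, dtype=float)
    lam2 = np.asarray(lam2, dtype=float)
    if np.any(lam2 < -1e-12) or np.any(lam1 - lam2 < -1e-12):
        raise ValueError("require lam1 >= lam2 >= 0")
    total = lam1 + lam2
    flat = total <= 0
    if np.any(flat):
        logger.debug("coherence undefined at %d flat voxels; set to 0",
                     int(np.count_nonzero(flat)))
    out = np.zeros(np.broadcast(lam1, lam2).shape, dtype=float)
    np.divide(lam1 - lam2, total, out=out, where=~flat)
    out = np.clip(out * out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def fractional_anisotropy(lam1, lam2, lam3):
    """Fractional anisotropy of three sorted non-negative eigenvalues.

    ``FA = sqrt(3/2) * ||lam - mean(lam)|| / ||lam||`` in [0, 1]; an
    all-zero triple (flat region) yields 0.
    """
    lam = np.stack(np.broadcast_arrays(
        np.asarray(lam1, dtype=float),
        np.asarray(lam2, dtype=float),
        np.asarray(lam3, dtype=float)), axis=-1)
    if np.any(lam[..., 2] < -1e-12) or np.any(np.diff(lam, axis=-1) > 1e-12):
        raise ValueError("require lam1 >= lam2 >= lam3 >= 0")
    norm2 = np.sum(lam * lam, axis=-1)
    flat = norm2 <= 0
    if np.any(flat):
        logger.debug("FA undefined at %d flat voxels; set to 0",
                     int(np.count_nonzero(flat)))
    mean = np.mean(lam, axis=-1, keepdims=True)
    dev2 = np.sum((lam - mean) ** 2, axis=-1)
    out = np.zeros(norm2.shape, dtype=float)
    np.sqrt(np.divide(1.5 * dev2, norm2, out=out, where=~flat), out=out)
    out = np.clip(out, 0.0, 1.0)
    return float(out) if out.ndim == 0 else out


def angle_2d(evec) -> float | np.ndarray:
    """Orientation angle of a 2-D unit eigenvector.

    ``atan(e_y / e_x)`` where ``e_x != 0``, and ``pi`` where
    ``e_x == 0`` (the convention used for vertical orientations).
    """
    evec = np.asarray(evec, dtype=float)
    ex, ey = evec[..., 0], evec[..., 1]
    norm = np.hypot(ex, ey)
    if np.any(norm == 0):
        raise ValueError("zero vector has no orientation angle")
    vertical = ex == 0
    out = np.full(np.shape(ex), np.pi, dtype=float)
    np.arctan(np.divide(ey, ex, out=np.zeros_like(out), where=~vertical),
              out=out, where=~vertical)
    return float(out) if out.ndim == 0 else out


def classify_tissue(tf: TensorField,
                    epsilon_M: float = 0.4,
                    pixel_size: float = 1.0,
                    brain_mask: np.ndarray | None = None,
                    flat_tol: float = 1e-8) -> TissueField:
    """Classify each voxel as white (anisotropy >= epsilon_M) or grey.

    The anisotropy is the 2-D coherence or 3-D fractional anisotropy of
    the tensor eigenvalues; the threshold comparison is inclusive.  The
    migration direction is the normalized principal eigenvector.

    Voxels whose leading eigenvalue is below ``flat_tol`` times the
    field maximum carry no meaningful orientation signal (numerically
    flat regions) and get anisotropy 0.
    """
    if not 0.0 <= epsilon_M <= 1.0:
        raise ValueError("epsilon_M must be in [0, 1]")
    ev = tf.eigenvalues
    if tf.ndim == 2:
        aniso = coherence_2d(ev[..., 0], ev[..., 1])
        angle = angle_2d(np.where(
            np.linalg.norm(tf.principal_evec, axis=-1, keepdims=True) > 0,
            tf.principal_evec, [1.0, 0.0]))
    else:
        aniso = fractional_anisotropy(ev[..., 0], ev[..., 1], ev[..., 2])
        angle = None
    aniso = np.atleast_1d(np.asarray(aniso, dtype=float)).reshape(tf.grid_shape)
    lam1 = ev[..., 0]
    lmax = float(lam1.max()) if lam1.size else 0.0
    if lmax > 0:
        aniso[lam1 <= flat_tol * lmax] = 0.0
    if brain_mask is None:
        brain_mask = np.ones(tf.grid_shape, dtype=bool)
    wm = (aniso >= epsilon_M) & brain_mask
    direction = tf.principal_evec.copy()
    norms = np.linalg.norm(direction, axis=-1, keepdims=True)
    np.divide(direction, norms, out=direction, where=norms > 0)
    return TissueField(anisotropy=aniso, wm_mask=wm, direction=direction,
                       epsilon_M=epsilon_M, pixel_size=pixel_size,
                       brain_mask=brain_mask, angle=angle)


def _nearest_voxel(pos: np.ndarray) -> np.ndarray:
    # half-up rounding so position i + 0.5 maps to voxel i + 1
    return np.floor(pos + 0.5).astype(np.intp)


def _in_bounds(idx: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    ok = np.ones(idx.shape[0], dtype=bool)
    for axis, n in enumerate(shape):
        ok &= (idx[:, axis] >= 0) & (idx[:, axis] < n)
    return ok


def lookup(tissue: TissueField, pos: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized nearest-voxel lookup for (N, d) positions.

    Returns ``(is_white, direction, in_brain)`` with out-of-grid
    positions reported as outside the brain.
    """
    pos = np.atleast_2d(np.asarray(pos, dtype=float))
    idx = _nearest_voxel(pos)
    ok = _in_bounds(idx, tissue.grid_shape)
    idx_safe = np.clip(idx, 0, np.asarray(tissue.grid_shape) - 1)
    sel = tuple(idx_safe.T)
    in_brain = ok & tissue.brain_mask[sel]
    is_white = in_brain & tissue.wm_mask[sel]
    direction = tissue.direction[sel]
    direction = np.where(in_brain[:, None], direction, 0.0)
    return is_white, direction, in_brain


def sample_field_at(tissue: TissueField, pos,
                    interp: str = "nearest"
                    ) -> tuple[bool, np.ndarray, bool]:
    """Sample tissue class, direction and brain membership at a point.

    Masks always use nearest-voxel lookup; with ``interp='linear'`` the
    direction is tri-/bi-linearly interpolated and renormalized.
    """
    single = np.asarray(pos).ndim == 1
    is_white, direction, in_brain = lookup(tissue, pos)
    if interp == "linear":
        pts = np.atleast_2d(np.asarray(pos, dtype=float))
        comps = [ndimage.map_coordinates(tissue.direction[..., k], pts.T,
                                         order=1, mode="nearest")
                 for k in range(tissue.ndim)]
        direction = np.stack(comps, axis=-1)
        norms = np.linalg.norm(direction, axis=-1, keepdims=True)
        np.divide(direction, norms, out=direction, where=norms > 0)
    elif interp != "nearest":
        raise ValueError("interp must be 'nearest' or 'linear'")
    if single:
        return bool(is_white[0]), direction[0], bool(in_brain[0])
    return is_white, direction, in_brain
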