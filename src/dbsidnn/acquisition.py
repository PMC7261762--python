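"""Diffusion acquisition schemes, voxel signals, and multi-contrast volumes.

Conventions used throughout the package
---------------------------------------
* b-values are in s/mm^2 and diffusivities in um^2/ms, so every signal
  exponent is ``-b * D * 1e-3``.
* Gradient directions live in the image frame; fitting is voxel-wise and
  orientation-relative, so no world-space handling is done beyond carrying
  the NIfTI affine through unchanged.
* Voxel indices are 0-based and raster ("x fastest") ordered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import FormatError, ValidationError

#: exponent scale so that b [s/mm^2] times D [um^2/ms] is dimensionless
B_D_SCALE = 1.0e-3

UNIT_NORM_TOL = 1.0e-6


@dataclass(frozen=True)
class AcquisitionScheme:
    """A diffusion-weighting experiment: K gradient directions and b-values.

    Parameters
    ----------
    directions : (K, 3) array
        Unit vectors in the image frame. The zero vector is allowed (and
        expected) on b = 0 entries only.
    bvalues : (K,) array
        Non-negative b-values in s/mm^2; at least one entry must be zero.
    """

    directions: np.ndarray
    bvalues: np.ndarray

    def __post_init__(self):
        dirs = np.asarray(self.directions, dtype=float)
        bvals = np.asarray(self.bvalues, dtype=float)
        if dirs.ndim != 2 or dirs.shape[1] != 3:
            raise ValidationError(f"directions must be (K, 3), got {dirs.shape}")
        if bvals.shape != (dirs.shape[0],):
            raise ValidationError(
                f"bvalues length {bvals.shape} does not match directions {dirs.shape}"
            )
        if dirs.shape[0] < 7:
            raise ValidationError(f"scheme needs K >= 7 measurements, got {dirs.shape[0]}")
        if np.any(bvals < 0):
            raise ValidationError("negative b-value in scheme")
        if not np.any(bvals == 0):
            raise ValidationError("scheme must contain at least one b = 0 entry")
        norms = np.linalg.norm(dirs, axis=1)
        weighted = bvals > 0
        if np.any(np.abs(norms[weighted] - 1.0) > UNIT_NORM_TOL):
            raise ValidationError("weighted directions must have unit norm (1 +/- 1e-6)")
        if np.any((norms == 0) & weighted):
            raise ValidationError("zero direction vector on a b > 0 entry")
        object.__setattr__(self, "directions", dirs)
        object.__setattr__(self, "bvalues", bvals)

    @property
    def K(self) -> int:
        return self.bvalues.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    @property
    def n_b0(self) -> int:
        return int(np.sum(self.b0_mask))

    @property
    def b_max(self) -> float:
        return float(np.max(self.bvalues))

    @property
    def shells(self) -> np.ndarray:
        """Distinct nonzero b-values, ascending."""
        return np.unique(self.bvalues[self.bvalues > 0])


@dataclass
class VoxelSignal:
    """Diffusion-weighted intensities of one voxel under a scheme.

    ``b0_mean`` is the mean over the scheme's b = 0 entries and is the
    normalization denominator everywhere a normalized signal is needed.
    ``index`` optionally retains the 0-based (x, y, z) voxel index.
    """

    values: np.ndarray
    b0_mean: float
    index: tuple | None = None

    @classmethod
    def from_values(cls, values, scheme: AcquisitionScheme, index=None) -> "VoxelSignal":
        values = np.asarray(values, dtype=float)
        if values.shape != (scheme.K,):
            raise ValidationError(
                f"signal length {values.shape} does not match scheme K = {scheme.K}"
            )
        b0_mean = float(np.mean(values[scheme.b0_mask]))
        return cls(values=values, b0_mean=b0_mean, index=index)

    @property
    def is_degenerate(self) -> bool:
        """True for voxels with non-positive b0 or an all-zero signal."""
        return (not np.isfinite(self.b0_mean)) or self.b0_mean <= 0 or np.all(self.values == 0)

    def normalized(self) -> np.ndarray:
        if self.b0_mean <= 0:
            raise ValidationError("cannot normalize a voxel with b0_mean <= 0")
        return self.values / self.b0_mean


@dataclass
class ContrastStack:
    """Co-registered structural volumes (scanner units) plus named masks."""

    t1w: np.ndarray | None = None
    t2w: np.ndarray | None = None
    mt_on: np.ndarray | None = None
    mt_off: np.ndarray | None = None
    b0: np.ndarray | None = None
    masks: dict = field(default_factory=dict)
    affine: np.ndarray | None = None

    def __post_init__(self):
        shapes = {
            name: vol.shape
            for name, vol in [
                ("t1w", self.t1w), ("t2w", self.t2w), ("mt_on", self.mt_on),
                ("mt_off", self.mt_off), ("b0", self.b0),
            ]
            if vol is not None
        }
        if len(set(shapes.values())) > 1:
            raise ValidationError(f"contrast volumes disagree on grid shape: {shapes}")
        grid = next(iter(shapes.values()), None)
        for name, mask in self.masks.items():
            mask = np.asarray(mask)
            if grid is not None and mask.shape != grid:
                raise ValidationError(f"mask {name!r} shape {mask.shape} != grid {grid}")
            uniq = np.unique(mask)
            if not np.all(np.isin(uniq, (0, 1))):
                raise ValidationError(f"mask {name!r} is not binary")


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_dwi(dwi_path, bval_path, bvec_path):
    """Load a 4-D DWI NIfTI with FSL-style bval/bvec tables.

    Returns ``(scheme, volume, affine)``. Directions are renormalized to unit
    length; the b = 0 rows may carry zero vectors.
    """
    img = nib.load(str(dwi_path))
    volume = np.asarray(img.dataobj, dtype=float)
    if volume.ndim != 4:
        raise FormatError(f"expected a 4-D DWI volume, got shape {volume.shape}")
    bvals = np.atleast_1d(np.loadtxt(str(bval_path), dtype=float).ravel())
    bvecs = np.loadtxt(str(bvec_path), dtype=float)
    if bvecs.ndim != 2 or 3 not in bvecs.shape:
        raise FormatError(f"bvec table must be 3 x K or K x 3, got {bvecs.shape}")
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T  # FSL writes 3 rows of K entries
    n_vol = volume.shape[3]
    if bvals.shape[0] != n_vol or bvecs.shape[0] != n_vol:
        raise FormatError(
            f"bval/bvec entry counts ({bvals.shape[0]}/{bvecs.shape[0]}) "
            f"do not match the {n_vol} volumes in {dwi_path}"
        )
    norms = np.linalg.norm(bvecs, axis=1)
    nonzero = norms > 0
    bvecs[nonzero] = bvecs[nonzero] / norms[nonzero, None]
    scheme = AcquisitionScheme(directions=bvecs, bvalues=bvals)
    return scheme, volume, img.affine


def save_dwi(volume, scheme: AcquisitionScheme, dwi_path, bval_path, bvec_path, affine=None):
    """Write a 4-D volume plus FSL-dialect bval/bvec files (3-row bvec)."""
    volume = np.asarray(volume, dtype=np.float64)
    if volume.ndim != 4 or volume.shape[3] != scheme.K:
        raise ValidationError(
            f"volume shape {volume.shape} does not match scheme K = {scheme.K}"
        )
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(volume, affine), str(dwi_path))
    np.savetxt(str(bval_path), scheme.bvalues[None, :], fmt="%.6g")
    np.savetxt(str(bvec_path), scheme.directions.T, fmt="%.8f")


def save_map(volume, path, affine=None):
    """Write one scalar map as a NIfTI volume."""
    if affine is None:
        affine = np.eye(4)
    nib.save(nib.Nifti1Image(np.asarray(volume, dtype=np.float64), affine), str(path))


# ---------------------------------------------------------------------------
# Scheme construction
# ---------------------------------------------------------------------------

def _spiral_points(n: int) -> np.ndarray:
    """Deterministic near-uniform points on the sphere (generalized spiral)."""
    k = np.arange(n, dtype=float)
    h = -1.0 + 2.0 * k / max(n - 1, 1)
    theta = np.arccos(np.clip(h, -1, 1))
    phi = np.zeros(n)
    golden = np.pi * (3.0 - np.sqrt(5.0))
    phi = k * golden
    sin_t = np.sin(theta)
    return np.column_stack([sin_t * np.cos(phi), sin_t * np.sin(phi), np.cos(theta)])


def _repel(points: np.ndarray, n_iter: int = 60, step: float = 0.05) -> np.ndarray:
    """Electrostatic-repulsion refinement with antipodal symmetry.

    Treats each direction and its antipode as one electrode, which is the
    right symmetry for diffusion sampling (the signal is antipodally even).
    """
    p = points.copy()
    for _ in range(n_iter):
        diff = p[:, None, :] - p[None, :, :]
        diff_a = p[:, None, :] + p[None, :, :]  # interaction with antipodes
        d2 = np.sum(diff**2, axis=2) + np.eye(len(p))
        d2a = np.sum(diff_a**2, axis=2) + 1e-12
        force = np.sum(diff / d2[:, :, None] ** 1.5, axis=1)
        force += np.sum(diff_a / d2a[:, :, None] ** 1.5, axis=1)
        # project force onto tangent plane
        force -= np.sum(force * p, axis=1, keepdims=True) * p
        p = p + step * force
        p /= np.linalg.norm(p, axis=1, keepdims=True)
    return p


def make_default_scheme(
    n_directions: int = 99,
    b_max: float = 1500.0,
    n_b0: int = 1,
    n_shells: int = 5,
) -> AcquisitionScheme:
    """Multi-b-value scheme emulating a 99-direction, b_max 1500 s/mm^2 protocol.

    ``n_b0`` unweighted entries are prepended; the remaining directions are
    spread near-uniformly on the sphere by electrostatic repulsion and
    assigned round-robin to ``n_shells`` evenly spaced b-values in
    ``(0, b_max]``.
    """
    if n_directions < 6:
        raise ValidationError("need at least 6 weighted directions")
    if b_max <= 0:
        raise ValidationError("b_max must be positive")
    if n_shells > n_directions:
        raise ValidationError(f"n_shells = {n_shells} exceeds n_directions = {n_directions}")
    if n_shells < 1 or n_b0 < 1:
        raise ValidationError("n_shells and n_b0 must be >= 1")
    dirs = _repel(_spiral_points(n_directions))
    shells = b_max * np.arange(1, n_shells + 1) / n_shells
    bvals = shells[np.arange(n_directions) % n_shells]
    directions = np.vstack([np.zeros((n_b0, 3)), dirs])
    bvalues = np.concatenate([np.zeros(n_b0), bvals])
    return AcquisitionScheme(directions=directions, bvalues=bvalues)


# ---------------------------------------------------------------------------
# ROI extraction
# ---------------------------------------------------------------------------

def extract_roi_voxels(volume, mask, scheme: AcquisitionScheme | None = None) -> list[VoxelSignal]:
    """Pull per-voxel signals out of a 4-D volume under a binary mask.

    Voxels come back in raster order (x fastest, then y, then z) with their
    0-based indices retained. When a scheme is supplied, ``b0_mean`` is the
    mean over its b = 0 entries; otherwise the mean over all frames is used
    (appropriate for stacks of unweighted volumes). An empty mask warns and
    returns an empty list.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(mask)
    if volume.ndim != 4:
        raise ValidationError(f"expected 4-D volume, got shape {volume.shape}")
    if mask.shape != volume.shape[:3]:
        raise ValidationError(
            f"mask shape {mask.shape} does not match volume grid {volume.shape[:3]}"
        )
    flat = np.flatnonzero(mask.astype(bool).ravel(order="F"))
    if flat.size == 0:
        warnings.warn("empty ROI mask: no voxels extracted", stacklevel=2)
        return []
    if scheme is not None and volume.shape[3] != scheme.K:
        raise ValidationError(
            f"volume has {volume.shape[3]} frames but scheme K = {scheme.K}"
        )
    xs, ys, zs = np.unravel_index(flat, mask.shape, order="F")
    out = []
    for x, y, z in zip(xs, ys, zs):
        values = volume[x, y, z, :]
        if scheme is not None:
            b0_mean = float(np.mean(values[scheme.b0_mask]))
        else:
            b0_mean = float(np.mean(values))
        out.append(VoxelSignal(values=values, b0_mean=b0_mean, index=(int(x), int(y), int(z))))
    return out
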