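"""Diffusion tensor estimation and deterministic streamline tractography.

The diffusion tensor D (symmetric 3x3, mm^2/s) is estimated per voxel by
unweighted log-linear least squares on the monoexponential signal model
``S = S0 * exp(-b g^T D g)``.  Tractography is deterministic fixed
step-length propagation along the interpolated principal eigenvector,
seeded on a regular sub-voxel grid where the Westin linear measure
CL = (l1 - l2) / (l1 + l2 + l3) exceeds a start threshold, and terminated
on low fractional anisotropy, excessive per-step turning, or mask exit.

Default tracking parameters follow common deterministic-DTI practice for
single-shell b=1000 s/mm^2 data: seed spacing 0.5 mm, CL start threshold
0.3, FA stop 0.17, streamline length within [20, 110] mm, step 0.5 mm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import map_coordinates

from peritract.curvegeom import Streamline

__all__ = [
    "AcquisitionScheme",
    "TensorField",
    "TensorScalars",
    "TrackingParams",
    "ConfigurationError",
    "InsufficientDataError",
    "fit_tensor",
    "tensor_scalars",
    "track",
    "sample_scalar",
]


class ConfigurationError(ValueError):
    pass


class InsufficientDataError(ValueError):
    pass


@dataclass
class AcquisitionScheme:
    """Diffusion gradient scheme: b-values (s/mm^2) and unit b-vectors."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        self.bvals = np.asarray(self.bvals, dtype=float).ravel()
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.shape != (len(self.bvals), 3):
            raise ConfigurationError("bvecs must be (n, 3) matching bvals")
        dw = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dw], axis=1)
        if dw.any() and np.max(np.abs(norms - 1.0)) > 1e-6:
            raise ConfigurationError("diffusion-weighted bvecs must be unit vectors")
        if len(self.bvals) < 7 or dw.sum() < 6 or (~dw).sum() < 1:
            raise InsufficientDataError(
                "tensor fit needs >= 1 b0 and >= 6 diffusion-weighted volumes"
            )

    def __len__(self) -> int:
        return len(self.bvals)

    @property
    def n_directions(self) -> int:
        return int(np.sum(self.bvals > 0))

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def design_matrix(self) -> np.ndarray:
        """Rows b * (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz) for b > 0."""
        g = self.bvecs[~self.b0_mask]
        b = self.bvals[~self.b0_mask]
        gx, gy, gz = g.T
        return b[:, None] * np.stack(
            [gx**2, gy**2, gz**2, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz], axis=1
        )


# component order of the 6-vector tensor representation
_TENSOR_IDX = [(0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2)]


def _vec6_to_mat(d6: np.ndarray) -> np.ndarray:
    """(…, 6) tensor components -> (…, 3, 3) symmetric matrices."""
    out = np.zeros(d6.shape[:-1] + (3, 3), dtype=d6.dtype)
    for k, (i, j) in enumerate(_TENSOR_IDX):
        out[..., i, j] = d6[..., k]
        out[..., j, i] = d6[..., k]
    return out


@dataclass
class TensorField:
    """Per-voxel symmetric diffusion tensors on a regular grid.

    ``tensor`` holds the 6 unique components (xx, yy, zz, xy, xz, yz) in
    mm^2/s; ``valid`` flags voxels with a usable fit; ``affine`` maps
    0-based voxel indices to world RAS mm.
    """

    tensor: np.ndarray  # (X, Y, Z, 6)
    affine: np.ndarray  # (4, 4)
    valid: np.ndarray  # (X, Y, Z) bool

    def __post_init__(self):
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ConfigurationError("affine must be 4x4")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ConfigurationError("affine is not invertible")

    @property
    def shape(self) -> tuple:
        return self.tensor.shape[:3]

    def matrices(self) -> np.ndarray:
        return _vec6_to_mat(self.tensor)

    def eigensystem(self):
        """Eigenvalues sorted descending (l1 >= l2 >= l3) and eigenvectors.

        Returns ``(evals, evecs)`` with evals (..., 3) and evecs (..., 3, 3)
        whose column ``[..., :, k]`` corresponds to ``evals[..., k]``.
        """
        w, v = np.linalg.eigh(self.matrices())
        return w[..., ::-1], v[..., :, ::-1]


@dataclass
class TensorScalars:
    """Rotation-invariant tensor scalars per voxel."""

    fa: np.ndarray
    md: np.ndarray
    cl: np.ndarray
    evals: np.ndarray  # (..., 3) descending


@dataclass
class TrackingParams:
    seed_spacing: float = 0.5  # mm
    start_cl_threshold: float = 0.3
    stop_fa: float = 0.17
    min_len: float = 20.0  # mm
    max_len: float = 110.0  # mm
    step: float = 0.5  # mm
    max_angle_per_step: float = 35.0  # degrees

    def __post_init__(self):
        if not (0 < self.step <= self.min_len):
            raise ConfigurationError("require 0 < step <= min_len")
        if not (0 <= self.stop_fa <= 1):
            raise ConfigurationError("stop_fa must lie in [0, 1]")


def fit_tensor(dwi: np.ndarray, scheme: AcquisitionScheme, mask: np.ndarray,
               affine: np.ndarray | None = None) -> TensorField:
    """Log-linear least-squares tensor fit per voxel.

    Voxels with any non-positive signal (including S0) are flagged invalid
    rather than raising; the fit itself is the pseudoinverse solution of
    ``B d = -log(S / S0)`` with one shared design matrix.
    """
    dwi = np.asarray(dwi, dtype=float)
    if dwi.ndim != 4 or dwi.shape[3] != len(scheme):
        raise ConfigurationError(
            f"dwi has {dwi.shape[3] if dwi.ndim == 4 else '?'} volumes, "
            f"scheme has {len(scheme)}"
        )
    mask = np.asarray(mask, dtype=bool)
    if affine is None:
        affine = np.eye(4)

    b0 = dwi[..., scheme.b0_mask].mean(axis=-1)
    sig = dwi[..., ~scheme.b0_mask]
    valid = mask & (b0 > 0) & np.all(sig > 0, axis=-1)

    design = scheme.design_matrix()
    pinv = np.linalg.pinv(design)

    tensor = np.zeros(dwi.shape[:3] + (6,), dtype=float)
    if valid.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            y = np.log(b0[valid][:, None]) - np.log(sig[valid])
        tensor[valid] = y @ pinv.T
    return TensorField(tensor=tensor, affine=np.asarray(affine, float), valid=valid)


def _scalars_from_evals(evals: np.ndarray) -> TensorScalars:
    lam_sum = evals.sum(axis=-1)
    lam_bar = lam_sum / 3.0
    dev = evals - lam_bar[..., None]
    num = np.sqrt((dev**2).sum(axis=-1))
    den = np.sqrt((evals**2).sum(axis=-1))
    with np.errstate(divide="ignore", invalid="ignore"):
        fa = np.where(den > 0, np.sqrt(1.5) * num / den, 0.0)
        cl = np.where(lam_sum > 0, (evals[..., 0] - evals[..., 1]) / lam_sum, 0.0)
    fa = np.clip(fa, 0.0, 1.0)
    cl = np.clip(cl, 0.0, 1.0)
    return TensorScalars(fa=fa, md=lam_bar, cl=cl, evals=evals)


def tensor_scalars(fieldlike) -> TensorScalars:
    """FA, MD and Westin CL from tensor eigenvalues.

    Accepts a :class:`TensorField` or an eigenvalue array (..., 3).
    FA of the zero tensor is 0 by convention; FA and CL are clipped into
    [0, 1] against round-off.
    """
    if isinstance(fieldlike, TensorField):
        evals, _ = fieldlike.eigensystem()
        scal = _scalars_from_evals(evals)
        scal.fa[~fieldlike.valid] = 0.0
        scal.cl[~fieldlike.valid] = 0.0
        return scal
    evals = np.sort(np.asarray(fieldlike, dtype=float), axis=-1)[..., ::-1]
    return _scalars_from_evals(evals)


def _world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return points @ inv[:3, :3].T + inv[:3, 3]


def _interp(volume: np.ndarray, vox_pts: np.ndarray, cval=0.0) -> np.ndarray:
    return map_coordinates(volume, vox_pts.T, order=1, mode="constant", cval=cval)


class _FieldSampler:
    """Trilinear tensor-component interpolation + pointwise eigensystem."""

    def __init__(self, field: TensorField):
        self.field = field
        scal = tensor_scalars(field)
        self.fa_vol = scal.fa
        self.cl_vol = scal.cl
        self.mask_vol = field.valid.astype(float)
        self.components = [field.tensor[..., k] for k in range(6)]

    def voxel(self, world_pts: np.ndarray) -> np.ndarray:
        return _world_to_voxel(world_pts, self.field.affine)

    def fa(self, world_pts):
        return _interp(self.fa_vol, self.voxel(world_pts))

    def cl(self, world_pts):
        return _interp(self.cl_vol, self.voxel(world_pts))

    def inside(self, world_pts):
        return _interp(self.mask_vol, self.voxel(world_pts)) > 0.5

    def principal_direction(self, world_pts: np.ndarray) -> np.ndarray:
        vox = self.voxel(world_pts)
        d6 = np.stack([_interp(c, vox) for c in self.components], axis=-1)
        w, v = np.linalg.eigh(_vec6_to_mat(d6))
        return v[..., :, -1]  # eigenvector of the largest eigenvalue


def _seed_grid(seed_mask: np.ndarray, affine: np.ndarray, spacing: float) -> np.ndarray:
    """World-mm grid nodes at `spacing` covering the seed mask, kept where
    the mask interpolates above 0.5."""
    idx = np.argwhere(seed_mask)
    if idx.size == 0:
        return np.empty((0, 3))
    lo = idx.min(axis=0).astype(float)
    hi = idx.max(axis=0).astype(float)
    corners = np.array(
        [[x, y, z] for x in (lo[0], hi[0]) for y in (lo[1], hi[1]) for z in (lo[2], hi[2])]
    )
    world = corners @ affine[:3, :3].T + affine[:3, 3]
    wlo, whi = world.min(axis=0), world.max(axis=0)
    axes = [np.arange(wlo[k], whi[k] + spacing / 2, spacing) for k in range(3)]
    grid = np.stack(np.meshgrid(*axes, indexing="ij"), axis=-1).reshape(-1, 3)
    vox = _world_to_voxel(grid, affine)
    keep = _interp(seed_mask.astype(float), vox) > 0.5
    return grid[keep]


def _propagate(sampler: _FieldSampler, seeds: np.ndarray, init_dir: np.ndarray,
               params: TrackingParams, n_steps: int):
    """Advance all seeds simultaneously; returns per-seed point lists."""
    n = len(seeds)
    pos = seeds.copy()
    direction = init_dir.copy()
    active = np.ones(n, dtype=bool)
    trails: list[list[np.ndarray]] = [[] for _ in range(n)]
    cos_max = np.cos(np.deg2rad(params.max_angle_per_step))

    for _ in range(n_steps):
        if not active.any():
            break
        new_pos = pos[active] + params.step * direction[active]
        ok = sampler.inside(new_pos) & (sampler.fa(new_pos) >= params.stop_fa)
        new_dir = sampler.principal_direction(new_pos)
        # keep forward orientation: eigenvectors have arbitrary sign
        dots = np.einsum("ij,ij->i", new_dir, direction[active])
        new_dir[dots < 0] *= -1
        ok &= np.abs(dots) >= cos_max
        act_idx = np.flatnonzero(active)
        for i, j in enumerate(act_idx):
            if ok[i]:
                trails[j].append(new_pos[i])
        pos[act_idx[ok]] = new_pos[ok]
        direction[act_idx[ok]] = new_dir[ok]
        active[act_idx[~ok]] = False
    return trails


def track(field: TensorField, params: TrackingParams, seed_mask: np.ndarray,
          rng: np.random.Generator | None = None) -> list[Streamline]:
    """Deterministic fixed-step streamline propagation.

    Seeds on a regular grid (spacing ``params.seed_spacing``) inside
    ``seed_mask`` where CL >= ``start_cl_threshold``; each seed is tracked
    in both directions along the principal eigenvector and the two halves
    concatenated.  Streamlines end when FA < ``stop_fa``, the per-step
    turning angle exceeds ``max_angle_per_step``, or the field mask is
    left; results outside [min_len, max_len] are discarded.
    """
    sampler = _FieldSampler(field)
    seeds = _seed_grid(np.asarray(seed_mask, bool), field.affine, params.seed_spacing)
    if len(seeds) == 0:
        warnings.warn("empty seed set; returning no streamlines")
        return []
    keep = (sampler.cl(seeds) >= params.start_cl_threshold) & \
           (sampler.fa(seeds) >= params.stop_fa) & sampler.inside(seeds)
    seeds = seeds[keep]
    if len(seeds) == 0:
        warnings.warn("no seeds above the CL start threshold")
        return []

    e1 = sampler.principal_direction(seeds)
    n_steps = int(np.ceil(params.max_len / params.step)) + 2
    fwd = _propagate(sampler, seeds, e1, params, n_steps)
    bwd = _propagate(sampler, seeds, -e1, params, n_steps)

    out: list[Streamline] = []
    for k in range(len(seeds)):
        pts = bwd[k][::-1] + [seeds[k]] + fwd[k]
        if len(pts) < 3:
            continue
        length = (len(pts) - 1) * params.step
        if params.min_len <= length <= params.max_len:
            out.append(Streamline(np.asarray(pts)))
    return out


def sample_scalar(volume: np.ndarray, affine: np.ndarray, curve: Streamline) -> np.ndarray:
    """Trilinear samples of a scalar volume along a streamline.

    Points outside the volume (beyond the outer voxel centres) yield NaN,
    to be excluded downstream.
    """
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ConfigurationError("affine is not invertible")
    vox = _world_to_voxel(curve.points, affine)
    vals = map_coordinates(np.asarray(volume, float), vox.T, order=1,
                           mode="constant", cval=np.nan)
    upper = np.asarray(volume.shape, float) - 1
    oob = np.any((vox < 0) | (vox > upper), axis=1)
    vals[oob] = np.nan
    return vals
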