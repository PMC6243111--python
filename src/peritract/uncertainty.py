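"""Per-voxel uncertainty ellipsoids from repeated-session streamline matches.

Between-session differences in tractography reflect measurement confounds
(scanner noise, motion, tensor-fit and tracking errors) as much as true
anatomy.  Repeated scans of the same subject over short intervals let one
measure the spatial scale of those confounds: for every matched point
pair the residual displacement (target minus transformed source) is
deposited at the voxel containing the source point, and each voxel's
displacement set is summarized by its second-moment matrix
M = mean(d d^T) taken about the origin — so a purely systematic shift
contributes as much as random spread, and anisotropy of the confounds is
retained.  The *uncertainty ellipsoid* is the ellipsoid with axes
2 * sqrt(eigenvalues of M); its major axis, the *uncertainty radius*
2 * sqrt(lambda_max), is the scale below which between-session changes at
that voxel should not be interpreted.  With this convention a constant
displacement of magnitude |d| gives radius 2 |d| (the full axis spans
+/- |d|); the factor is exposed for users preferring a semi-axis
convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "UncertaintyField",
    "voxel_displacements",
    "uncertainty_field",
    "summarize_radius",
]

N_MIN_DEFAULT = 5  # minimum displacement samples per voxel
RADIUS_FACTOR = 2.0  # full-axis convention: radius = 2 sqrt(lambda_max)


@dataclass
class UncertaintyField:
    moment: np.ndarray       # (X, Y, Z, 3, 3) second-moment matrices, mm^2
    radius: np.ndarray       # (X, Y, Z) mm
    count: np.ndarray        # (X, Y, Z) samples per voxel
    valid: np.ndarray        # (X, Y, Z) bool, count >= n_min

    def major_axis(self) -> np.ndarray:
        """Unit major-axis direction per voxel (arbitrary where radius 0)."""
        w, v = np.linalg.eigh(self.moment)
        return v[..., :, -1]


def _world_to_voxel(points: np.ndarray, affine: np.ndarray) -> np.ndarray:
    inv = np.linalg.inv(affine)
    return points @ inv[:3, :3].T + inv[:3, 3]


def voxel_displacements(matches, shape, affine,
                        apply_global: bool = True,
                        spacing: float = 0.5) -> dict:
    """Pool matched-point displacement vectors per source voxel.

    ``matches`` is an iterable of (MatchResult, source Bundle, target
    Bundle) triples from pairwise session matching (all in one world
    frame).  For every matched point pair the displacement
    target - (global transform applied to source, unless
    ``apply_global=False``) is deposited at the voxel containing the
    source point.  Returns ``{(i, j, k): (n, 3) array}``.
    """
    from peritract.curvegeom import resample
    from peritract.matching import index_correspondence

    deposits: dict = {}
    any_pairs = False
    for result, source, target in matches:
        rot, t = result.global_rotation, result.global_translation
        if not apply_global:
            rot, t = np.eye(3), np.zeros(3)
        for pair in result.pairs:
            any_pairs = True
            # re-derive the point correspondence used by the match
            a = resample(source.streamlines[pair.source], spacing)
            b = resample(target.streamlines[pair.target], spacing)
            # position metric: sessions share a frame, and spatial alignment
            # is well-posed even where curvature carries no information
            imap = index_correspondence(a, b, spacing, metric="position")
            pa = a.points[imap.pairs[:, 0]]
            pb = b.points[imap.pairs[:, 1]]
            disp = pb - (pa @ rot.T + t)
            vox = np.round(_world_to_voxel(pa, affine)).astype(int)
            inside = np.all((vox >= 0) & (vox < np.asarray(shape)), axis=1)
            for v, d in zip(vox[inside], disp[inside]):
                deposits.setdefault(tuple(v), []).append(d)
    if not any_pairs:
        warnings.warn("no matched point pairs; uncertainty field is empty")
    return {k: np.asarray(v) for k, v in deposits.items()}


def uncertainty_field(displacements: dict, shape,
                      restriction_mask: np.ndarray | None = None,
                      n_min: int = N_MIN_DEFAULT,
                      radius_factor: float = RADIUS_FACTOR) -> UncertaintyField:
    """Second-moment ellipsoid and uncertainty radius per voxel.

    Voxels with fewer than ``n_min`` samples (or outside the restriction
    mask) are flagged invalid; their radius is NaN.
    """
    shape = tuple(shape)
    moment = np.zeros(shape + (3, 3))
    radius = np.full(shape, np.nan)
    count = np.zeros(shape, dtype=int)
    valid = np.zeros(shape, dtype=bool)
    for vox, d in displacements.items():
        if restriction_mask is not None and not restriction_mask[vox]:
            continue
        count[vox] = len(d)
        if len(d) < n_min:
            continue
        m = (d[:, :, None] * d[:, None, :]).mean(axis=0)
        moment[vox] = m
        lam_max = float(np.linalg.eigvalsh(m)[-1])
        radius[vox] = radius_factor * np.sqrt(max(lam_max, 0.0))
        valid[vox] = True
    return UncertaintyField(moment=moment, radius=radius, count=count, valid=valid)


def summarize_radius(field: UncertaintyField,
                     restriction_mask: np.ndarray | None = None) -> tuple[float, float]:
    """Mean and sample SD (n-1) of the radius over valid (masked) voxels."""
    sel = field.valid.copy()
    if restriction_mask is not None:
        sel &= np.asarray(restriction_mask, bool)
    vals = field.radius[sel]
    if vals.size == 0:
        raise ValueError("no valid voxels in the restriction mask")
    mu = float(vals.mean())
    sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    return mu, sd
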