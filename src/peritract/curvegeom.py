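"""Streamlines as 3D space curves: arc length, curvature and torsion.

Tractography streamlines are treated as piecewise-differentiable space
curves.  The rigid-motion-invariant descriptors curvature ``kappa``
(|r' x r''| / |r'|^3, 1/mm, non-negative) and torsion ``tau``
((r' x r'') . r''' / |r' x r''|^2, 1/mm, signed) uniquely characterise a
regular curve up to a rigid transform, which is what makes them usable as
matching features across imaging sessions.

Derivatives are estimated by centred finite differences on a uniform
arc-length parametrization (one-sided at the endpoints).  Torsion is
numerically unstable where the curve is almost straight, so ``tau`` is
flagged undefined wherever ``kappa`` falls below ``KAPPA_FLOOR``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.ndimage import gaussian_filter1d

#: curvature (1/mm) below which torsion is reported as undefined
KAPPA_FLOOR = 1e-4

#: default resampling spacing in mm, matched to the tracking step length
DEFAULT_SPACING = 0.5


class CurveError(ValueError):
    """Raised for degenerate or too-short curves."""


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise CurveError(f"expected (n, 3) point array, got {pts.shape}")
    return pts


def arc_length_coords(points: np.ndarray) -> np.ndarray:
    """Cumulative chord-length coordinate (mm) of each point, starting at 0."""
    pts = _as_points(points)
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


@dataclass
class Streamline:
    """Ordered 3D polyline in world millimetres.

    Parameters
    ----------
    points : (n, 3) array
        Vertex coordinates in world mm, n >= 3.
    s : (n,) array, optional
        Arc-length coordinate per point; recomputed from chord lengths
        if not given.  Must be strictly increasing.
    """

    points: np.ndarray
    s: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.points = _as_points(self.points)
        if len(self.points) < 3:
            raise CurveError("streamline needs at least 3 points")
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        if np.any(seg == 0):
            raise CurveError("consecutive points must be distinct")
        if self.s is None:
            self.s = arc_length_coords(self.points)
        else:
            self.s = np.asarray(self.s, dtype=float)
            if self.s.shape != (len(self.points),) or np.any(np.diff(self.s) <= 0):
                raise CurveError("s must be strictly increasing, one per point")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def length(self) -> float:
        """Total chord arc length in mm."""
        return float(self.s[-1] - self.s[0])

    def reversed(self) -> "Streamline":
        # keep the existing s grid (reflected) so uniform parametrizations
        # stay exactly uniform under reversal
        return Streamline(self.points[::-1].copy(),
                          s=self.s[-1] - self.s[::-1])


@dataclass
class CurveInvariants:
    """Per-sample curvature/torsion profile aligned to arc-length samples."""

    s: np.ndarray
    kappa: np.ndarray
    tau: np.ndarray
    tau_defined: np.ndarray  # boolean; False where kappa < KAPPA_FLOOR

    def __post_init__(self):
        assert np.all(self.kappa >= 0)


def resample(curve: Streamline, spacing: float = DEFAULT_SPACING) -> Streamline:
    """Resample a curve to points equidistant in arc length.

    Coordinates are interpolated with a cubic spline against the chord
    arc-length parameter; both endpoints are preserved exactly.  The
    target spacing is adjusted minimally so that an integer number of
    intervals covers the full length.
    """
    if spacing <= 0:
        raise CurveError("spacing must be positive")
    total = curve.length
    if total < 2 * spacing:
        raise CurveError(
            f"curve length {total:.3f} mm too short for spacing {spacing} mm"
        )
    n_seg = int(round(total / spacing))
    n_seg = max(n_seg, 2)
    spline = CubicSpline(curve.s, curve.points, axis=0)
    s_new = np.linspace(curve.s[0], curve.s[-1], n_seg + 1)
    pts = spline(s_new)
    pts[0] = curve.points[0]
    pts[-1] = curve.points[-1]
    return Streamline(pts, s=s_new - s_new[0])


def smooth(curve: Streamline, sigma_mm: float) -> Streamline:
    """Gaussian smoothing of coordinates along the curve (sigma in mm).

    Optional denoising before curvature/torsion estimation on noisy
    tractography output; endpoints handled by nearest-value extension.
    """
    if sigma_mm <= 0:
        return curve
    ds = float(np.mean(np.diff(curve.s)))
    pts = gaussian_filter1d(curve.points, sigma_mm / ds, axis=0, mode="nearest")
    return Streamline(pts)


def _derivatives(points: np.ndarray, h: float):
    """First three derivatives w.r.t. the uniform parameter, step h."""
    r1 = np.gradient(points, h, axis=0, edge_order=2)
    r2 = np.gradient(r1, h, axis=0, edge_order=2)
    r3 = np.gradient(r2, h, axis=0, edge_order=2)
    return r1, r2, r3


def invariants(curve: Streamline, kappa_floor: float = KAPPA_FLOOR) -> CurveInvariants:
    """Curvature and torsion profiles from finite-difference Frenet formulas.

    The curve must already be uniformly resampled (see :func:`resample`);
    a non-uniform parametrization raises :class:`CurveError`.
    """
    if len(curve) < 5:
        raise CurveError("need at least 5 samples for curvature/torsion")
    ds = np.diff(curve.s)
    h = float(ds.mean())
    if np.max(np.abs(ds - h)) > 1e-6 * max(h, 1.0):
        raise CurveError("curve must be resampled at uniform spacing first")

    r1, r2, r3 = _derivatives(curve.points, h)
    cross = np.cross(r1, r2)
    cross_norm = np.linalg.norm(cross, axis=1)
    speed = np.linalg.norm(r1, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.where(speed > 0, cross_norm / speed**3, 0.0)
        tau = np.where(
            cross_norm > 0,
            np.einsum("ij,ij->i", cross, r3) / cross_norm**2,
            0.0,
        )
    defined = kappa >= kappa_floor
    tau = np.where(defined, tau, np.nan)
    return CurveInvariants(s=curve.s.copy(), kappa=kappa, tau=tau, tau_defined=defined)


def validate_rotation(rotation: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Check that a 3x3 matrix is a proper rotation (orthonormal, det +1)."""
    rot = np.asarray(rotation, dtype=float)
    if rot.shape != (3, 3):
        raise CurveError("rotation must be 3x3")
    if np.max(np.abs(rot.T @ rot - np.eye(3))) > tol:
        raise CurveError("rotation matrix is not orthonormal")
    if abs(np.linalg.det(rot) - 1.0) > 1e-6:
        raise CurveError("rotation must be proper (det +1)")
    return rot


def apply_rigid(curve: Streamline, rotation, translation) -> Streamline:
    """Map each point x to R x + t; arc length is preserved (isometry)."""
    rot = validate_rotation(rotation)
    t = np.asarray(translation, dtype=float).reshape(3)
    return Streamline(curve.points @ rot.T + t, s=curve.s.copy())
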