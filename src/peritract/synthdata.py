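"""Synthetic longitudinal phantoms for every pipeline stage.

Generates, with full seed determinism and emitted ground truth:

* tensor fields containing coherent fibre bundles (straight, circular-arc
  or helical centerlines) embedded in an isotropic background;
* diffusion-weighted volumes from the monoexponential model at b = 0 and
  b = 1000 s/mm^2 over 64 directions, with Rician magnitude noise at a
  stated SNR (S0 / sigma);
* SWI volumes with hypointense spherical microbleeds, and acute/chronic
  FLAIR pairs in which perilesional hyperintense rings are present
  acutely and resolve (traumatic) or persist (non-traumatic);
* longitudinal session pairs related by a known rigid motion, with a
  planted perilesional FA decrease applied exactly (closed-form
  eigenvalue shrinkage toward isotropy);
* cohorts with mTBI / old-HC / young-HC arms, per-subject seeds derived
  from one master seed.

Defaults mirror the measurement setting the toolkit targets: 64-direction
single-shell DWI, 2 mm isotropic voxels, bundle eigenvalues
(1.7, 0.2, 0.2) x 10^-3 mm^2/s (FA ~ 0.87) over an isotropic background
well below the FA tracking stop threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from peritract.curvegeom import Streamline
from peritract.diffusion import (
    AcquisitionScheme,
    TensorField,
    tensor_scalars,
)

__all__ = [
    "BundleDescriptor",
    "LesionSpec",
    "PhantomSpec",
    "LongitudinalSpec",
    "make_scheme",
    "make_tensor_phantom",
    "make_dwi",
    "plant_delta_fa",
    "make_lesion_volumes",
    "make_longitudinal_subject",
    "make_cohort",
    "rotation_about_axis",
]

INSIDE_EVALS = (1.7e-3, 0.2e-3, 0.2e-3)  # mm^2/s, FA ~ 0.8704
BACKGROUND_EVALS = (0.7e-3, 0.7e-3, 0.7e-3)  # isotropic, FA = 0


def make_scheme(n_directions: int = 64, bval: float = 1000.0) -> AcquisitionScheme:
    """One b=0 volume plus ``n_directions`` Fibonacci-sphere directions."""
    k = np.arange(n_directions)
    golden = (1 + 5**0.5) / 2
    theta = 2 * np.pi * k / golden
    z = 1 - (2 * k + 1) / n_directions
    r = np.sqrt(1 - z**2)
    dirs = np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)
    bvals = np.concatenate([[0.0], np.full(n_directions, bval)])
    bvecs = np.vstack([[0.0, 0.0, 0.0], dirs])
    return AcquisitionScheme(bvals=bvals, bvecs=bvecs)


def rotation_about_axis(axis, angle_deg: float) -> np.ndarray:
    """Rodrigues rotation matrix about ``axis`` by ``angle_deg`` degrees."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    th = np.deg2rad(angle_deg)
    k = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(th) * k + (1 - np.cos(th)) * (k @ k)


@dataclass
class BundleDescriptor:
    """A coherent fibre bundle around an analytic centerline.

    kind: "straight" (along ``direction`` through ``origin``),
    "arc" (circle of ``arc_radius`` in the plane of ``direction``/normal),
    or "helix" (radius ``arc_radius``, pitch parameter ``helix_pitch``).
    ``extent_mm`` is the centerline length.
    """

    kind: str = "straight"
    origin: tuple = (0.0, 0.0, 0.0)
    direction: tuple = (1.0, 0.0, 0.0)
    extent_mm: float = 60.0
    radius_mm: float = 4.0
    arc_radius: float = 40.0
    helix_pitch: float = 10.0
    sine_amplitude: float = 8.0
    sine_period: float = 45.0
    inside_evals: tuple = INSIDE_EVALS
    flat_caps: bool = True  # cut the tube flat at the centerline ends

    def centerline(self, step: float = 0.5) -> np.ndarray:
        o = np.asarray(self.origin, dtype=float)
        d = np.asarray(self.direction, dtype=float)
        d = d / np.linalg.norm(d)
        if self.kind == "straight":
            t = np.arange(0, self.extent_mm + step / 2, step)
            return o + t[:, None] * d
        if self.kind == "arc":
            # quarter-plane arc in the x-y plane rotated to `direction`
            phi_max = self.extent_mm / self.arc_radius
            phi = np.arange(0, phi_max + step / self.arc_radius / 2,
                            step / self.arc_radius)
            pts = np.stack([
                self.arc_radius * np.sin(phi),
                self.arc_radius * (1 - np.cos(phi)),
                np.zeros_like(phi),
            ], axis=1)
            return o + pts
        if self.kind == "sine":
            # varying curvature along the course; identifiable geometry for
            # transform-recovery studies (arcs/helices are self-similar)
            t = np.arange(0, self.extent_mm + step / 2, step)
            y = self.sine_amplitude * np.sin(2 * np.pi * t / self.sine_period)
            return o + np.stack([t, y, np.zeros_like(t)], axis=1)
        if self.kind == "helix":
            a, b = self.arc_radius, self.helix_pitch
            speed = np.hypot(a, b)
            t = np.arange(0, self.extent_mm / speed + step / speed / 2,
                          step / speed)
            return o + np.stack([a * np.cos(t) - a, a * np.sin(t), b * t], axis=1)
        raise ValueError(f"unknown centerline kind {self.kind!r}")


@dataclass
class LesionSpec:
    centre_mm: tuple
    radius_mm: float = 2.0
    contrast: float = 0.6          # SWI signal drop inside the lesion
    acute_ring: bool = True
    chronic_ring: bool = False
    ring_contrast: float = 0.6     # FLAIR hyperintensity above background
    ring_thickness_mm: float = 2.0
    affected: bool = False         # carries a planted perilesional dFA


@dataclass
class PhantomSpec:
    shape: tuple = (64, 64, 64)
    voxel_size: float = 2.0        # mm, isotropic
    bundles: list = field(default_factory=lambda: [BundleDescriptor()])
    background_evals: tuple = BACKGROUND_EVALS
    s0: float = 1000.0
    snr: float | None = 30.0       # None = noiseless
    seed: int = 0

    @property
    def affine(self) -> np.ndarray:
        out = np.eye(4)
        out[:3, :3] *= self.voxel_size
        return out


@dataclass
class LongitudinalSpec:
    n_sessions: int = 2
    rotation_axis: tuple = (0.0, 0.0, 1.0)
    rotation_deg: float = 2.0
    translation_mm: tuple = (1.0, 0.5, 0.0)
    delta_fa: float = -0.10        # planted perilesional FA change
    region_radius_mm: float = 8.0
    lesions: list = field(default_factory=list)
    lesion_noise_sd: float = 0.02  # SWI/FLAIR additive noise (0 = off)
    seed: int = 0

    def __post_init__(self):
        if abs(self.rotation_deg) > 15 or np.linalg.norm(self.translation_mm) > 10:
            raise ValueError("inter-session motion exceeds configured bounds")


def _grid_world(shape, affine) -> np.ndarray:
    idx = np.stack(np.meshgrid(*[np.arange(n) for n in shape], indexing="ij"),
                   axis=-1).reshape(-1, 3)
    return idx @ affine[:3, :3].T + affine[:3, 3]


def make_tensor_phantom(spec: PhantomSpec, transform=None):
    """Tensor field with bundles aligned to their centerline tangents.

    ``transform``: optional (R, t) rigid motion applied to all centerlines
    (used for follow-up sessions).  Returns ``(field, bundle_mask,
    centerlines)`` with the mask flagging in-bundle voxels and the
    (transformed) centerlines as Streamlines for ground truth.
    """
    shape = tuple(spec.shape)
    affine = spec.affine
    world = _grid_world(shape, affine)

    bg = np.asarray(spec.background_evals, dtype=float)
    tensor6 = np.zeros(shape + (6,))
    tensor6[..., 0] = bg[0]
    tensor6[..., 1] = bg[1]
    tensor6[..., 2] = bg[2]

    bundle_mask = np.zeros(shape, dtype=bool)
    centerlines = []
    for desc in spec.bundles:
        cl = desc.centerline(step=spec.voxel_size / 4)
        if transform is not None:
            rot, t = transform
            cl = cl @ np.asarray(rot).T + np.asarray(t)
        centerlines.append(Streamline(cl))
        tangents = np.gradient(cl, axis=0)
        tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
        tree = cKDTree(cl)
        dist, nearest = tree.query(world)
        inside = dist <= desc.radius_mm
        if desc.flat_caps:
            # drop the hemispherical caps beyond the centerline ends
            inside &= (nearest > 0) & (nearest < len(cl) - 1)
        if not inside.any():
            continue
        tan = tangents[nearest[inside]]
        lam = np.asarray(desc.inside_evals, dtype=float)
        # build D = lam1 e1 e1^T + lam_perp (I - e1 e1^T); transverse
        # eigenvalues are equal by construction so any frame works
        if abs(lam[1] - lam[2]) > 1e-15:
            raise ValueError("transverse eigenvalues must be equal")
        outer = tan[:, :, None] * tan[:, None, :]
        mats = lam[1] * np.eye(3) + (lam[0] - lam[1]) * outer
        flat_idx = np.flatnonzero(inside)
        vox = np.unravel_index(flat_idx, shape)
        tensor6[vox[0], vox[1], vox[2], 0] = mats[:, 0, 0]
        tensor6[vox[0], vox[1], vox[2], 1] = mats[:, 1, 1]
        tensor6[vox[0], vox[1], vox[2], 2] = mats[:, 2, 2]
        tensor6[vox[0], vox[1], vox[2], 3] = mats[:, 0, 1]
        tensor6[vox[0], vox[1], vox[2], 4] = mats[:, 0, 2]
        tensor6[vox[0], vox[1], vox[2], 5] = mats[:, 1, 2]
        bundle_mask.ravel()[flat_idx] = True

    valid = np.ones(shape, dtype=bool)
    return TensorField(tensor=tensor6, affine=affine, valid=valid), bundle_mask, centerlines


def make_dwi(field: TensorField, scheme: AcquisitionScheme, s0: float = 1000.0,
             snr: float | None = 30.0, seed: int = 0) -> np.ndarray:
    """Forward-simulated DWI with Rician noise (sigma = S0 / SNR)."""
    g = scheme.bvecs
    b = scheme.bvals
    gx, gy, gz = g.T
    # g^T D g as a matmul against the 6 unique tensor components
    coef = np.stack([gx**2, gy**2, gz**2, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz],
                    axis=1)  # (n_vol, 6)
    quad = field.tensor @ coef.T  # (..., n_vol)
    signal = s0 * np.exp(-quad * b)
    if snr is None or not np.isfinite(snr):
        return signal
    sigma = s0 / snr
    rng = np.random.default_rng(seed)
    re = signal + rng.normal(0, sigma, signal.shape)
    im = rng.normal(0, sigma, signal.shape)
    return np.hypot(re, im)


def plant_delta_fa(field: TensorField, region_mask: np.ndarray,
                   delta_fa: float) -> TensorField:
    """Shift FA by ``delta_fa`` inside a region, exactly, preserving MD.

    Eigenvalues are shrunk toward their mean: lam(a) = lam_bar + (1-a)
    (lam - lam_bar).  The deviatoric norm u = (1-a) |lam - lam_bar|
    achieving target FA f satisfies u = f lam_bar sqrt(3 / (1.5 - f^2)),
    a closed form, so the planted change carries no iteration error.
    Target FA is clipped into [0, 1).
    """
    evals, evecs = field.eigensystem()
    scal = tensor_scalars(field)
    target = np.clip(scal.fa + delta_fa, 0.0, 0.999999)

    lam_bar = evals.mean(axis=-1)
    dev = evals - lam_bar[..., None]
    dev_norm = np.linalg.norm(dev, axis=-1)
    with np.errstate(divide="ignore", invalid="ignore"):
        u = target * lam_bar * np.sqrt(3.0 / (1.5 - target**2))
        scale = np.where(dev_norm > 0, u / np.maximum(dev_norm, 1e-300), 0.0)
    region = np.asarray(region_mask, bool) & field.valid & (dev_norm > 0)
    new_evals = np.where(region[..., None],
                         lam_bar[..., None] + scale[..., None] * dev, evals)
    new_evals = np.maximum(new_evals, 0.0)
    mats = np.einsum("...ij,...j,...kj->...ik", evecs, new_evals, evecs)
    tensor6 = np.stack([mats[..., 0, 0], mats[..., 1, 1], mats[..., 2, 2],
                        mats[..., 0, 1], mats[..., 0, 2], mats[..., 1, 2]],
                       axis=-1)
    return TensorField(tensor=tensor6, affine=field.affine.copy(),
                       valid=field.valid.copy())


def _ellipsoid_mask(shape) -> np.ndarray:
    """Brain-like mask: axis-aligned ellipsoid inscribed in the grid."""
    axes = [np.arange(n) - (n - 1) / 2 for n in shape]
    zz = np.zeros(shape)
    for k, ax in enumerate(axes):
        sl = [None, None, None]
        sl[k] = slice(None)
        semi = (shape[k] - 1) / 2 * 0.92
        zz = zz + (ax[tuple(sl)] / semi) ** 2
    return zz <= 1.0


def make_lesion_volumes(scene: list, shape, affine, seed: int = 0,
                        noise_sd: float = 0.02):
    """SWI + acute/chronic FLAIR with planted microbleeds and edema rings.

    Background intensity 1.0 inside an ellipsoidal brain mask; each lesion
    is a hypointense ball on SWI; hyperintense shells (ring_thickness
    beyond the lesion radius) are added on the acute and/or chronic FLAIR
    according to the lesion's flags.  Returns (swi, flair_acute,
    flair_chronic, brain_mask, truth) with truth as a DataFrame.
    """
    shape = tuple(shape)
    affine = np.asarray(affine, dtype=float)
    world = _grid_world(shape, affine).reshape(shape + (3,))
    mask = _ellipsoid_mask(shape)

    swi = np.where(mask, 1.0, 0.0)
    fl_a = np.where(mask, 1.0, 0.0)
    fl_c = np.where(mask, 1.0, 0.0)
    rows = []
    for k, les in enumerate(scene):
        c = np.asarray(les.centre_mm, dtype=float)
        d = np.linalg.norm(world - c, axis=-1)
        ball = (d <= les.radius_mm) & mask
        shell = (d > les.radius_mm) & (d <= les.radius_mm + les.ring_thickness_mm) & mask
        swi[ball] = 1.0 - les.contrast
        if les.acute_ring:
            fl_a[shell] = 1.0 + les.ring_contrast
        if les.chronic_ring:
            fl_c[shell] = 1.0 + les.ring_contrast
        if les.acute_ring and not les.chronic_ring:
            truth_label = "traumatic"
        elif les.acute_ring:
            truth_label = "non_traumatic"
        else:
            truth_label = "indeterminate"
        # does the ball leak outside the mask (boundary-rule exercise)?
        clipped = bool(np.any((d <= les.radius_mm) & ~mask))
        rows.append({"id": k, "x_mm": c[0], "y_mm": c[1], "z_mm": c[2],
                     "radius_mm": les.radius_mm, "contrast": les.contrast,
                     "etiology_truth": truth_label, "affected": les.affected,
                     "boundary_clipped": clipped})
    rng = np.random.default_rng(seed)
    for vol in (swi, fl_a, fl_c):
        vol[mask] += rng.normal(0, noise_sd, int(mask.sum()))
    return swi, fl_a, fl_c, mask, pd.DataFrame(rows)


@dataclass
class SessionData:
    """All volumes and ground truth of one imaging session."""

    tensor_field: TensorField
    fa: np.ndarray
    dwi: np.ndarray
    bundle_mask: np.ndarray
    centerlines: list
    swi: np.ndarray
    flair: np.ndarray
    brain_mask: np.ndarray


@dataclass
class SubjectTruth:
    rotation: np.ndarray
    translation: np.ndarray
    lesion_table: pd.DataFrame
    delta_fa: float
    region_radius_mm: float


def make_longitudinal_subject(spec: LongitudinalSpec, phantom: PhantomSpec,
                              scheme: AcquisitionScheme | None = None):
    """Two-session synthetic subject with known motion and planted changes.

    Session 2 geometry (bundles and lesions) equals session 1 transformed
    by the spec's rigid motion; the planted perilesional FA change is
    applied to session 2 inside spheres of ``region_radius_mm`` around
    each *affected* lesion; each session gets fresh Rician noise.
    Session-1 FLAIR carries the acute rings, session-2 FLAIR the chronic
    ones.  Returns ``(sessions, truth)``.
    """
    if scheme is None:
        scheme = make_scheme()
    rot = rotation_about_axis(spec.rotation_axis, spec.rotation_deg)
    t = np.asarray(spec.translation_mm, dtype=float)
    ss = np.random.SeedSequence([phantom.seed, spec.seed])
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]

    sessions = []
    for k in range(2):
        transform = None if k == 0 else (rot, t)
        field, bmask, cls = make_tensor_phantom(phantom, transform=transform)
        if k == 1 and spec.delta_fa != 0.0 and spec.lesions:
            world = _grid_world(phantom.shape, phantom.affine).reshape(
                phantom.shape + (3,))
            region = np.zeros(phantom.shape, dtype=bool)
            for les in spec.lesions:
                if not les.affected:
                    continue
                c2 = rot @ np.asarray(les.centre_mm, float) + t
                region |= np.linalg.norm(world - c2, axis=-1) <= spec.region_radius_mm
            field = plant_delta_fa(field, region, spec.delta_fa)
        dwi = make_dwi(field, scheme, s0=phantom.s0, snr=phantom.snr,
                       seed=seeds[k])
        fa = tensor_scalars(field).fa
        scene = []
        for les in spec.lesions:
            c = np.asarray(les.centre_mm, float)
            if k == 1:
                c = rot @ c + t
            scene.append(replace(les, centre_mm=tuple(c)))
        swi, fl_a, fl_c, mask, table = make_lesion_volumes(
            scene, phantom.shape, phantom.affine, seed=seeds[2 + k],
            noise_sd=spec.lesion_noise_sd)
        sessions.append(SessionData(
            tensor_field=field, fa=fa, dwi=dwi, bundle_mask=bmask,
            centerlines=cls, swi=swi, flair=fl_a if k == 0 else fl_c,
            brain_mask=mask))
        if k == 0:
            truth_table = table
    truth = SubjectTruth(rotation=rot, translation=t, lesion_table=truth_table,
                         delta_fa=spec.delta_fa,
                         region_radius_mm=spec.region_radius_mm)
    return sessions, truth


def make_cohort(n_per_arm: dict, phantom: PhantomSpec,
                longitudinal: LongitudinalSpec, master_seed: int = 0,
                affected_fraction: float = 0.5, n_lesions: int = 4,
                lesion_sites=None) -> pd.DataFrame:
    """Cohort manifest: per-subject arm, sex, seeds, and planted truth.

    Arms are keyed "mtbi", "old_hc", "young_hc".  mTBI subjects receive
    ``n_lesions`` microbleeds of traumatic etiology at ``lesion_sites``
    (world mm; defaults spread along the first bundle), a planted fraction
    ``affected_fraction`` of which carries the perilesional FA change.
    Healthy-control subjects carry no lesions and no planted change.
    Subject seeds derive deterministically from ``master_seed``.
    """
    ss = np.random.SeedSequence(master_seed)
    rows = []
    sid = 0
    total = sum(n_per_arm.values())
    child = ss.spawn(total)
    for arm, n in n_per_arm.items():
        for k in range(n):
            seed = int(child[sid].generate_state(1)[0] % (2**31))
            n_affected = int(round(affected_fraction * n_lesions)) if arm == "mtbi" else 0
            rows.append({
                "subject": f"{arm}_{k:02d}",
                "arm": arm,
                "sex": "F" if sid % 2 == 0 else "M",
                "seed": seed,
                "n_lesions": n_lesions if arm == "mtbi" else 0,
                "n_affected": n_affected,
            })
            sid += 1
    return pd.DataFrame(rows)
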