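"""Cerebral microbleed (CMB) detection on susceptibility-weighted MRI.

CMBs are small, roughly spherical hemorrhagic lesions that appear as
clearly-margined hypointensities on SWI.  Detection proceeds in stages:

1. intensity normalization by the in-mask median, so thresholds are
   comparable across scanners and subjects;
2. a voxel stage: hypointense voxels (below median - z * robust SD) form
   26-connected candidate components, filtered by physical volume;
   components adjacent to the brain-mask boundary are rejected outright,
   since true CMBs are not connected to the meninges;
3. an object/shape stage: each candidate's sphericity (isoperimetric
   ratio pi^(1/3) (6V)^(2/3) / A of its surface) and margin contrast
   grade it "certain" (small, spherical, clearly defined) or "doubtful"
   (deviating from sphericity or less well defined) following the
   Microbleed Anatomic Rating Scale vocabulary, or reject it;
4. an etiology stage on paired FLAIR scans: a CMB is called traumatic
   when a perilesional FLAIR hyperintense ring is present acutely
   (post-traumatic edema) and has resolved by the chronic scan; a ring
   persisting across sessions points to a chronic small-vessel cause
   instead (hypertensive vasculopathy, amyloid angiopathy).

All numeric cut-offs live in :class:`DetectorParams` and are deliberately
exposed: they are operating points, not physical constants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure

__all__ = [
    "DetectorParams",
    "CmbRecord",
    "normalize_intensity",
    "robust_stats",
    "detect_candidates",
    "sphericity",
    "isoperimetric_sphericity",
    "classify_mars",
    "classify_etiology",
    "detect_cmbs",
    "records_to_dataframe",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_MAD_TO_SD = 1.4826  # consistency factor for Gaussian data


@dataclass
class DetectorParams:
    hypo_z: float = 3.0               # z below robust centre for hypointensity
    min_volume_mm3: float = 4.0       # ~2 mm diameter, the conventional CMB floor
    max_volume_mm3: float = 120.0
    sphericity_hi: float = 0.85       # "certain" floor
    sphericity_lo: float = 0.65       # "doubtful" floor
    contrast_hi: float = 0.3
    contrast_lo: float = 0.15
    flair_z: float = 3.0              # z above robust centre for hyperintensity
    ring_coverage: float = 0.5        # min acute shell fraction (condition 1)
    persistence_tol: float = 0.1      # max chronic shell fraction (condition 2)
    presmooth_sigma: float = 0.5      # voxels; Gaussian presmoothing of the
                                      # thresholded volume, suppressing
                                      # single-voxel noise excursions

    def __post_init__(self):
        if not self.min_volume_mm3 < self.max_volume_mm3:
            raise ValueError("min volume must be below max volume")


@dataclass
class CmbRecord:
    voxels: np.ndarray                # (n, 3) int indices
    centroid_world: np.ndarray        # (3,) mm
    volume_mm3: float
    mean_intensity: float
    contrast: float
    sphericity: float
    mars_label: str = "rejected"      # certain | doubtful | rejected
    etiology: str = "indeterminate"   # traumatic | non_traumatic | indeterminate
    reject_reason: str = ""

    def __post_init__(self):
        assert self.volume_mm3 > 0
        assert 0.0 <= self.sphericity <= 1.0
        if self.mars_label == "rejected":
            assert self.reject_reason


def normalize_intensity(volume: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Divide in-mask intensities by the in-mask median; zero outside.

    Leaves the in-mask median of the result at exactly 1 and makes the
    output invariant to any positive rescaling of the raw intensities.
    """
    volume = np.asarray(volume, dtype=float)
    mask = np.asarray(brain_mask, dtype=bool)
    if not mask.any():
        raise ValueError("brain mask is empty")
    med = float(np.median(volume[mask]))
    if med <= 0:
        raise ValueError("non-positive in-mask median intensity")
    out = np.zeros_like(volume)
    out[mask] = volume[mask] / med
    return out


def robust_stats(values: np.ndarray) -> tuple[float, float]:
    """Median and MAD-based robust SD (MAD * 1.4826)."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, _MAD_TO_SD * mad


def _component_slices(labels: np.ndarray, n: int):
    return ndimage.find_objects(labels, max_label=n)


def detect_candidates(swi_norm: np.ndarray, brain_mask: np.ndarray,
                      params: DetectorParams,
                      voxel_size=(1.0, 1.0, 1.0)):
    """Hypointense 26-connected components, volume-filtered.

    Returns ``(kept, boundary_rejected)`` where each element is a list of
    (n, 3) voxel-index arrays.  Components 26-adjacent to the brain-mask
    boundary (including the array edge) go to the second list.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    raw = np.asarray(swi_norm, dtype=float)
    med_r, sd_r = robust_stats(raw[mask])
    hypo_raw = mask & (raw < med_r - params.hypo_z * sd_r)
    if params.presmooth_sigma > 0:
        # smoothed pass localizes candidates (kills isolated noise voxels);
        # mask-normalized smoothing so out-of-mask zeros do not bleed in
        num = ndimage.gaussian_filter(np.where(mask, raw, 0.0), params.presmooth_sigma)
        den = ndimage.gaussian_filter(mask.astype(float), params.presmooth_sigma)
        sm = np.where(mask, num / np.maximum(den, 1e-12), 0.0)
        med_s, sd_s = robust_stats(sm[mask])
        region = mask & (sm < med_s - params.hypo_z * sd_s)
        # refine to raw-hypointense voxels so sizes are not inflated and
        # nearby lesions bridged by smoothing are split again
        hypo = region & hypo_raw
    else:
        hypo = hypo_raw
    labels, n = ndimage.label(hypo, structure=_STRUCT26)
    voxvol = float(np.prod(voxel_size))

    # in-mask voxels adjacent to outside (or to the array edge) = boundary band
    interior = ndimage.binary_erosion(mask, structure=_STRUCT26, border_value=0)
    boundary_band = mask & ~interior

    kept, boundary = [], []
    for lab, sl in enumerate(_component_slices(labels, n), start=1):
        comp = labels[sl] == lab
        idx = np.argwhere(comp) + np.array([s.start for s in sl])
        vol = len(idx) * voxvol
        # the band contains every in-mask voxel 26-adjacent to outside
        # (erosion border_value=0 also catches the array edge)
        touches = bool(np.any(boundary_band[tuple(idx.T)]))
        if touches:
            boundary.append(idx)
            continue
        if params.min_volume_mm3 <= vol <= params.max_volume_mm3:
            kept.append(idx)
    return kept, boundary


def isoperimetric_sphericity(volume: float, area: float) -> float:
    """pi^(1/3) (6 V)^(2/3) / A, clipped into [0, 1]; 1 for a perfect sphere."""
    if area <= 0:
        return 0.0
    psi = np.pi ** (1 / 3) * (6.0 * volume) ** (2 / 3) / area
    return float(np.clip(psi, 0.0, 1.0))


def _voxel_face_surface(comp: np.ndarray, voxel_size) -> float:
    """Exact surface area of the voxelized solid (sum of exposed faces)."""
    vs = np.asarray(voxel_size, dtype=float)
    face_area = [vs[1] * vs[2], vs[0] * vs[2], vs[0] * vs[1]]
    padded = np.pad(comp, 1)
    area = 0.0
    for axis in range(3):
        diff = np.abs(np.diff(padded.astype(np.int8), axis=axis))
        area += diff.sum() * face_area[axis]
    return float(area)


def sphericity(component: np.ndarray, voxel_size=(1.0, 1.0, 1.0),
               smoothing_sigma: float = 1.0) -> float:
    """Sphericity of a binary component via its surface.

    Blob-like components (>= 2 voxels thick in every axis) use a
    marching-cubes mesh of the Gaussian-smoothed occupancy field, which
    suppresses the voxelization staircase; mesh volume comes from the
    divergence theorem.  Thin components (rods, sheets, single voxels)
    fall back to the exact voxel-face surface, where the mesh would be
    unreliable.
    """
    comp = np.asarray(component, dtype=bool)
    if comp.sum() == 0:
        raise ValueError("component is empty")
    vs = np.asarray(voxel_size, dtype=float)
    voxvol = float(np.prod(vs))
    extents = [int(np.ptp(ax)) + 1 for ax in np.nonzero(comp)]

    if min(extents) < 2 or comp.sum() < 8:
        vol = comp.sum() * voxvol
        area = _voxel_face_surface(comp, vs)
        return isoperimetric_sphericity(vol, area)

    pad = int(np.ceil(3 * smoothing_sigma)) + 1
    f = np.pad(comp.astype(float), pad)
    if smoothing_sigma > 0:
        f = ndimage.gaussian_filter(f, smoothing_sigma)
    try:
        verts, faces, _, _ = measure.marching_cubes(f, level=0.5, spacing=tuple(vs))
    except (ValueError, RuntimeError):
        vol = comp.sum() * voxvol
        return isoperimetric_sphericity(vol, _voxel_face_surface(comp, vs))
    area = float(measure.mesh_surface_area(verts, faces))
    tri = verts[faces]
    vol = float(abs(np.einsum("ij,ij->i", tri[:, 0],
                              np.cross(tri[:, 1], tri[:, 2])).sum()) / 6.0)
    return isoperimetric_sphericity(vol, area)


def _shell(comp_mask: np.ndarray, brain_mask: np.ndarray, thickness: int = 1) -> np.ndarray:
    dil = ndimage.binary_dilation(comp_mask, structure=_STRUCT26, iterations=thickness)
    return dil & ~comp_mask & brain_mask


def _component_record(idx: np.ndarray, swi_norm: np.ndarray, brain_mask: np.ndarray,
                      affine: np.ndarray, voxel_size) -> CmbRecord:
    comp_mask = np.zeros(swi_norm.shape, dtype=bool)
    comp_mask[tuple(idx.T)] = True
    shell = _shell(comp_mask, np.asarray(brain_mask, bool), thickness=2)
    mean_in = float(swi_norm[comp_mask].mean())
    bg = float(swi_norm[shell].mean()) if shell.any() else mean_in
    centroid_vox = idx.mean(axis=0)
    centroid_world = affine[:3, :3] @ centroid_vox + affine[:3, 3]
    sl = tuple(slice(idx[:, k].min(), idx[:, k].max() + 1) for k in range(3))
    sph = sphericity(comp_mask[sl], voxel_size)
    return CmbRecord(
        voxels=idx,
        centroid_world=centroid_world,
        volume_mm3=len(idx) * float(np.prod(voxel_size)),
        mean_intensity=mean_in,
        contrast=bg - mean_in,
        sphericity=sph,
        reject_reason="unclassified",
    )


def classify_mars(records: list, params: DetectorParams) -> list:
    """Assign certain / doubtful / rejected labels from shape and contrast."""
    for rec in records:
        if rec.sphericity >= params.sphericity_hi and rec.contrast >= params.contrast_hi:
            rec.mars_label, rec.reject_reason = "certain", ""
        elif rec.sphericity >= params.sphericity_lo or rec.contrast >= params.contrast_lo:
            rec.mars_label, rec.reject_reason = "doubtful", ""
        else:
            rec.mars_label = "rejected"
            rec.reject_reason = "shape"
    return records


def classify_etiology(record: CmbRecord, flair_acute_norm: np.ndarray,
                      flair_chronic_norm: np.ndarray | None,
                      brain_mask: np.ndarray, params: DetectorParams) -> str:
    """Traumatic vs. non-traumatic etiology from the perilesional FLAIR ring.

    Condition 1: on the acute scan, the 1-voxel shell around the lesion is
    hyperintense over at least ``ring_coverage`` of its voxels.
    Condition 2: on the chronic scan, the hyperintense shell fraction has
    dropped to at most ``persistence_tol`` (the edema has resolved).
    Both satisfied -> traumatic; ring present acutely and persisting ->
    non-traumatic; no acute ring (or missing chronic scan) -> indeterminate.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    comp_mask = np.zeros(mask.shape, dtype=bool)
    comp_mask[tuple(record.voxels.T)] = True
    shell = _shell(comp_mask, mask)
    if not shell.any():
        record.etiology = "indeterminate"
        return record.etiology

    def hyper_fraction(flair: np.ndarray) -> float:
        med, sd = robust_stats(flair[mask])
        return float(np.mean(flair[shell] > med + params.flair_z * sd))

    cond1 = hyper_fraction(flair_acute_norm) >= params.ring_coverage
    if flair_chronic_norm is None:
        if cond1:
            warnings.warn("chronic FLAIR missing; etiology indeterminate")
        record.etiology = "indeterminate"
        return record.etiology
    cond2 = hyper_fraction(flair_chronic_norm) <= params.persistence_tol

    if cond1 and cond2:
        record.etiology = "traumatic"
    elif cond1:
        record.etiology = "non_traumatic"
    else:
        record.etiology = "indeterminate"
    return record.etiology


def detect_cmbs(swi: np.ndarray, brain_mask: np.ndarray, affine: np.ndarray,
                params: DetectorParams | None = None,
                flair_acute: np.ndarray | None = None,
                flair_chronic: np.ndarray | None = None,
                voxel_size=None) -> list:
    """Full detection pipeline on raw SWI (+ optional FLAIR pair).

    Returns all candidate records, including rejected ones (with their
    rejection reason), sorted by volume descending.
    """
    if params is None:
        params = DetectorParams()
    affine = np.asarray(affine, dtype=float)
    if voxel_size is None:
        voxel_size = np.abs(np.diag(affine[:3, :3]))
    swi_norm = normalize_intensity(swi, brain_mask)
    kept, boundary = detect_candidates(swi_norm, brain_mask, params, voxel_size)

    records = [_component_record(idx, swi_norm, brain_mask, affine, voxel_size)
               for idx in kept]
    classify_mars(records, params)
    for idx in boundary:
        rec = _component_record(idx, swi_norm, brain_mask, affine, voxel_size)
        rec.mars_label, rec.reject_reason = "rejected", "boundary"
        records.append(rec)

    if flair_acute is not None:
        fa = normalize_intensity(flair_acute, brain_mask)
        fc = (normalize_intensity(flair_chronic, brain_mask)
              if flair_chronic is not None else None)
        for rec in records:
            if rec.mars_label != "rejected":
                classify_etiology(rec, fa, fc, brain_mask, params)
    return sorted(records, key=lambda r: -r.volume_mm3)


def records_to_dataframe(records: list) -> pd.DataFrame:
    """Lesion table (one row per candidate) for CSV/JSON export."""
    rows = []
    for k, r in enumerate(records):
        rows.append({
            "id": k,
            "centroid_x_mm": r.centroid_world[0],
            "centroid_y_mm": r.centroid_world[1],
            "centroid_z_mm": r.centroid_world[2],
            "volume_mm3": r.volume_mm3,
            "mean_intensity": r.mean_intensity,
            "contrast": r.contrast,
            "sphericity": r.sphericity,
            "mars_label": r.mars_label,
            "etiology": r.etiology,
            "reject_reason": r.reject_reason,
        })
    return pd.DataFrame(rows)
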