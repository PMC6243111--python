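"""End-to-end orchestration: detect -> track -> match -> uncertainty -> test.

The subject-level workflow mirrors the stage order of the analysis
flowchart: microbleeds are detected on the first-session SWI (with the
FLAIR pair dating their etiology), tensors are fitted per session and
deterministic tractography run, streamlines are clustered into bundles
and matched within subject across sessions, per-voxel uncertainty is
accumulated from matched healthy-control sessions, and each traumatic
microbleed's perilesional bundle is tested for a between-session change
in mean FA against the pooled control reference distribution, with Holm
family-wise error control within subject.

Healthy-control subjects contribute pseudo-lesion regions of interest at
the same anatomical sites, processed by the identical estimator, so the
reference distribution measures exactly the confound level of the
perilesional statistic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from peritract import alongtract, cmbdetect, diffusion, matching, synthdata, uncertainty
from peritract.matching import Bundle

__all__ = [
    "PipelineConfig",
    "CohortConfig",
    "SubjectBundlePackage",
    "CohortReport",
    "cluster_streamlines",
    "analyze_subject",
    "run_subject",
    "run_cohort",
    "cmb_change_fraction",
]


@dataclass
class PipelineConfig:
    tracking: diffusion.TrackingParams = field(
        default_factory=lambda: diffusion.TrackingParams(seed_spacing=3.0))
    # smoothing + raised torsion floor stabilize kappa/tau on noisy
    # tractography output; oracle-clean curves don't need either
    match: matching.MatchParams = field(default_factory=lambda: matching.MatchParams(
        smooth_sigma=2.0, kappa_floor=0.02, position_weight=1e-3,
        correspondence_metric="position"))
    detector: cmbdetect.DetectorParams = field(
        default_factory=cmbdetect.DetectorParams)
    roi_radius_mm: float | None = None   # None: max(5, 2 x uncertainty radius)
    roi_radius_floor: float = 5.0
    analysis_window_factor: float = 1.5  # FA differencing restricted to track
                                         # samples within factor x roi_radius
                                         # of the lesion (the perilesional
                                         # window); keeps two lesions on one
                                         # tract statistically separable
    coverage: float = alongtract.DEFAULT_COVERAGE
    alpha: float = alongtract.DEFAULT_ALPHA
    fwer_method: str = "holm"
    cluster_linkage_mm: float = 6.0      # single-linkage distance for bundles
    max_streamlines_per_bundle: int = 12
    min_mean_fa: float = 0.3             # discard streamlines whose mean
                                         # sampled FA falls below this; culls
                                         # tracks escaping into the noise floor
    compute_uncertainty: bool = True


@dataclass
class RoiResult:
    roi_id: str
    centre_mm: np.ndarray
    kind: str                 # "cmb" or "pseudo"
    delta_fa: float | None
    n_streamlines: int


@dataclass
class SubjectBundlePackage:
    subject_id: str
    arm: str
    sex: str
    cmb_records: list
    n_streamlines: tuple
    match_results: list
    rois: list
    change_tests: list = field(default_factory=list)
    uncertainty_summary: tuple | None = None

    @property
    def traumatic_cmbs(self) -> list:
        return [r for r in self.cmb_records
                if r.mars_label != "rejected" and r.etiology == "traumatic"]


def _mdf_signatures(streamlines, n_points: int = 15) -> np.ndarray:
    """Equally spaced point signatures for fast bundle clustering."""
    sig = np.empty((len(streamlines), n_points, 3))
    for k, s in enumerate(streamlines):
        t = np.linspace(s.s[0], s.s[-1], n_points)
        for d in range(3):
            sig[k, :, d] = np.interp(t, s.s, s.points[:, d])
    return sig


def cluster_streamlines(streamlines, linkage_mm: float = 6.0) -> list:
    """Group streamlines into bundles by single-linkage MDF distance.

    Uses the minimum-average-direct-flip distance on equally spaced point
    signatures (the QuickBundles metric), fully vectorized, followed by
    connected components of the sub-threshold adjacency graph.
    """
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n = len(streamlines)
    if n == 0:
        return []
    sig = _mdf_signatures(streamlines)
    direct = np.linalg.norm(sig[:, None] - sig[None, :], axis=-1).mean(axis=-1)
    flipped = np.linalg.norm(sig[:, None] - sig[None, :, ::-1], axis=-1).mean(axis=-1)
    dist = np.minimum(direct, flipped)
    adj = csr_matrix(dist <= linkage_mm)
    n_comp, labels = connected_components(adj, directed=False)
    return [np.flatnonzero(labels == c) for c in range(n_comp)]


def _subsample(indices: np.ndarray, streamlines, k: int) -> np.ndarray:
    """Deterministic reduction to at most k streamlines: sort by length
    descending (then index) and take evenly spaced ranks."""
    if len(indices) <= k:
        return indices
    order = sorted(indices, key=lambda i: (-streamlines[i].length, i))
    sel = np.linspace(0, len(order) - 1, k).round().astype(int)
    return np.array([order[i] for i in sel])


def _pair_clusters(clusters_a, clusters_b, streamlines_a, streamlines_b):
    """Greedy pairing of session bundles by centroid distance."""
    ca = [np.mean([streamlines_a[i].points.mean(axis=0) for i in idx], axis=0)
          for idx in clusters_a]
    cb = [np.mean([streamlines_b[j].points.mean(axis=0) for j in idx], axis=0)
          for idx in clusters_b]
    pairs = []
    used = set()
    for i in np.argsort([min(np.linalg.norm(c - d) for d in cb) if cb else np.inf
                         for c in ca]):
        if not cb:
            break
        dists = [np.linalg.norm(ca[i] - d) for d in cb]
        order = np.argsort(dists)
        for j in order:
            if j not in used and dists[j] < 20.0:
                pairs.append((int(i), int(j)))
                used.add(int(j))
                break
    return pairs


def analyze_subject(sessions, subject_id: str = "", arm: str = "", sex: str = "",
                    config: PipelineConfig | None = None,
                    pseudo_sites=None) -> SubjectBundlePackage:
    """Run the full within-subject workflow on two imaging sessions.

    ``sessions`` is a 2-list of :class:`peritract.synthdata.SessionData`
    (or any object with dwi/swi/flair/brain_mask and the grid affine via
    ``tensor_field.affine``).  ``pseudo_sites`` (world mm) adds
    pseudo-lesion ROIs, used on controls to feed the reference
    distribution.
    """
    if config is None:
        config = PipelineConfig()
    s1, s2 = sessions[0], sessions[1]
    affine = s1.tensor_field.affine

    # 1. lesion identification on session-1 SWI, FLAIR pair dates etiology
    records = cmbdetect.detect_cmbs(
        s1.swi, s1.brain_mask, affine, config.detector,
        flair_acute=s1.flair, flair_chronic=s2.flair)

    # 2-3. per-session tensor fit + tractography
    scheme = synthdata.make_scheme()
    streams = []
    fas = []
    for s in (s1, s2):
        fit = diffusion.fit_tensor(s.dwi, scheme, s.brain_mask, affine=affine)
        scal = diffusion.tensor_scalars(fit)
        fas.append(scal.fa)
        raw = diffusion.track(fit, config.tracking, s.brain_mask)
        kept = [sl for sl in raw
                if np.nanmean(diffusion.sample_scalar(scal.fa, affine, sl))
                >= config.min_mean_fa]
        streams.append(kept)
    fa1, fa2 = fas
    st1, st2 = streams

    # 4. bundle clustering and within-subject matching
    cl1 = cluster_streamlines(st1, config.cluster_linkage_mm)
    cl2 = cluster_streamlines(st2, config.cluster_linkage_mm)
    match_results = []
    for i, j in _pair_clusters(cl1, cl2, st1, st2):
        idx1 = _subsample(cl1[i], st1, config.max_streamlines_per_bundle)
        idx2 = _subsample(cl2[j], st2, config.max_streamlines_per_bundle)
        b1 = Bundle([st1[k] for k in idx1], session_id="1")
        b2 = Bundle([st2[k] for k in idx2], session_id="2")
        res = matching.match_bundles(b1, b2, config.match)
        match_results.append((res, b1, b2))

    # 5. uncertainty from the pooled matches
    unc_summary = None
    if config.compute_uncertainty and match_results:
        dep = uncertainty.voxel_displacements(
            match_results, s1.tensor_field.shape, affine, spacing=0.25)
        ufield = uncertainty.uncertainty_field(dep, s1.tensor_field.shape)
        if ufield.valid.any():
            unc_summary = uncertainty.summarize_radius(ufield)

    roi_radius = config.roi_radius_mm
    if roi_radius is None:
        roi_radius = config.roi_radius_floor
        if unc_summary is not None:
            roi_radius = max(roi_radius, 2.0 * unc_summary[0])

    # 6. perilesional (and pseudo) ROI deltas on matched sub-bundles
    rois = []
    traumatic = [r for r in records
                 if r.mars_label != "rejected" and r.etiology == "traumatic"]
    targets = [(f"cmb_{k}", r.centroid_world, "cmb")
               for k, r in enumerate(traumatic)]
    for k, c in enumerate(pseudo_sites or []):
        targets.append((f"pseudo_{k}", np.asarray(c, float), "pseudo"))

    for roi_id, centre, kind in targets:
        delta, n_sl = _roi_delta(match_results, centre, roi_radius,
                                 fa1, fa2, affine, config)
        rois.append(RoiResult(roi_id=roi_id, centre_mm=np.asarray(centre),
                              kind=kind, delta_fa=delta, n_streamlines=n_sl))

    return SubjectBundlePackage(
        subject_id=subject_id, arm=arm, sex=sex, cmb_records=records,
        n_streamlines=(len(st1), len(st2)), match_results=match_results,
        rois=rois, uncertainty_summary=unc_summary)


def _roi_delta(match_results, centre, roi_radius, fa1, fa2, affine, config):
    """Between-session change in perilesional mean FA near a ROI centre.

    Matched streamlines with a point inside the ROI are differenced
    pairwise (each track against its own matched counterpart) over the
    perilesional window (samples within ``analysis_window_factor x
    roi_radius`` of the lesion, mapped into the follow-up session by the
    bundle's global transform), and the per-pair differences averaged.
    Pairwise differencing cancels per-track composition offsets; the
    window keeps lesions on a shared tract statistically separable.
    """
    from peritract.curvegeom import resample
    from peritract.matching import index_correspondence

    centre = np.asarray(centre, float)
    window = config.analysis_window_factor * roi_radius
    spacing = config.match.spacing
    diffs = []
    for res, b1, b2 in match_results:
        t_by_src = {p.source: p.target for p in res.pairs}
        for i, s in enumerate(b1.streamlines):
            if i not in t_by_src:
                continue
            if np.min(np.linalg.norm(s.points - centre, axis=1)) > roi_radius:
                continue
            t = b2.streamlines[t_by_src[i]]
            # transfer the window through the point correspondence so both
            # sessions average FA over the same physical stretch of track
            rs, rt = resample(s, spacing), resample(t, spacing)
            imap = index_correspondence(rs, rt, spacing, metric="position")
            src_idx, tgt_idx = imap.pairs[:, 0], imap.pairs[:, 1]
            inside = np.linalg.norm(rs.points[src_idx] - centre,
                                    axis=1) <= window
            if not inside.any():
                continue
            p1 = diffusion.sample_scalar(fa1, affine, rs)[src_idx[inside]]
            p2 = diffusion.sample_scalar(fa2, affine, rt)[tgt_idx[inside]]
            m1, m2 = np.nanmean(p1), np.nanmean(p2)
            if np.isfinite(m1) and np.isfinite(m2):
                diffs.append(m2 - m1)
    if not diffs:
        return None, 0
    return float(np.mean(diffs)), len(diffs)


def apply_reference_tests(package: SubjectBundlePackage,
                          reference: alongtract.ReferenceDistribution,
                          config: PipelineConfig | None = None) -> SubjectBundlePackage:
    """Test the subject's CMB-ROI deltas against a reference distribution."""
    if config is None:
        config = PipelineConfig()
    deltas = {r.roi_id: r.delta_fa for r in package.rois
              if r.kind == "cmb" and r.delta_fa is not None}
    if deltas:
        package.change_tests = alongtract.test_change(
            deltas, reference, alpha=config.alpha, method=config.fwer_method)
    else:
        package.change_tests = []
    return package


def cmb_change_fraction(package: SubjectBundlePackage) -> float | None:
    """Fraction of traumatic CMBs with a significant perilesional bundle.

    Returns None (missing) when the subject has no traumatic CMBs.
    """
    cmb_rois = [r for r in package.rois if r.kind == "cmb"]
    if not cmb_rois:
        return None
    sig = {t.bundle_id for t in package.change_tests if t.significant}
    hit = sum(1 for r in cmb_rois if r.roi_id in sig)
    return hit / len(cmb_rois)


# ---------------------------------------------------------------------------
# cohort level
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Synthetic cohort: arms, phantom geometry, lesion scene, seeds."""

    n_mtbi: int = 4
    n_old_hc: int = 4
    n_young_hc: int = 2
    phantom: synthdata.PhantomSpec = None  # type: ignore[assignment]
    lesion_sites: list = None              # type: ignore[assignment]
    affected_fraction: float = 0.5
    delta_fa: float = -0.10
    region_radius_mm: float = 14.0
    master_seed: int = 0
    pipeline: PipelineConfig = field(
        default_factory=lambda: PipelineConfig(
            roi_radius_mm=8.0, min_mean_fa=0.8,
            max_streamlines_per_bundle=16))

    def __post_init__(self):
        if self.phantom is None:
            self.phantom = default_phantom()
        if self.lesion_sites is None:
            self.lesion_sites = default_lesion_sites()


def default_phantom(seed: int = 0) -> synthdata.PhantomSpec:
    """Four parallel straight bundles in a 96 mm cube at 2 mm voxels."""
    bundles = [
        synthdata.BundleDescriptor(origin=(14.0, y, z), direction=(1, 0, 0),
                                   extent_mm=66.0, radius_mm=6.0)
        for y in (34.0, 62.0) for z in (34.0, 62.0)
    ]
    return synthdata.PhantomSpec(shape=(48, 48, 48), voxel_size=2.0,
                                 bundles=bundles, snr=30.0, seed=seed)


def default_lesion_sites() -> list:
    """One site per bundle, 6 mm off-axis at the bundle midpoint."""
    return [(47.0, y + (6.0 if y < 48 else -6.0), z)
            for y in (34.0, 62.0) for z in (34.0, 62.0)]


def _subject_package(row, cfg: CohortConfig) -> SubjectBundlePackage:
    phantom = replace(cfg.phantom, seed=int(row["seed"]))
    lesions = []
    pseudo = None
    if row["arm"] == "mtbi":
        n_aff = int(row["n_affected"])
        for k, site in enumerate(cfg.lesion_sites[: int(row["n_lesions"])]):
            lesions.append(synthdata.LesionSpec(
                centre_mm=site, radius_mm=2.5, contrast=0.6,
                ring_thickness_mm=3.0,
                acute_ring=True, chronic_ring=False, affected=k < n_aff))
    else:
        pseudo = cfg.lesion_sites
    lspec = synthdata.LongitudinalSpec(
        lesions=lesions, delta_fa=cfg.delta_fa,
        region_radius_mm=cfg.region_radius_mm, seed=int(row["seed"]))
    sessions, _ = synthdata.make_longitudinal_subject(lspec, phantom)
    compute_unc = cfg.pipeline.compute_uncertainty and row["arm"] == "young_hc"
    pcfg = replace(cfg.pipeline, compute_uncertainty=compute_unc)
    return analyze_subject(sessions, subject_id=row["subject"], arm=row["arm"],
                           sex=row["sex"], config=pcfg, pseudo_sites=pseudo)


@dataclass
class CohortReport:
    references: dict
    packages: list
    fractions: pd.DataFrame
    anova: pd.DataFrame | None
    uncertainty_mm: tuple | None

    def to_json(self, path=None) -> str:
        doc = {
            "references": {
                g: {"mu_ref": r.mu_ref, "sigma_ref": r.sigma_ref, "n": r.n}
                for g, r in self.references.items()
            },
            "subjects": [
                {
                    "subject": p.subject_id,
                    "arm": p.arm,
                    "n_traumatic_cmbs": len(p.traumatic_cmbs),
                    "tests": [
                        {"roi": t.bundle_id, "delta_fa": t.delta_fa,
                         "p_raw": t.p_raw, "p_adjusted": t.p_adjusted,
                         "significant": t.significant}
                        for t in p.change_tests
                    ],
                }
                for p in self.packages
            ],
            "fractions": self.fractions.to_dict(orient="records"),
            "uncertainty_mm": self.uncertainty_mm,
        }
        if self.anova is not None:
            doc["anova"] = json.loads(self.anova.to_json())
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_subject(row, cfg: CohortConfig,
                reference: alongtract.ReferenceDistribution | None = None
                ) -> SubjectBundlePackage:
    """Build and analyze one synthetic subject (manifest row)."""
    package = _subject_package(row, cfg)
    if reference is not None:
        apply_reference_tests(package, reference, cfg.pipeline)
    return package


def run_cohort(cfg: CohortConfig | None = None, verbose: bool = False) -> CohortReport:
    """Full cohort: references from controls, tests on mTBI subjects.

    Control subjects (young and old) contribute pseudo-ROI deltas pooled
    into their group's reference distribution; mTBI subjects are tested
    against the age-matched (old) control reference.
    """
    if cfg is None:
        cfg = CohortConfig()
    manifest = synthdata.make_cohort(
        {"mtbi": cfg.n_mtbi, "old_hc": cfg.n_old_hc, "young_hc": cfg.n_young_hc},
        cfg.phantom, None, master_seed=cfg.master_seed,
        affected_fraction=cfg.affected_fraction,
        n_lesions=len(cfg.lesion_sites))

    packages = []
    ref_values: dict = {"young_hc": [], "old_hc": []}
    for _, row in manifest.iterrows():
        if verbose:
            print(f"  subject {row['subject']}")
        pkg = _subject_package(row, cfg)
        packages.append(pkg)
        if row["arm"] in ref_values:
            ref_values[row["arm"]].extend(
                r.delta_fa for r in pkg.rois
                if r.kind == "pseudo" and r.delta_fa is not None)

    references = {g: alongtract.reference_distribution(v, g)
                  for g, v in ref_values.items() if len(v) >= 2}

    rows = []
    anova_rows = []
    for pkg in packages:
        if pkg.arm == "mtbi" and "old_hc" in references:
            apply_reference_tests(pkg, references["old_hc"], cfg.pipeline)
            frac = cmb_change_fraction(pkg)
            rows.append({"subject": pkg.subject_id, "fraction": frac,
                         "n_cmbs": len([r for r in pkg.rois if r.kind == "cmb"])})
        age = "young" if pkg.arm == "young_hc" else "old"
        dx = "mtbi" if pkg.arm == "mtbi" else "hc"
        for r in pkg.rois:
            if r.delta_fa is not None:
                anova_rows.append({"delta_fa": r.delta_fa, "sex": pkg.sex,
                                   "age_group": age, "diagnosis": dx})

    anova = None
    atab = pd.DataFrame(anova_rows)
    for interaction in (True, False):
        try:
            anova = alongtract.cohort_anova(atab, interaction=interaction)
            break
        except ValueError:
            continue

    unc = [p.uncertainty_summary for p in packages if p.uncertainty_summary]
    unc_mean = (float(np.mean([u[0] for u in unc])),
                float(np.mean([u[1] for u in unc]))) if unc else None

    return CohortReport(references=references, packages=packages,
                        fractions=pd.DataFrame(rows), anova=anova,
                        uncertainty_mm=unc_mean)
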