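"""Within-subject streamline correspondence across imaging sessions.

Two regular space curves that are rigid transforms of one another have
identical curvature/torsion profiles once a one-to-one correspondence of
arc-length samples (a *curve index correspondence*) is established.  This
module scores candidate streamline pairs by the mean squared difference of
their curvature/torsion profiles, assigns a one-to-one matching, computes
a local rigid transform per matched pair via Schoenemann's closed-form
solution to the orthogonal Procrustes problem, and estimates one global
rigid transform by minimizing the pooled squared point-to-point distance
over all matched pairs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np

from peritract.curvegeom import (
    CurveInvariants,
    Streamline,
    invariants,
    resample,
)

__all__ = [
    "Bundle",
    "IndexMap",
    "MatchParams",
    "MatchResult",
    "index_correspondence",
    "feature_distance",
    "procrustes",
    "ProcrustesResult",
    "match_bundles",
]


@dataclass
class Bundle:
    """A set of streamlines sharing one world coordinate frame."""

    streamlines: list
    session_id: str = ""
    label: str = ""

    def __post_init__(self):
        if len(self.streamlines) == 0:
            raise ValueError("bundle must be non-empty")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)


@dataclass
class IndexMap:
    """Correspondence of arc-length sample indices between two curves.

    ``pairs[k] = (i, j)`` links sample i of the source curve to sample j
    of the target curve, both in the curves' original index spaces.
    ``target_reversed`` records whether the target had to be reoriented
    (its start swapped with its end) to align starting ends; ``offset``
    is the integer sample shift of the shorter curve along the longer.
    """

    pairs: np.ndarray  # (m, 2) int
    target_reversed: bool
    offset: int


def _overlap_distance(inv_a: CurveInvariants, inv_b: CurveInvariants,
                      ia: np.ndarray, ib: np.ndarray, tau_weight: float) -> float:
    dk = inv_a.kappa[ia] - inv_b.kappa[ib]
    both_tau = inv_a.tau_defined[ia] & inv_b.tau_defined[ib]
    dt = np.where(both_tau, np.nan_to_num(inv_a.tau[ia]) - np.nan_to_num(inv_b.tau[ib]), 0.0)
    return float(np.mean(dk**2 + tau_weight * dt**2))


def index_correspondence(a: Streamline, b: Streamline, spacing: float,
                         tau_weight: float = 1.0,
                         kappa_floor: float | None = None,
                         metric: str = "features") -> IndexMap:
    """Match equal arc-length samples of two curves from aligned starting ends.

    Both curves are resampled at ``spacing``.  The orientation of the
    target (which end counts as its start) and the integer arc-length
    offset of the shorter curve along the longer are chosen to minimize
    the curvature/torsion feature distance over the overlap
    (``metric="features"``), or the mean Euclidean distance of paired
    points (``metric="position"``) for curves already in a common frame —
    well-posed even for straight curves, whose invariant profiles carry
    no alignment information.  Overhanging samples of the longer curve
    stay unmatched.
    """
    from peritract.curvegeom import KAPPA_FLOOR

    if metric not in ("features", "position"):
        raise ValueError(f"unknown correspondence metric {metric!r}")
    if kappa_floor is None:
        kappa_floor = KAPPA_FLOOR
    ra, rb = resample(a, spacing), resample(b, spacing)
    inv_a = invariants(ra, kappa_floor)
    na, nb = len(ra), len(rb)

    best = None
    for reverse in (False, True):
        cand = rb.reversed() if reverse else rb
        inv_b = invariants(cand, kappa_floor) if metric == "features" else None
        if na <= nb:
            offsets = range(nb - na + 1)
        else:
            offsets = range(na - nb + 1)
        for off in offsets:
            if na <= nb:
                ia = np.arange(na)
                jb = off + ia
            else:
                jb = np.arange(nb)
                ia = off + jb
            if metric == "features":
                d = _overlap_distance(inv_a, inv_b, ia, jb, tau_weight)
            else:
                d = float(np.mean(np.linalg.norm(
                    ra.points[ia] - cand.points[jb], axis=1)))
            key = (d, reverse, off)
            if best is None or key < best[0]:
                best = (key, ia, jb, reverse, off)

    (_, ia, jb, reverse, off) = best[0], best[1], best[2], best[3], best[4]
    if reverse:
        jb = (nb - 1) - jb
    return IndexMap(pairs=np.stack([ia, jb], axis=1), target_reversed=reverse,
                    offset=off)


def feature_distance(a: CurveInvariants, b: CurveInvariants,
                     index_map: IndexMap, tau_weight: float = 1.0) -> float:
    """Mean over corresponded samples of (dkappa)^2 + w (dtau)^2.

    Samples where torsion is undefined on either curve contribute only the
    curvature term.  Target indices are taken in the orientation recorded
    by the index map.
    """
    if len(index_map.pairs) == 0:
        raise ValueError("empty index map")
    ia = index_map.pairs[:, 0]
    jb = index_map.pairs[:, 1]
    if index_map.target_reversed:
        # work in the reoriented frame; kappa and tau are orientation-invariant
        b = CurveInvariants(s=b.s, kappa=b.kappa[::-1], tau=b.tau[::-1],
                            tau_defined=b.tau_defined[::-1])
        jb = (len(b.kappa) - 1) - jb
    return _overlap_distance(a, b, ia, jb, tau_weight)


@dataclass
class ProcrustesResult:
    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,)
    rms: float
    unique: bool = True

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def inverse(self) -> "ProcrustesResult":
        rot = self.rotation.T
        return ProcrustesResult(rotation=rot, translation=-rot @ self.translation,
                                rms=self.rms, unique=self.unique)


def procrustes(p: np.ndarray, q: np.ndarray) -> ProcrustesResult:
    """Closed-form SVD solution of the orthogonal Procrustes problem.

    Finds the proper rotation R and translation t minimizing
    sum |R p_k + t - q_k|^2 after centroid removal; ``rms`` is the root
    mean square of the remaining point-to-point distances.  Collinear or
    otherwise rank-deficient configurations are flagged ``unique=False``
    (the minimizer is then not unique but still optimal).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape or p.ndim != 2 or p.shape[1] != 3:
        raise ValueError("p and q must both be (n, 3)")
    if len(p) < 3:
        raise ValueError("need at least 3 point pairs")
    pc, qc = p.mean(axis=0), q.mean(axis=0)
    h = (p - pc).T @ (q - qc)
    u, sv, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = qc - rot @ pc
    resid = p @ rot.T + t - q
    rms = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    scale = sv[0] if sv[0] > 0 else 1.0
    unique = bool(sv[1] / scale > 1e-9)
    return ProcrustesResult(rotation=rot, translation=t, rms=rms, unique=unique)


@dataclass
class MatchParams:
    spacing: float = 0.5  # mm, arc-length resampling
    ceiling: float = 0.01  # 1/mm^2, max admissible feature distance
    tau_weight: float = 1.0
    optimal: bool = False  # Hungarian assignment instead of greedy
    smooth_sigma: float = 0.0  # mm, optional coordinate smoothing before
                               # invariants (for noisy tractography output)
    kappa_floor: float | None = None  # torsion-undefined threshold override
    position_weight: float = 0.0  # 1/mm^2 per mm; adds spatial proximity to
                                  # the assignment cost, resolving ties among
                                  # geometrically indistinguishable curves
                                  # (e.g. parallel tracks); the feature-
                                  # distance ceiling ignores this term
    correspondence_metric: str = "features"  # alignment of arc-length samples:
                                  # "features" (kappa/tau) or "position"
                                  # (Euclidean; for co-registered sessions
                                  # where constant-curvature stretches make
                                  # the feature profile uninformative)


@dataclass
class MatchedPair:
    source: int
    target: int
    distance: float
    rotation: np.ndarray
    translation: np.ndarray
    residual: float


@dataclass
class MatchResult:
    pairs: list
    global_rotation: np.ndarray
    global_translation: np.ndarray
    unmatched_source: list
    unmatched_target: list

    @property
    def global_affine(self) -> np.ndarray:
        out = np.eye(4)
        out[:3, :3] = self.global_rotation
        out[:3, 3] = self.global_translation
        return out

    def to_json(self, path=None) -> str:
        doc = {
            "pairs": [
                {
                    "source": int(p.source),
                    "target": int(p.target),
                    "feature_distance": float(p.distance),
                    "residual_mm": float(p.residual),
                }
                for p in self.pairs
            ],
            "global_transform": self.global_affine.tolist(),
            "unmatched_source": [int(i) for i in self.unmatched_source],
            "unmatched_target": [int(i) for i in self.unmatched_target],
        }
        text = json.dumps(doc, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def _assignment(dist: np.ndarray, ceiling: float, optimal: bool) -> list:
    """One-to-one assignment below the ceiling.

    Greedy (default): repeatedly take the globally smallest admissible
    distance, ties broken by lower source then target index.  Optimal:
    Hungarian algorithm on the admissible subproblem.
    """
    ns, nt = dist.shape
    if optimal:
        from scipy.optimize import linear_sum_assignment

        big = 1e9
        cost = np.where(dist <= ceiling, dist, big)
        rows, cols = linear_sum_assignment(cost)
        return [(int(i), int(j)) for i, j in zip(rows, cols) if dist[i, j] <= ceiling]
    pairs = []
    used_s = np.zeros(ns, bool)
    used_t = np.zeros(nt, bool)
    order = sorted(
        ((dist[i, j], i, j) for i in range(ns) for j in range(nt)
         if dist[i, j] <= ceiling),
        key=lambda x: (x[0], x[1], x[2]),
    )
    for d, i, j in order:
        if not used_s[i] and not used_t[j]:
            pairs.append((i, j))
            used_s[i] = used_t[j] = True
    return sorted(pairs)


def match_bundles(source: Bundle, target: Bundle,
                  params: MatchParams | None = None) -> MatchResult:
    """Match streamlines across sessions and estimate the global rigid motion.

    Candidate pairs are scored by curvature/torsion feature distance on
    their curve index correspondence; a one-to-one assignment below the
    distance ceiling is computed; each matched pair receives a local
    Procrustes transform; the global transform is a single Procrustes fit
    over all matched point pairs pooled, which directly minimizes the
    total squared inter-curve distance.
    """
    from peritract.curvegeom import KAPPA_FLOOR, smooth

    if params is None:
        params = MatchParams()
    kfloor = params.kappa_floor if params.kappa_floor is not None else KAPPA_FLOOR

    def prep(s):
        s = resample(s, params.spacing)
        if params.smooth_sigma > 0:
            s = resample(smooth(s, params.smooth_sigma), params.spacing)
        return s

    src = [prep(s) for s in source]
    tgt = [prep(t) for t in target]

    dist = np.full((len(src), len(tgt)), np.inf)
    cost = np.full((len(src), len(tgt)), np.inf)
    maps: dict = {}
    inv_src = [invariants(a, kfloor) for a in src]
    inv_tgt = [invariants(b, kfloor) for b in tgt]
    for i, a in enumerate(src):
        for j, b in enumerate(tgt):
            imap = index_correspondence(a, b, params.spacing, params.tau_weight,
                                        kappa_floor=kfloor,
                                        metric=params.correspondence_metric)
            dist[i, j] = feature_distance(inv_src[i], inv_tgt[j], imap,
                                          params.tau_weight)
            maps[(i, j)] = imap
            cost[i, j] = dist[i, j]
            if params.position_weight > 0:
                pa = a.points[imap.pairs[:, 0]]
                pb = b.points[imap.pairs[:, 1]]
                cost[i, j] += params.position_weight * float(
                    np.mean(np.linalg.norm(pa - pb, axis=1)))

    assigned = _assignment(cost, np.inf if params.position_weight > 0
                           else params.ceiling, params.optimal)
    if params.position_weight > 0:
        # the admissibility ceiling still applies to the feature part only
        assigned = [(i, j) for i, j in assigned if dist[i, j] <= params.ceiling]
    if not assigned:
        warnings.warn("no streamline pair below the feature-distance ceiling")
        return MatchResult(pairs=[], global_rotation=np.eye(3),
                           global_translation=np.zeros(3),
                           unmatched_source=list(range(len(src))),
                           unmatched_target=list(range(len(tgt))))

    pairs = []
    pooled_p, pooled_q = [], []
    for i, j in assigned:
        imap = maps[(i, j)]
        pa = src[i].points[imap.pairs[:, 0]]
        pb = tgt[j].points[imap.pairs[:, 1]]
        local = procrustes(pa, pb)
        pairs.append(MatchedPair(source=i, target=j, distance=float(dist[i, j]),
                                 rotation=local.rotation,
                                 translation=local.translation,
                                 residual=local.rms))
        pooled_p.append(pa)
        pooled_q.append(pb)

    glob = procrustes(np.vstack(pooled_p), np.vstack(pooled_q))
    matched_s = {i for i, _ in assigned}
    matched_t = {j for _, j in assigned}
    return MatchResult(
        pairs=pairs,
        global_rotation=glob.rotation,
        global_translation=glob.translation,
        unmatched_source=[i for i in range(len(src)) if i not in matched_s],
        unmatched_target=[j for j in range(len(tgt)) if j not in matched_t],
    )
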