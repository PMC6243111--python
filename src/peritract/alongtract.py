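"""Along-tract FA statistics and longitudinal change testing.

Fractional anisotropy is sampled along each streamline's arc-length
coordinate; pointwise mean and variance over the streamlines of a bundle
form the along-tract profile, restricted to the arc-length interval
covered by a preponderance of the bundle's streamlines.  A bundle's
summary statistic is the mean FA over that common domain.

Longitudinal testing compares each perilesional bundle's between-session
change in mean FA (dFA) against an empirical reference distribution of
such changes built from healthy-control subjects rescanned over a short
interval, pooled within age group: z = (dFA - mu_ref) / sigma_ref with a
two-sided normal p-value and Holm (default) family-wise error control
across the bundles tested within a subject.  A cohort-level ANCOVA of
dFA on age group x diagnosis with sex as covariate is provided alongside
the per-bundle reference test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from peritract.cmbdetect import CmbRecord
from peritract.matching import Bundle

__all__ = [
    "AlongTractProfile",
    "ReferenceDistribution",
    "ChangeTest",
    "perilesional_bundles",
    "common_domain",
    "bundle_mean_fa",
    "reference_distribution",
    "test_change",
    "fwer_adjust",
    "cohort_anova",
    "welch_t",
]

DEFAULT_COVERAGE = 0.8  # fraction of streamlines a coordinate must reach
DEFAULT_ALPHA = 0.05


@dataclass
class AlongTractProfile:
    s: np.ndarray          # arc-length coordinates, mm
    mean_fa: np.ndarray
    var_fa: np.ndarray     # sample variance (n-1); NaN where count < 2
    count: np.ndarray      # contributing streamlines per coordinate


@dataclass
class ReferenceDistribution:
    group: str             # e.g. "young_hc" / "old_hc"
    mu_ref: float
    sigma_ref: float
    n: int
    degenerate: bool = False


@dataclass
class ChangeTest:
    bundle_id: str
    delta_fa: float
    z: float
    p_raw: float
    p_adjusted: float
    significant: bool


def perilesional_bundles(streamlines, cmb: CmbRecord, roi_radius: float) -> Bundle | None:
    """Streamlines with at least one point within ``roi_radius`` of the CMB.

    The CMB centroid (world mm) defines the centre of the perilesional
    region of interest.  Returns None when no streamline qualifies.
    """
    if roi_radius <= 0:
        raise ValueError("roi_radius must be positive")
    centre = np.asarray(cmb.centroid_world, dtype=float)
    selected = [s for s in streamlines
                if np.min(np.linalg.norm(s.points - centre, axis=1)) <= roi_radius]
    if not selected:
        return None
    return Bundle(selected, label=f"cmb_roi_{roi_radius:g}mm")


def common_domain(s_list, coverage: float = DEFAULT_COVERAGE,
                  spacing: float = 0.5) -> tuple[float, float] | None:
    """Maximal arc-length interval covered by >= ``coverage`` of streamlines.

    ``s_list`` holds each streamline's arc-length coordinates on the
    bundle's shared parametrization.  Coverage is evaluated on a grid of
    step ``spacing``; the longest contiguous run of sufficiently covered
    grid points is returned as (s_lo, s_hi), or None if nothing qualifies.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    n = len(s_list)
    lo = min(float(np.min(s)) for s in s_list)
    hi = max(float(np.max(s)) for s in s_list)
    grid = np.arange(lo, hi + spacing / 2, spacing)
    counts = np.zeros(len(grid))
    for s in s_list:
        counts += (grid >= np.min(s) - 1e-9) & (grid <= np.max(s) + 1e-9)
    ok = counts / n >= coverage - 1e-12
    if not ok.any():
        return None
    # longest contiguous run
    best, cur_start, best_run = None, None, 0
    run = 0
    for k, flag in enumerate(ok):
        if flag:
            if run == 0:
                cur_start = k
            run += 1
            if run > best_run:
                best_run, best = run, (cur_start, k)
        else:
            run = 0
    return float(grid[best[0]]), float(grid[best[1]])


def bundle_mean_fa(bundle: Bundle, fa_volume: np.ndarray, affine: np.ndarray,
                   coverage: float = DEFAULT_COVERAGE,
                   spacing: float = 0.5) -> tuple[AlongTractProfile, float]:
    """Pointwise FA statistics on the common domain and the bundle mean.

    Each streamline is resampled to the shared spacing, FA is sampled by
    trilinear interpolation, and coordinates outside the common domain or
    with missing samples are excluded.  The bundle mean is the average of
    the pointwise means over the domain.
    """
    from peritract.curvegeom import resample
    from peritract.diffusion import sample_scalar

    curves = [resample(s, spacing) for s in bundle]
    profiles = [sample_scalar(fa_volume, affine, c) for c in curves]
    s_list = [c.s for c in curves]
    domain = common_domain(s_list, coverage, spacing)
    if domain is None:
        raise ValueError("empty common arc-length domain")
    lo, hi = domain
    grid = np.arange(lo, hi + spacing / 2, spacing)

    n_pts = len(grid)
    sums = np.zeros(n_pts)
    sqs = np.zeros(n_pts)
    counts = np.zeros(n_pts)
    for s, prof in zip(s_list, profiles):
        vals = np.interp(grid, s, prof, left=np.nan, right=np.nan)
        good = np.isfinite(vals)
        sums[good] += vals[good]
        sqs[good] += vals[good] ** 2
        counts[good] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
        var = np.where(counts > 1,
                       (sqs - counts * mean**2) / np.maximum(counts - 1, 1),
                       np.nan)
    var = np.where(counts > 1, np.maximum(var, 0.0), var)
    profile = AlongTractProfile(s=grid, mean_fa=mean, var_fa=var, count=counts)
    return profile, float(np.nanmean(mean))


def reference_distribution(delta_values, group: str) -> ReferenceDistribution:
    """Pooled reference distribution of between-session bundle dFA values.

    ``delta_values`` are per-bundle between-session mean-FA differences
    from matched control bundles, already pooled across the subjects of
    one group (young or old healthy controls).
    """
    d = np.asarray(list(delta_values), dtype=float)
    if len(d) < 2:
        raise ValueError("need at least 2 reference values")
    mu = float(d.mean())
    sigma = float(d.std(ddof=1))
    return ReferenceDistribution(group=group, mu_ref=mu, sigma_ref=sigma,
                                 n=len(d), degenerate=sigma == 0.0)


def fwer_adjust(p_values, method: str = "holm") -> np.ndarray:
    """Family-wise error rate adjustment (Holm step-down or Bonferroni)."""
    p = np.asarray(list(p_values), dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return p
    from statsmodels.stats.multitest import multipletests

    if method not in ("holm", "bonferroni"):
        raise ValueError(f"unknown FWER method {method!r}")
    return multipletests(p, method=method)[1]


def test_change(deltas: dict, reference: ReferenceDistribution,
                alpha: float = DEFAULT_ALPHA, method: str = "holm") -> list:
    """Per-bundle z-test of dFA against the reference, FWER-corrected.

    ``deltas`` maps bundle id -> between-session change in bundle mean FA.
    The null is no between-session difference beyond the confound level
    captured by the reference distribution.
    """
    if reference.degenerate or reference.sigma_ref <= 0:
        raise ValueError("degenerate reference distribution (sigma_ref = 0)")
    ids = list(deltas.keys())
    d = np.array([deltas[i] for i in ids], dtype=float)
    z = (d - reference.mu_ref) / reference.sigma_ref
    p_raw = 2.0 * stats.norm.sf(np.abs(z))
    p_adj = fwer_adjust(p_raw, method=method)
    return [
        ChangeTest(bundle_id=str(i), delta_fa=float(dv), z=float(zv),
                   p_raw=float(pr), p_adjusted=float(pa),
                   significant=bool(pa < alpha))
        for i, dv, zv, pr, pa in zip(ids, d, z, p_raw, p_adj)
    ]


def cohort_anova(table: pd.DataFrame, interaction: bool = True) -> pd.DataFrame:
    """ANCOVA of dFA on age group x diagnosis with sex as covariate.

    ``table`` needs columns ``delta_fa``, ``sex``, ``age_group``,
    ``diagnosis``.  Returns the statsmodels type-II ANOVA table with F and
    p per term; raises on rank-deficient designs, naming the aliased term.
    ``interaction=False`` fits the additive model instead, appropriate
    when a stratification cell is empty by design (e.g. no young
    patients were recruited).
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    required = {"delta_fa", "sex", "age_group", "diagnosis"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    for col in ("sex", "age_group", "diagnosis"):
        levels = table[col].nunique()
        if levels < 2:
            raise ValueError(f"factor {col!r} has {levels} level(s); need >= 2")
    op = "*" if interaction else "+"
    model = smf.ols(
        f"delta_fa ~ C(sex) + C(age_group) {op} C(diagnosis)", data=table
    ).fit()
    if np.linalg.matrix_rank(model.model.exog) < model.model.exog.shape[1]:
        names = model.model.exog_names
        raise ValueError(f"rank-deficient design; aliased among {names}")
    return anova_lm(model, typ=2)


def welch_t(m1: float, s1: float, n1: int, m2: float, s2: float, n2: int):
    """Welch's t statistic and Welch-Satterthwaite degrees of freedom.

    For group summaries (mean, SD, n) with unequal variances:
    t = (m1 - m2) / sqrt(s1^2/n1 + s2^2/n2).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if s1 <= 0 and s2 <= 0:
        raise ValueError("zero variance in both groups")
    v1, v2 = s1**2 / n1, s2**2 / n2
    t = (m1 - m2) / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    return float(t), float(df)
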