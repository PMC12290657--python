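"""Step-profile extraction and the repeated-measures statistical battery.

Profiles are per-subject mean z per gradient step; inference uses a one-way
within-subject ANOVA with Mauchly's sphericity test, Greenhouse-Geisser
correction of the degrees of freedom whenever Mauchly rejects, and Holm
step-down adjusted pairwise paired t-tests as post-hocs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateInputError

__all__ = [
    "StepProfile",
    "PairedTestResult",
    "RmAnovaResult",
    "OverlapCounts",
    "step_profile",
    "mean_gm_z",
    "overlap_counts",
    "paired_t",
    "rm_anova",
    "holm_adjust",
    "holm_posthoc",
]


@dataclass
class StepProfile:
    subject_id: str
    lobule: int
    hemisphere: str
    direction: str
    contrast_name: str
    mean_z: np.ndarray                # length K, NaN where a step is empty
    voxel_counts: np.ndarray          # length K

    @property
    def n_steps(self) -> int:
        return len(self.mean_z)


@dataclass
class PairedTestResult:
    t: float
    df: int
    p: float
    mean_diff: float
    sd_diff: float
    pair: tuple = ()
    p_adjusted: float | None = None


@dataclass
class RmAnovaResult:
    """One-way repeated-measures ANOVA with sphericity diagnostics.

    ``df1``/``df2``/``p`` are Greenhouse-Geisser corrected when ``corrected``
    is set (Mauchly p below the trigger); the uncorrected values are always
    retained alongside.
    """

    F: float
    df1: float
    df2: float
    p: float
    mauchly_W: float
    mauchly_p: float
    gg_epsilon: float
    corrected: bool
    p_uncorrected: float
    n_subjects: int
    n_levels: int


@dataclass
class OverlapCounts:
    only_a: int
    only_b: int
    both: int


def step_profile(zmap, stepmap, gm_mask: np.ndarray, subject_id: str = "") -> StepProfile:
    """Mean z per gradient step within the grey-matter mask.

    Empty steps are recorded as NaN (missing), never 0.
    """
    gm = gm_mask.astype(bool)
    K = stepmap.n_steps
    mean_z = np.full(K, np.nan)
    counts = np.zeros(K, dtype=int)
    zdata = zmap.z if hasattr(zmap, "z") else np.asarray(zmap)
    for s in range(1, K + 1):
        sel = (stepmap.steps == s) & gm
        n = int(np.count_nonzero(sel))
        counts[s - 1] = n
        if n:
            mean_z[s - 1] = float(zdata[sel].mean())
    return StepProfile(
        subject_id=subject_id,
        lobule=stepmap.lobule,
        hemisphere=stepmap.hemisphere,
        direction=stepmap.direction,
        contrast_name=getattr(zmap, "name", ""),
        mean_z=mean_z,
        voxel_counts=counts,
    )


def mean_gm_z(zmap, gm_mask: np.ndarray) -> float:
    """Mean z over the grey-matter mask."""
    gm = gm_mask.astype(bool)
    if not gm.any():
        raise DegenerateInputError("grey-matter mask is empty")
    zdata = zmap.z if hasattr(zmap, "z") else np.asarray(zmap)
    return float(zdata[gm].mean())


def overlap_counts(mask_a: np.ndarray, mask_b: np.ndarray, roi: np.ndarray | None = None) -> OverlapCounts:
    """Voxels active only in A, only in B, and in both, within an ROI."""
    a = mask_a.astype(bool)
    b = mask_b.astype(bool)
    if roi is not None:
        r = roi.astype(bool)
        a, b = a & r, b & r
    return OverlapCounts(
        only_a=int(np.count_nonzero(a & ~b)),
        only_b=int(np.count_nonzero(b & ~a)),
        both=int(np.count_nonzero(a & b)),
    )


def paired_t(a, b) -> PairedTestResult:
    """Two-sided paired t-test, closed form."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be 1D vectors of equal length")
    n = len(a)
    if n < 2:
        raise DegenerateInputError("need at least 2 pairs")
    d = a - b
    md = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if md == 0.0:
            return PairedTestResult(t=0.0, df=n - 1, p=1.0, mean_diff=0.0, sd_diff=0.0)
        raise DegenerateInputError("zero variance of differences with nonzero mean")
    t = md / (sd / math.sqrt(n))
    p = 2.0 * stats.t.sf(abs(t), n - 1)
    return PairedTestResult(t=t, df=n - 1, p=min(p, 1.0), mean_diff=md, sd_diff=sd)


def _gg_epsilon(S: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the double-centred covariance."""
    K = S.shape[0]
    H = np.eye(K) - np.ones((K, K)) / K
    Sdc = H @ S @ H
    tr = np.trace(Sdc)
    denom = (K - 1) * np.sum(Sdc * Sdc)
    if denom <= 0:
        return 1.0
    eps = tr * tr / denom
    return float(np.clip(eps, 1.0 / (K - 1), 1.0))


def _mauchly(S: np.ndarray, n: int) -> tuple[float, float]:
    """Mauchly's W on the orthonormal-contrast covariance with the standard
    chi-square approximation.  Returns (W, p); trivially (1, 1) for K = 2."""
    K = S.shape[0]
    if K == 2:
        return 1.0, 1.0
    # orthonormal contrast basis: Helmert rows, normalised
    C = np.linalg.qr(np.eye(K) - np.ones((K, K)) / K)[0][:, : K - 1]
    Sc = C.T @ S @ C
    eig = np.linalg.eigvalsh(Sc)
    eig = np.clip(eig, 0.0, None)
    mean_eig = eig.mean()
    if mean_eig <= 0 or np.any(eig <= 0):
        return 0.0, 0.0
    W = float(np.exp(np.sum(np.log(eig)) - (K - 1) * math.log(mean_eig)))
    W = min(W, 1.0)
    d = K - 1
    f = 1.0 - (2.0 * d * d + d + 2.0) / (6.0 * d * (n - 1))
    chi2 = -(n - 1) * f * math.log(max(W, np.finfo(float).tiny))
    df = K * (K - 1) // 2 - 1
    p = float(stats.chi2.sf(chi2, df))
    return W, p


def rm_anova(table, gg_trigger_alpha: float = 0.05) -> RmAnovaResult:
    """One-way within-subject ANOVA on an ``n_subjects x K`` table.

    Decomposes SS_total into subject, level (step) and error components;
    F = MS_steps / MS_error with (K-1, (K-1)(n-1)) df.  When Mauchly's test
    rejects sphericity at ``gg_trigger_alpha``, the reported ``p`` uses
    Greenhouse-Geisser shrunken degrees of freedom; both p-values are kept.
    Subjects with any missing (NaN) level are dropped with a warning.
    """
    X = np.asarray(table, dtype=float)
    if X.ndim != 2:
        raise ValueError("table must be 2D (subjects x levels)")
    bad = np.isnan(X).any(axis=1)
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} subject(s) with missing steps from the ANOVA")
        X = X[~bad]
    n, K = X.shape
    if n < 2 or K < 2:
        raise DegenerateInputError("need at least 2 subjects and 2 levels")

    grand = X.mean()
    subj_means = X.mean(axis=1)
    step_means = X.mean(axis=0)
    ss_total = float(((X - grand) ** 2).sum())
    ss_subjects = float(K * ((subj_means - grand) ** 2).sum())
    ss_steps = float(n * ((step_means - grand) ** 2).sum())
    ss_error = ss_total - ss_subjects - ss_steps
    df1 = K - 1
    df2 = (K - 1) * (n - 1)
    ms_error = ss_error / df2
    if ms_error <= 0:
        if ss_steps <= 1e-12 * max(ss_total, 1.0):
            # no within-subject variation at all: vacuous test
            return RmAnovaResult(F=0.0, df1=float(df1), df2=float(df2), p=1.0,
                                 mauchly_W=1.0, mauchly_p=1.0, gg_epsilon=1.0,
                                 corrected=False, p_uncorrected=1.0,
                                 n_subjects=n, n_levels=K)
        raise DegenerateInputError("zero within-subject error variance")
    F = (ss_steps / df1) / ms_error
    p_unc = float(stats.f.sf(F, df1, df2))

    S = np.cov(X, rowvar=False)
    W, p_mauchly = _mauchly(S, n)
    eps = _gg_epsilon(S)
    corrected = p_mauchly < gg_trigger_alpha
    if corrected:
        cdf1 = eps * df1
        cdf2 = eps * df2
        p = float(stats.f.sf(F, cdf1, cdf2))
        return RmAnovaResult(F=F, df1=cdf1, df2=cdf2, p=p, mauchly_W=W, mauchly_p=p_mauchly,
                             gg_epsilon=eps, corrected=True, p_uncorrected=p_unc,
                             n_subjects=n, n_levels=K)
    return RmAnovaResult(F=F, df1=float(df1), df2=float(df2), p=p_unc, mauchly_W=W,
                         mauchly_p=p_mauchly, gg_epsilon=eps, corrected=False,
                         p_uncorrected=p_unc, n_subjects=n, n_levels=K)


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment: sort ascending, adj_p(i) is the running
    maximum of ``min(1, (m - j + 1) * p(j))`` over j <= i."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum(1.0, (m - np.arange(m)) * p[order])
    adj_sorted = np.maximum.accumulate(adj_sorted)
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj


def holm_posthoc(table) -> list[PairedTestResult]:
    """All pairwise paired t-tests between levels, Holm-adjusted as one
    family.  Returns results ordered by level pair (i, j), i < j, with
    1-based pair indices."""
    X = np.asarray(table, dtype=float)
    bad = np.isnan(X).any(axis=1)
    X = X[~bad]
    n, K = X.shape
    results = []
    for i in range(K):
        for j in range(i + 1, K):
            r = paired_t(X[:, i], X[:, j])
            r.pair = (i + 1, j + 1)
            results.append(r)
    adj = holm_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adjusted = float(a)
    return results
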