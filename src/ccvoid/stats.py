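"""Reliability and diurnal-variation inference.

One-way within-subject (repeated-measures) ANOVA over timepoints, with
Mauchly's sphericity test and the Greenhouse–Geisser degrees-of-freedom
correction, mirrors the standard workflow for diurnal designs: the GG
adjustment is applied conditionally, when Mauchly rejects sphericity at 0.05
(policy "conditional"), or unconditionally (policy "always"). Intraclass
correlation quantifies grader agreement; the default ICC(2,1) — two-way
random effects, absolute agreement, single measurement — is the model
appropriate for interchangeable graders.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats as sps

from .errors import UsageError, ValidationError


@dataclass
class LongitudinalMatrix:
    """Subjects × timepoints measurements for one visit and one variable."""

    values: np.ndarray
    subject_ids: Optional[Sequence] = None
    timepoints: Optional[Sequence] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise UsageError("values must be a 2-D subjects x timepoints matrix")
        n, k = self.values.shape
        if n < 2 or k < 2:
            raise UsageError("need at least 2 subjects and 2 timepoints")
        if not np.all(np.isfinite(self.values)):
            raise UsageError("missing cells remain; apply listwise deletion first")
        if self.subject_ids is None:
            self.subject_ids = list(range(n))
        if self.timepoints is None:
            self.timepoints = list(range(k))

    @classmethod
    def from_long(cls, df: pd.DataFrame, value: str, subject: str = "subject_id",
                  timepoint: str = "timepoint") -> "LongitudinalMatrix":
        """Pivot a long table; subjects with any missing timepoint are dropped."""
        wide = df.pivot_table(index=subject, columns=timepoint, values=value,
                              aggfunc="mean", sort=False)
        complete = wide.dropna()
        dropped = len(wide) - len(complete)
        if dropped:
            warnings.warn(f"listwise deletion removed {dropped} subject(s)")
        return cls(complete.to_numpy(), list(complete.index), list(complete.columns))

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[1]


@dataclass
class MauchlyResult:
    W: float
    chi2: float
    df: int
    p: float


@dataclass
class RMAnovaResult:
    """One-way within-subject ANOVA with sphericity diagnostics."""

    F: float
    df_num: float
    df_den: float
    p_unadjusted: float
    mauchly_W: float
    mauchly_p: float
    gg_epsilon: float
    df_num_adj: float
    df_den_adj: float
    p_gg: float
    p_reported: float
    policy: str
    degenerate: Optional[str] = None

    def __post_init__(self) -> None:
        for p in (self.p_unadjusted, self.p_gg, self.p_reported, self.mauchly_p):
            if not (0.0 <= p <= 1.0 or np.isnan(p)):
                raise ValidationError("p values must lie in [0, 1]")


@dataclass
class ICCResult:
    icc: float
    model: str
    ci95: tuple
    degenerate: Optional[str] = None


# ---------------------------------------------------------------------------
# internals


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k matrix with orthonormal rows orthogonal to the unit vector."""
    return linalg.helmert(k)


def _anova_decomposition(X: np.ndarray):
    n, k = X.shape
    grand = X.mean()
    ss_time = n * np.sum((X.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((X.mean(axis=1) - grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_err = ss_total - ss_time - ss_subj
    return ss_time, ss_subj, max(ss_err, 0.0)


def mauchly_test(data: LongitudinalMatrix) -> MauchlyResult:
    """Mauchly's W with its chi-square approximation.

    W = det(S*) / (tr(S*)/(k-1))^(k-1), where S* is the sample covariance of
    the timepoint measures projected onto orthonormal contrasts; df =
    k(k-1)/2 - 1. For k = 2 sphericity holds trivially (W = 1, p = 1); a
    singular S* yields W = 0 with p ~ 0 and a warning (e.g. when n <= k).
    """
    X = data.values
    n, k = X.shape
    if k == 2:
        return MauchlyResult(W=1.0, chi2=0.0, df=0, p=1.0)
    C = _orthonormal_contrasts(k)
    S = np.cov(X, rowvar=False, ddof=1)
    St = C @ S @ C.T
    d = k - 1
    tr = np.trace(St)
    det = np.linalg.det(St)
    if tr <= 0 or det <= np.finfo(float).tiny:
        warnings.warn("singular contrast covariance; Mauchly W set to 0")
        return MauchlyResult(W=0.0, chi2=np.inf, df=int(k * (k - 1) / 2 - 1), p=0.0)
    W = float(det / (tr / d) ** d)
    f = 1.0 - (2 * d ** 2 + d + 2) / (6.0 * d * (n - 1))
    chi2 = float(-(n - 1) * f * np.log(W))
    df = int(k * (k - 1) / 2 - 1)
    p = float(sps.chi2.sf(chi2, df))
    return MauchlyResult(W=W, chi2=chi2, df=df, p=p)


def gg_epsilon(data: LongitudinalMatrix) -> float:
    """Greenhouse–Geisser epsilon from the orthonormalized covariance.

    eps = (sum lambda)^2 / ((k-1) * sum lambda^2) over eigenvalues of the
    contrast-projected covariance, clamped to [1/(k-1), 1]. Equals 1 under
    perfect sphericity and 1/(k-1) for a rank-one covariance.
    """
    X = data.values
    k = X.shape[1]
    if k == 2:
        return 1.0
    C = _orthonormal_contrasts(k)
    St = C @ np.cov(X, rowvar=False, ddof=1) @ C.T
    lam = np.linalg.eigvalsh(St)
    d = k - 1
    denom = d * np.sum(lam ** 2)
    if denom <= 0:
        return 1.0
    eps = float(np.sum(lam) ** 2 / denom)
    return float(np.clip(eps, 1.0 / d, 1.0))


def rm_anova(data: LongitudinalMatrix, policy: str = "conditional",
             alpha_sphericity: float = 0.05) -> RMAnovaResult:
    """One-way repeated-measures ANOVA: F = MS_time / MS_(subject x time).

    ``policy`` selects ``p_reported``: "conditional" reports the GG-adjusted
    p when Mauchly's test rejects sphericity (p < ``alpha_sphericity``) and
    the unadjusted p otherwise; "always" reports the GG-adjusted p
    unconditionally. Zero within-subject variance is flagged degenerate with
    F = 0, p = 1; a perfect time effect (zero error) is flagged with
    F = inf, p = 0.
    """
    if policy not in ("conditional", "always"):
        raise UsageError(f"unknown GG policy {policy!r}")
    X = data.values
    n, k = X.shape
    ss_time, _, ss_err = _anova_decomposition(X)
    df_num = float(k - 1)
    df_den = float((n - 1) * (k - 1))
    ms_time = ss_time / df_num
    ms_err = ss_err / df_den

    degenerate = None
    scale = max(np.abs(X).max(), 1.0)
    tol = (1e-12 * scale) ** 2 * n * k
    if ss_err <= tol:
        if ss_time <= tol:
            # every subject constant across timepoints
            return RMAnovaResult(
                F=0.0, df_num=df_num, df_den=df_den, p_unadjusted=1.0,
                mauchly_W=np.nan, mauchly_p=np.nan, gg_epsilon=np.nan,
                df_num_adj=df_num, df_den_adj=df_den, p_gg=1.0,
                p_reported=1.0, policy=policy, degenerate="zero_within_subject_variance")
        return RMAnovaResult(
            F=np.inf, df_num=df_num, df_den=df_den, p_unadjusted=0.0,
            mauchly_W=np.nan, mauchly_p=np.nan, gg_epsilon=np.nan,
            df_num_adj=df_num, df_den_adj=df_den, p_gg=0.0,
            p_reported=0.0, policy=policy, degenerate="perfect_fit")

    F = float(ms_time / ms_err)
    p_unadj = float(sps.f.sf(F, df_num, df_den))
    mauchly = mauchly_test(data)
    eps = gg_epsilon(data)
    df_num_adj = eps * df_num
    df_den_adj = eps * df_den
    p_gg = float(sps.f.sf(F, df_num_adj, df_den_adj))
    if policy == "always":
        p_reported = p_gg
    else:
        p_reported = p_gg if mauchly.p < alpha_sphericity else p_unadj
    return RMAnovaResult(
        F=F, df_num=df_num, df_den=df_den, p_unadjusted=p_unadj,
        mauchly_W=mauchly.W, mauchly_p=mauchly.p, gg_epsilon=eps,
        df_num_adj=df_num_adj, df_den_adj=df_den_adj, p_gg=p_gg,
        p_reported=p_reported, policy=policy, degenerate=degenerate)


# ---------------------------------------------------------------------------
# intraclass correlation

ICC_MODELS = ("icc2_1", "icc3_1")


def icc(ratings: np.ndarray, model: str = "icc2_1",
        confidence: float = 0.95) -> ICCResult:
    """Single-measurement intraclass correlation from two-way ANOVA mean squares.

    ``ratings`` is subjects x raters. ``icc2_1`` is two-way random effects,
    absolute agreement (rater offsets count as disagreement); ``icc3_1`` is
    two-way mixed, consistency (offsets forgiven). The 95% CI uses the
    standard F-based interval (Shrout & Fleiss). Zero between-subject
    variance leaves the ICC undefined (NaN, flagged).
    """
    if model not in ICC_MODELS:
        raise UsageError(f"unknown ICC model {model!r}; choose from {ICC_MODELS}")
    X = np.asarray(ratings, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise UsageError("ratings must be subjects x raters with >= 2 of each")
    n, k = X.shape
    ss_rater, ss_subj, ss_err = _anova_decomposition(X)
    msr = ss_subj / (n - 1)          # rows: subjects
    msc = ss_rater / (k - 1)         # columns: raters
    mse = ss_err / ((n - 1) * (k - 1))

    if np.var(X.mean(axis=1)) == 0:
        warnings.warn("zero between-subject variance; ICC undefined")
        return ICCResult(icc=np.nan, model=model, ci95=(np.nan, np.nan),
                         degenerate="zero_between_subject_variance")

    alpha = 1.0 - confidence
    if model == "icc3_1":
        denom = msr + (k - 1) * mse
        val = (msr - mse) / denom if denom > 0 else 1.0
        if mse == 0:
            return ICCResult(icc=1.0, model=model, ci95=(1.0, 1.0))
        F = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = F / sps.f.ppf(1 - alpha / 2, df1, df2)
        fu = F * sps.f.ppf(1 - alpha / 2, df2, df1)
        lower = (fl - 1) / (fl + k - 1)
        upper = (fu - 1) / (fu + k - 1)
        return ICCResult(icc=float(val), model=model,
                         ci95=(float(lower), float(min(upper, 1.0))))

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return ICCResult(icc=np.nan, model=model, ci95=(np.nan, np.nan),
                         degenerate="non_positive_denominator")
    val = float((msr - mse) / denom)
    if mse == 0 and msc == 0:
        return ICCResult(icc=1.0, model=model, ci95=(1.0, 1.0))
    # Shrout & Fleiss (1979) interval for ICC(2,1)
    fj = msc / mse if mse > 0 else np.inf
    a = k * val / (n * (1 - val)) if val < 1 else np.inf
    b = 1 + k * val * (n - 1) / (n * (1 - val)) if val < 1 else np.inf
    if np.isfinite(fj) and np.isfinite(a) and np.isfinite(b):
        v = ((a * fj + b) ** 2 /
             (a ** 2 * fj ** 2 / (k - 1) + b ** 2 / (n - 1)))
        f_l = sps.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sps.f.ppf(1 - alpha / 2, v, n - 1)
        lower = (n * (msr - f_l * mse) /
                 (f_l * (k * msc + (k * n - k - n) * mse) + n * msr))
        upper = (n * (f_u * msr - mse) /
                 (k * msc + (k * n - k - n) * mse + n * f_u * msr))
        ci = (float(lower), float(min(upper, 1.0)))
    else:
        ci = (np.nan, np.nan)
    return ICCResult(icc=val, model=model, ci95=ci)
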