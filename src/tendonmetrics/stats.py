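"""Group statistics: ANOVA / Kruskal-Wallis with eta-squared, normality
gating, Pearson correlation, and 1D statistical parametric mapping (SPM).

Scalar endpoints (volume, length, CSA, stiffness, modulus, T2*, ...) are
compared between two groups with a classical one-way ANOVA, replaced by a
Kruskal-Wallis H-test when either group fails a Shapiro-Wilk normality check
(this is the conventional gate for skewed endpoints such as T2*).  Effect
sizes are eta-squared: SS_between / SS_total for ANOVA (equal to
F / (F + df2) when df1 = 1) and (H - k + 1) / (n - k) for Kruskal-Wallis.

Regional CSA profiles (101 stations at 1% of tendon length) are compared
with a two-sample t-test at every station.  Field-wise inference is
nonparametric by default: group labels are permuted, the max-|t| distribution
sets the critical threshold at the chosen alpha, and supra-threshold
clusters receive p-values from the permutation distribution of maximal
cluster mass (the integral of |t| above the threshold).  A parametric
1D random-field-theory threshold is available as an alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.optimize import brentq

from tendonmetrics.geometry import CSAProfile

__all__ = [
    "GroupTestResult",
    "SPMResult",
    "one_way_anova",
    "kruskal_wallis",
    "shapiro_wilk",
    "pearson_correlation",
    "spm_ttest_profiles",
    "gated_group_test",
    "eta_squared_from_f",
    "eta_squared_from_h",
]


def eta_squared_from_f(f: float, df2: int, df1: int = 1) -> float:
    """Eta-squared from a one-way F statistic: (df1*F) / (df1*F + df2).

    For a two-group design (df1 = 1) this reduces to F / (F + df2) and
    equals SS_between / SS_total.
    """
    return (df1 * f) / (df1 * f + df2)


def eta_squared_from_h(h: float, k: int, n: int) -> float:
    """Eta-squared for a Kruskal-Wallis H with k groups and n observations:
    (H - k + 1) / (n - k)."""
    return (h - k + 1) / (n - k)


@dataclass(frozen=True)
class GroupTestResult:
    """Outcome of a two-group scalar comparison."""

    test: Literal["anova", "kruskal"]
    statistic: float  # F or H
    df: tuple[int, int] | int  # (df1, df2) for ANOVA, k-1 for Kruskal-Wallis
    p: float
    eta_squared: float

    def to_dict(self) -> dict:
        return {
            "test": self.test,
            "statistic": self.statistic,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p": self.p,
            "eta_squared": self.eta_squared,
        }


def one_way_anova(group_a: Sequence[float], group_b: Sequence[float]) -> GroupTestResult:
    """Classical one-way F-test for two groups with eta-squared.

    eta^2 = SS_between / SS_total, which for df1 = 1 equals F / (F + df2).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    pooled = np.concatenate([a, b])
    grand = pooled.mean()
    ss_total = float(np.sum((pooled - grand) ** 2))
    if ss_total <= 0:
        raise ValueError("zero total variance: F undefined")
    ss_between = float(
        len(a) * (a.mean() - grand) ** 2 + len(b) * (b.mean() - grand) ** 2
    )
    ss_within = ss_total - ss_between
    df1, df2 = 1, len(pooled) - 2
    f = (ss_between / df1) / (ss_within / df2) if ss_within > 0 else np.inf
    p = float(sps.f.sf(f, df1, df2))
    return GroupTestResult(
        test="anova",
        statistic=float(f),
        df=(df1, df2),
        p=p,
        eta_squared=ss_between / ss_total,
    )


def kruskal_wallis(group_a: Sequence[float], group_b: Sequence[float]) -> GroupTestResult:
    """Rank-based Kruskal-Wallis H-test (tie corrected) with eta-squared
    computed as (H - k + 1) / (n - k)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    n, k = len(a) + len(b), 2
    if np.ptp(np.concatenate([a, b])) == 0:
        h, p = 0.0, 1.0  # all values tied
    else:
        h, p = sps.kruskal(a, b)
    return GroupTestResult(
        test="kruskal",
        statistic=float(h),
        df=k - 1,
        p=float(p),
        eta_squared=(float(h) - k + 1) / (n - k),
    )


def shapiro_wilk(values: Sequence[float]) -> tuple[float, float]:
    """Shapiro-Wilk W statistic and p-value (3 <= n <= 5000)."""
    v = np.asarray(values, dtype=float)
    if not (3 <= len(v) <= 5000):
        raise ValueError("Shapiro-Wilk needs 3 <= n <= 5000")
    if np.ptp(v) == 0:
        raise ValueError("constant input: W undefined")
    w, p = sps.shapiro(v)
    return float(w), float(p)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided p-value."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if len(xv) != len(yv) or len(xv) < 3:
        raise ValueError("need matched samples with n >= 3")
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        raise ValueError("zero variance input: r undefined")
    r, p = sps.pearsonr(xv, yv)
    return float(r), float(p)


def gated_group_test(
    group_a: Sequence[float], group_b: Sequence[float], alpha: float = 0.05
) -> GroupTestResult:
    """ANOVA when both groups pass Shapiro-Wilk at ``alpha``, otherwise
    Kruskal-Wallis."""
    normal = all(shapiro_wilk(g)[1] >= alpha for g in (group_a, group_b))
    test = one_way_anova if normal else kruskal_wallis
    return test(group_a, group_b)


# ---------------------------------------------------------------------------
# 1D statistical parametric mapping


@dataclass(frozen=True)
class SPMResult:
    """Station-wise t-curve with field-wise threshold and clusters.

    ``clusters`` holds (start %, end %, cluster p) for each maximal
    contiguous supra-threshold run of |t|.
    """

    t_curve: np.ndarray  # 101 values
    critical_threshold: float
    clusters: list[tuple[float, float, float]]
    method: Literal["permutation", "rft"]

    @property
    def significant(self) -> bool:
        return bool(self.clusters)

    def to_dataframe(self) -> pd.DataFrame:
        in_cluster = np.zeros(101, dtype=bool)
        for start, end, _ in self.clusters:
            in_cluster[int(round(start)) : int(round(end)) + 1] = True
        return pd.DataFrame(
            {
                "percent": np.arange(101),
                "t": self.t_curve,
                "threshold": self.critical_threshold,
                "in_cluster": in_cluster,
            }
        )


def _as_matrix(profiles: Iterable) -> np.ndarray:
    rows = []
    for p in profiles:
        rows.append(p.csa if isinstance(p, CSAProfile) else np.asarray(p, float))
    mat = np.asarray(rows, dtype=float)
    if mat.ndim != 2 or mat.shape[1] != 101:
        raise ValueError("profiles must share the common 101-point grid")
    return mat


def _t_curves(pooled: np.ndarray, member_a: np.ndarray) -> np.ndarray:
    """Two-sample t at every station for many label assignments at once.

    ``pooled`` is (n, q); ``member_a`` a boolean (P, n) matrix, one row per
    label assignment (True = group A).  Returns (P, q) t-values.
    """
    n, _ = pooled.shape
    na = member_a[0].sum()
    nb = n - na
    ba = member_a.astype(float)
    sum_a = ba @ pooled
    sumsq_a = ba @ pooled**2
    tot = pooled.sum(axis=0)
    totsq = (pooled**2).sum(axis=0)
    mean_a = sum_a / na
    mean_b = (tot - sum_a) / nb
    ss_a = sumsq_a - na * mean_a**2
    ss_b = (totsq - sumsq_a) - nb * mean_b**2
    sp2 = (ss_a + ss_b) / (n - 2)
    denom = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
    diff = mean_a - mean_b
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / denom
    # zero pooled variance: infinite t in the direction of the mean shift
    degenerate = np.where(diff > 0, np.inf, np.where(diff < 0, -np.inf, 0.0))
    return np.where(denom > 0, t, degenerate)


def _cluster_masses(abs_t: np.ndarray, threshold: float) -> list[tuple[int, int, float]]:
    """Maximal contiguous supra-threshold runs with their masses
    (sum of |t| - threshold over the run)."""
    supra = abs_t >= threshold
    clusters = []
    start = None
    for i, flag in enumerate(supra):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            clusters.append((start, i - 1, float(np.sum(abs_t[start:i] - threshold))))
            start = None
    if start is not None:
        clusters.append(
            (start, len(supra) - 1, float(np.sum(abs_t[start:] - threshold)))
        )
    return clusters


def _max_cluster_mass(abs_t_rows: np.ndarray, threshold: float) -> np.ndarray:
    """Per-row maximal cluster mass for a (P, q) array of |t| curves."""
    excess = np.clip(abs_t_rows - threshold, 0.0, None)
    masses = np.zeros(abs_t_rows.shape[0])
    running = np.zeros(abs_t_rows.shape[0])
    for q in range(abs_t_rows.shape[1]):
        active = abs_t_rows[:, q] >= threshold
        running = np.where(active, running + excess[:, q], 0.0)
        masses = np.maximum(masses, running)
    return masses


def _rft_threshold(alpha: float, nu: int, resels: float) -> float:
    """Parametric field-wise t threshold from 1D random field theory.

    Solves ``alpha = P(T > u) + resels * EC1(u)`` where EC1 is the 1D Euler
    characteristic density of a t-field with ``nu`` degrees of freedom.
    """

    def ec1(u: float) -> float:
        return (
            np.sqrt(4.0 * np.log(2.0))
            / (2.0 * np.pi)
            * (1.0 + u**2 / nu) ** (-(nu - 1) / 2.0)
        )

    def excursion(u: float) -> float:
        return float(sps.t.sf(u, nu) + resels * ec1(u)) - alpha

    return float(brentq(excursion, 0.1, 100.0))


def _estimate_fwhm(residuals: np.ndarray) -> float:
    """Smoothness (FWHM, in stations) of a residual field from the gradient
    of the normalised residuals."""
    norm = residuals / np.linalg.norm(residuals, axis=0, keepdims=True)
    grad = np.gradient(norm, axis=1)
    v = float(np.mean(np.sum(grad**2, axis=0)))
    if v <= 0:
        return float(residuals.shape[1])
    return float(np.sqrt(4.0 * np.log(2.0) / v))


def spm_ttest_profiles(
    profiles_a: Iterable,
    profiles_b: Iterable,
    n_permutations: int = 10000,
    alpha: float = 0.05,
    method: Literal["permutation", "rft"] = "permutation",
    seed: int | None = None,
) -> SPMResult:
    """Two-sample SPM t-test over 101-station CSA profiles.

    Parameters
    ----------
    profiles_a, profiles_b : iterables of CSAProfile or (101,) arrays
    n_permutations : int
        Permutations of group labels for the max-|t| null (exhausted when the
        design allows fewer distinct assignments than requested).
    alpha : float
        Field-wise error rate for the critical threshold.
    method : {"permutation", "rft"}
        Threshold source; cluster p-values always come from the permutation
        distribution of maximal cluster mass at that threshold.
    seed : int, optional
        Seed for the label-permutation sampler.
    """
    A = _as_matrix(profiles_a)
    B = _as_matrix(profiles_b)
    na, nb = len(A), len(B)
    if na < 2 or nb < 2:
        raise ValueError("each group needs n >= 2 profiles")
    n = na + nb
    pooled = np.vstack([A, B])

    n_distinct = comb(n, na)
    if n_distinct < 100:
        warnings.warn(
            f"only {n_distinct} distinct label assignments; "
            "using exhaustive enumeration",
            stacklevel=2,
        )
    if n_distinct <= n_permutations:
        member = np.zeros((n_distinct, n), dtype=bool)
        for row, idx in enumerate(combinations(range(n), na)):
            member[row, list(idx)] = True
    else:
        rng = np.random.default_rng(seed)
        member = np.zeros((n_permutations, n), dtype=bool)
        member[0, :na] = True  # observed labelling always included
        for row in range(1, n_permutations):
            member[row, rng.choice(n, size=na, replace=False)] = True

    t_all = _t_curves(pooled, member)
    observed = _t_curves(pooled, np.array([[True] * na + [False] * nb]))[0]
    abs_all = np.abs(t_all)
    max_t = abs_all.max(axis=1)

    if method == "permutation":
        threshold = float(np.quantile(max_t, 1.0 - alpha))
    else:
        groups_mean = np.where(
            np.array([True] * na + [False] * nb)[:, None], A.mean(axis=0), B.mean(axis=0)
        )
        residuals = pooled - groups_mean
        fwhm = _estimate_fwhm(residuals)
        threshold = _rft_threshold(alpha, n - 2, resels=100.0 / fwhm)

    raw_clusters = _cluster_masses(np.abs(observed), threshold)
    cluster_ps: list[tuple[float, float, float]] = []
    if raw_clusters:
        null_masses = _max_cluster_mass(abs_all, threshold)
        for start, end, mass in raw_clusters:
            p = float(np.mean(null_masses >= mass))
            cluster_ps.append((float(start), float(end), max(p, 1.0 / len(max_t))))
    return SPMResult(
        t_curve=observed,
        critical_threshold=threshold,
        clusters=cluster_ps,
        method=method,
    )
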