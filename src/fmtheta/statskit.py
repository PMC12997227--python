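"""Behavioral and nonparametric statistics for the Go/NoGo analysis.

Implements signal-detection sensitivity (d') with the log-linear correction,
Mann–Whitney / Wilcoxon / Kolmogorov–Smirnov tests with z statistics and
rank-biserial effect sizes, effect-size arithmetic (partial eta squared from
F and degrees of freedom, Cohen's d from a dependent-contrast t), bootstrap
stability summaries (percentile CIs, direction consistency, p-stability),
leave-one-out influence analysis, and Spearman correlation with an exact
small-sample p.

Conventions fixed here (the field has several): rank-biserial
``r = 2U/(n_x n_y) - 1``; Cohen's ``d = t / sqrt(n)`` for a one-sample /
dependent contrast; zero differences are dropped in the signed-rank test.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
from scipy import stats
from scipy.special import ndtr

__all__ = [
    "BehavioralCounts",
    "StatsRecord",
    "BootstrapStability",
    "norm_ppf",
    "dprime",
    "rank_sum_test",
    "signed_rank_test",
    "ks_two_sample",
    "partial_eta_sq",
    "cohens_d_from_t",
    "bootstrap_stability",
    "leave_one_out",
    "spearman_corr",
]


@dataclass(frozen=True)
class BehavioralCounts:
    """Hit / false-alarm counts with the corresponding trial totals."""

    H: int
    F: int
    N_signal: int
    N_noise: int

    def __post_init__(self) -> None:
        for name in ("H", "F", "N_signal", "N_noise"):
            v = getattr(self, name)
            if not float(v).is_integer():
                raise ValueError(f"{name} must be an integer count")
        if not (0 <= self.H <= self.N_signal and 0 <= self.F <= self.N_noise):
            raise ValueError("counts must satisfy 0 <= H <= N_signal, 0 <= F <= N_noise")


@dataclass
class StatsRecord:
    test_name: str
    statistic: float
    z: float | None
    p: float
    tail: str
    effect_size_r: float | None = None
    n: tuple[int, ...] | None = None

    def to_dict(self) -> dict:
        return {
            "test": self.test_name,
            "statistic": float(self.statistic),
            "z": None if self.z is None else float(self.z),
            "p": float(self.p),
            "tail": self.tail,
            "effect_size_r": None
            if self.effect_size_r is None
            else float(self.effect_size_r),
            "n": None if self.n is None else list(self.n),
        }


@dataclass
class BootstrapStability:
    n_resamples: int
    ci_low: float
    ci_high: float
    direction_consistency: float
    p_stability: float
    seed: int | None
    original_r: float
    original_p: float
    median_diff_ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        return {
            "n_resamples": int(self.n_resamples),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "direction_consistency": float(self.direction_consistency),
            "p_stability": float(self.p_stability),
            "seed": self.seed,
            "original_r": float(self.original_r),
            "original_p": float(self.original_p),
            "median_diff_ci": None
            if self.median_diff_ci is None
            else [float(v) for v in self.median_diff_ci],
        }


# ---------------------------------------------------------------------------
# normal quantile and d'

# Acklam's rational approximation to the standard normal quantile, refined by
# one Halley step on Phi(x) - p = 0; the refinement brings the absolute error
# to ~1e-15 over (0, 1).
_A = (-3.969683028665376e01, 2.209460984245205e02, -2.759285104469687e02,
      1.383577518672690e02, -3.066479806614716e01, 2.506628277459239e00)
_B = (-5.447609879822406e01, 1.615858368580409e02, -1.556989798598866e02,
      6.680131188771972e01, -1.328068155288572e01)
_C = (-7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e00,
      -2.549732539343734e00, 4.374664141464968e00, 2.938163982698783e00)
_D = (7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e00,
      3.754408661907416e00)


def norm_ppf(p):
    """Standard normal quantile, accurate to ~1e-15 on (0, 1).

    Rational initial approximation followed by one Halley refinement using
    the exact normal CDF; vectorised over array input.
    """
    p = np.asarray(p, dtype=float)
    scalar = p.ndim == 0
    p = np.atleast_1d(p)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("norm_ppf requires probabilities strictly in (0, 1)")
    # work in the lower tail, where Phi(x) - p keeps full relative precision
    # (1 - p is exact for p >= 0.5); reflect the upper half at the end
    upper = p > 0.5
    p = np.where(upper, 1.0 - p, p)
    x = np.empty_like(p)
    plow, phigh = 0.02425, 1 - 0.02425

    lo = p < plow
    hi = p > phigh
    mid = ~(lo | hi)
    if np.any(lo):
        q = np.sqrt(-2.0 * np.log(p[lo]))
        x[lo] = (((((_C[0] * q + _C[1]) * q + _C[2]) * q + _C[3]) * q + _C[4]) * q + _C[5]) / (
            (((_D[0] * q + _D[1]) * q + _D[2]) * q + _D[3]) * q + 1.0
        )
    if np.any(hi):
        q = np.sqrt(-2.0 * np.log(1.0 - p[hi]))
        x[hi] = -(((((_C[0] * q + _C[1]) * q + _C[2]) * q + _C[3]) * q + _C[4]) * q + _C[5]) / (
            (((_D[0] * q + _D[1]) * q + _D[2]) * q + _D[3]) * q + 1.0
        )
    if np.any(mid):
        q = p[mid] - 0.5
        r = q * q
        x[mid] = (((((_A[0] * r + _A[1]) * r + _A[2]) * r + _A[3]) * r + _A[4]) * r + _A[5]) * q / (
            ((((_B[0] * r + _B[1]) * r + _B[2]) * r + _B[3]) * r + _B[4]) * r + 1.0
        )

    # Halley refinement: e = Phi(x) - p, x <- x - u / (1 + x u / 2), u = e/phi(x)
    e = ndtr(x) - p
    u = e * np.sqrt(2.0 * np.pi) * np.exp(0.5 * x * x)
    x = x - u / (1.0 + 0.5 * x * u)
    x = np.where(upper, -x, x)
    return float(x[0]) if scalar else x


def dprime(counts: BehavioralCounts) -> float:
    """Sensitivity d' with the log-linear correction.

    Rates are ``(count + 0.5) / (total + 1)``, which keeps d' finite even
    for perfect performance; ``d' = ppf(hit rate) - ppf(false-alarm rate)``.
    """
    h_hat = (counts.H + 0.5) / (counts.N_signal + 1)
    f_hat = (counts.F + 0.5) / (counts.N_noise + 1)
    return float(norm_ppf(h_hat) - norm_ppf(f_hat))


# ---------------------------------------------------------------------------
# rank tests

_TAILS = ("two_sided", "greater", "less")


def _check_tail(tail: str) -> None:
    if tail not in _TAILS:
        raise ValueError(f"tail must be one of {_TAILS}")


def _tie_term(values: np.ndarray) -> float:
    _, counts = np.unique(values, return_counts=True)
    return float(np.sum(counts**3 - counts))


def _cc_z_and_p(stat: float, mu: float, sigma: float, tail: str) -> tuple[float, float]:
    """Continuity-corrected z and normal-approximation p for a rank statistic.

    One-sided tails correct by half a unit toward the tested tail
    (P(S >= s) ~ 1 - Phi((s - 0.5 - mu)/sigma)); the two-sided version
    shrinks |s - mu| by half a unit.
    """
    if sigma <= 0:
        return 0.0, 1.0
    if tail == "greater":
        z = (stat - mu - 0.5) / sigma
        p = 1.0 - ndtr(z)
    elif tail == "less":
        z = (stat - mu + 0.5) / sigma
        p = float(ndtr(z))
    else:
        z = np.sign(stat - mu) * max(abs(stat - mu) - 0.5, 0.0) / sigma
        p = 2.0 * (1.0 - ndtr(abs(z)))
    return float(z), float(min(max(p, np.finfo(float).tiny), 1.0))


def rank_sum_test(x, y, tail: str = "two_sided") -> StatsRecord:
    """Mann–Whitney U rank-sum test of x versus y.

    U counts pairs where x exceeds y (midranks for ties).  The p-value is
    exact by enumeration when the pooled sample has at most 12 values and
    no ties, otherwise a normal approximation with tie-corrected variance
    and continuity correction is used.  ``tail='greater'`` tests x > y.
    Effect size is the rank-biserial correlation ``2U/(n_x n_y) - 1``.
    """
    _check_tail(tail)
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    nx, ny = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    U = float(ranks[:nx].sum() - nx * (nx + 1) / 2.0)

    N = nx + ny
    mu = nx * ny / 2.0
    tie = _tie_term(pooled)
    sigma2 = nx * ny / 12.0 * ((N + 1) - tie / (N * (N - 1)))
    sigma = float(np.sqrt(sigma2)) if sigma2 > 0 else 0.0
    z, p_norm = _cc_z_and_p(U, mu, sigma, tail)

    no_ties = len(np.unique(pooled)) == N
    if N <= 12 and no_ties:
        alt = {"two_sided": "two-sided", "greater": "greater", "less": "less"}[tail]
        p = float(stats.mannwhitneyu(x, y, alternative=alt, method="exact").pvalue)
    else:
        p = p_norm

    r = 2.0 * U / (nx * ny) - 1.0
    return StatsRecord("mann_whitney_u", U, z, p, tail, effect_size_r=r, n=(nx, ny))


def signed_rank_test(x, y=None, tail: str = "two_sided") -> StatsRecord:
    """Paired Wilcoxon signed-rank test (zero differences dropped).

    ``x`` and ``y`` are paired samples (or ``y=None`` and ``x`` the
    differences).  Exact p for at most 12 nonzero differences without tied
    absolute values; otherwise a tie-corrected normal approximation.
    ``tail='greater'`` tests x > y.  Effect size is the matched-pairs
    rank-biserial correlation.
    """
    _check_tail(tail)
    x = np.asarray(x, dtype=float)
    d = x - np.asarray(y, dtype=float) if y is not None else x
    if len(d) < 2:
        raise ValueError("need at least 2 pairs")
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all differences are zero; the test is undefined")
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    W = float(ranks[d > 0].sum())

    mu = n * (n + 1) / 4.0
    tie = _tie_term(np.abs(d))
    sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - tie / 48.0
    sigma = float(np.sqrt(sigma2)) if sigma2 > 0 else 0.0
    z, p_norm = _cc_z_and_p(W, mu, sigma, tail)

    if n <= 12:
        # exact sign-flip enumeration on midranks (valid with tied |d|)
        signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
        W_all = signs @ ranks
        if tail == "greater":
            p = float(np.mean(W_all >= W - 1e-12))
        elif tail == "less":
            p = float(np.mean(W_all <= W + 1e-12))
        else:
            p = float(np.mean(np.abs(W_all - mu) >= abs(W - mu) - 1e-12))
    else:
        p = p_norm

    r = 2.0 * (W - mu) / (n * (n + 1) / 2.0)
    return StatsRecord("wilcoxon_signed_rank", W, z, p, tail, effect_size_r=r, n=(n,))


def ks_two_sample(x, y) -> StatsRecord:
    """Two-sample Kolmogorov–Smirnov test on the ECDF difference.

    D is the maximal absolute difference between the two empirical CDFs;
    the p-value is exact for small samples (n_x * n_y <= 10^4) and
    asymptotic otherwise.  Two-sided by construction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be nonempty")
    method = "exact" if len(x) * len(y) <= 10_000 else "asymp"
    res = stats.ks_2samp(x, y, method=method)
    return StatsRecord(
        "kolmogorov_smirnov",
        float(res.statistic),
        None,
        float(res.pvalue),
        "two_sided",
        n=(len(x), len(y)),
    )


# ---------------------------------------------------------------------------
# effect sizes


def partial_eta_sq(F: float, df1: float, df2: float) -> float:
    """Partial eta squared recovered from an F statistic:
    ``F * df1 / (F * df1 + df2)``."""
    if F < 0:
        raise ValueError("F must be non-negative")
    if df1 <= 0 or df2 <= 0:
        raise ValueError("degrees of freedom must be positive")
    return float(F * df1 / (F * df1 + df2))


def cohens_d_from_t(t: float, n: int) -> float:
    """Cohen's d for a one-sample / dependent contrast: ``t / sqrt(n)``."""
    if n < 2:
        raise ValueError("need at least 2 subjects")
    return float(t / np.sqrt(n))


# ---------------------------------------------------------------------------
# resampling


def _mann_whitney_batch(XB: np.ndarray, YB: np.ndarray, tail: str):
    """Vectorised U, rank-biserial r, and normal-approximation p per row."""
    B, nx = XB.shape
    ny = YB.shape[1]
    pooled = np.concatenate([XB, YB], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    U = ranks[:, :nx].sum(axis=1) - nx * (nx + 1) / 2.0
    N = nx + ny
    mu = nx * ny / 2.0
    tie = np.empty(B)
    for b in range(B):  # tie runs per row; rows are small
        tie[b] = _tie_term(pooled[b])
    sigma2 = nx * ny / 12.0 * ((N + 1) - tie / (N * (N - 1)))
    sigma = np.sqrt(np.clip(sigma2, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        if tail == "greater":
            z = (U - mu - 0.5) / sigma
            p = 1.0 - ndtr(z)
        elif tail == "less":
            z = (U - mu + 0.5) / sigma
            p = ndtr(z)
        else:
            z = np.sign(U - mu) * np.clip(np.abs(U - mu) - 0.5, 0.0, None) / sigma
            p = 2.0 * (1.0 - ndtr(np.abs(z)))
    p = np.where(sigma > 0, p, 1.0)
    r = 2.0 * U / (nx * ny) - 1.0
    return U, r, np.minimum(p, 1.0)


def bootstrap_stability(
    x,
    y,
    tail: str = "two_sided",
    n_resamples: int = 10_000,
    seed: int | None = None,
    alpha: float = 0.05,
    with_median_diff: bool = False,
) -> BootstrapStability:
    """Within-group bootstrap of the Mann–Whitney group comparison.

    Each resample redraws |x| values from x and |y| from y with
    replacement and recomputes the U statistic, rank-biserial r, and
    p-value.  Reported are the percentile 95% CI of r (and optionally of
    the median group difference x - y), the proportion of resamples whose
    effect direction matches the original, and the proportion significant
    at p < 0.05 ("p-stability").
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    _check_tail(tail)
    orig = rank_sum_test(x, y, tail=tail)
    rng = np.random.default_rng(seed)
    XB = rng.choice(x, size=(n_resamples, len(x)), replace=True)
    YB = rng.choice(y, size=(n_resamples, len(y)), replace=True)
    _, r_b, p_b = _mann_whitney_batch(XB, YB, tail)
    ref_sign = np.sign(orig.effect_size_r) or 1.0
    direction = float(np.mean(np.sign(r_b) == ref_sign))
    ci = np.percentile(r_b, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    med_ci = None
    if with_median_diff:
        diffs = np.median(XB, axis=1) - np.median(YB, axis=1)
        lo, hi = np.percentile(diffs, [100 * alpha / 2, 100 * (1 - alpha / 2)])
        med_ci = (float(lo), float(hi))
    return BootstrapStability(
        n_resamples=n_resamples,
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        direction_consistency=direction,
        p_stability=float(np.mean(p_b < 0.05)),
        seed=seed,
        original_r=float(orig.effect_size_r),
        original_p=float(orig.p),
        median_diff_ci=med_ci,
    )


def leave_one_out(
    x, y, test=None, which: str = "groupB", tail: str = "two_sided"
) -> list[StatsRecord]:
    """Influence analysis: repeat the group test excluding one subject.

    ``which='groupB'`` (default) excludes only members of the second
    (clinical) group — one iteration per member; ``which='all'`` excludes
    each participant of either group in turn.  Deterministic.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 values")
    if test is None:
        test = lambda a, b: rank_sum_test(a, b, tail=tail)
    out: list[StatsRecord] = []
    if which in ("all",):
        for i in range(len(x)):
            out.append(test(np.delete(x, i), y))
    elif which != "groupB":
        raise ValueError("which must be 'groupB' or 'all'")
    for j in range(len(y)):
        out.append(test(x, np.delete(y, j)))
    return out


def spearman_corr(x, y) -> StatsRecord:
    """Spearman rank correlation with a two-sided p.

    p is exact (enumeration over all rank permutations) for n <= 7 and the
    usual t approximation otherwise.  Constant inputs are rejected.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input has no rank correlation")
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 7:
        count = 0
        total = 0
        base = rx - rx.mean()
        denom = np.sqrt(np.sum(base**2))
        ryc = ry - ry.mean()
        dy = np.sqrt(np.sum(ryc**2))
        for perm in permutations(ryc):
            r_p = float(base @ np.asarray(perm) / (denom * dy))
            total += 1
            if abs(r_p) >= abs(rho) - 1e-12:
                count += 1
        p = count / total
    else:
        t = rho * np.sqrt((n - 2) / max(1e-300, 1.0 - rho**2))
        p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return StatsRecord(
        "spearman", rho, None, float(min(p, 1.0)), "two_sided", effect_size_r=rho, n=(n,)
    )
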