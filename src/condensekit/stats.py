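"""Statistical procedures for condensate quantification studies.

Implements the small set of tests used throughout the package's analyses:
mean with a 95% t-interval, the unpaired two-tailed Student's t-test
(pooled variance, with Welch available behind a flag), one-way ANOVA, and
an extra-sum-of-squares F-test comparing regression slopes between groups
(the ANCOVA construction behind "compare slopes of fitted lines").

Every test returns a :class:`StatResult` (or :class:`SlopeComparison`)
record that serializes cleanly to JSON.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "StatResult",
    "SlopeComparison",
    "mean_ci95",
    "t_test_unpaired",
    "one_way_anova",
    "slope_equality_ftest",
]


@dataclass(frozen=True)
class StatResult:
    """Uniform record for a hypothesis test."""

    statistic: float
    df: tuple[float, ...]
    p_value: float
    method: str
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["df"] = list(self.df)
        d["flags"] = list(self.flags)
        return d


@dataclass(frozen=True)
class SlopeComparison:
    """Result of the slope-equality (ANCOVA extra-sum-of-squares) F-test.

    Attributes
    ----------
    slopes, intercepts : dict
        Per-group ordinary-least-squares estimates from the full model
        (separate slope and intercept for each group).
    common_slope : float
        Slope estimate under the reduced model (shared slope, per-group
        intercepts).
    f_statistic, df_num, df_den, p_value
        The extra-sum-of-squares F-test of slope homogeneity:
        ``F = [(SSE_reduced − SSE_full)/df_num] / [SSE_full/df_den]`` with
        ``df_num = n_groups − 1`` and ``df_den = N − 2·n_groups``.
    """

    slopes: dict[str, float]
    intercepts: dict[str, float]
    common_slope: float
    f_statistic: float
    df_num: int
    df_den: int
    p_value: float
    sse_full: float = field(default=float("nan"))
    sse_reduced: float = field(default=float("nan"))

    def to_dict(self) -> dict:
        return asdict(self)

    def summary(self) -> str:
        lines = ["Slope-equality F-test (extra sum of squares)"]
        for g in self.slopes:
            lines.append(
                f"  {g}: slope={self.slopes[g]:+.5g}, intercept={self.intercepts[g]:.5g}"
            )
        lines.append(f"  common slope: {self.common_slope:+.5g}")
        lines.append(
            f"  F({self.df_num}, {self.df_den}) = {self.f_statistic:.5g}, "
            f"p = {self.p_value:.4g}"
        )
        return "\n".join(lines)


def mean_ci95(values) -> tuple[float, float, float]:
    """Mean with a two-sided 95% t-interval.

    Returns ``(mean, lower, upper)`` where the half-width is
    ``t_{0.975, n−1} · s / √n``. Requires ``n ≥ 2``.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise ValueError("mean_ci95 requires at least 2 values")
    m = float(x.mean())
    sem = float(x.std(ddof=1)) / np.sqrt(n)
    half = float(sps.t.ppf(0.975, n - 1)) * sem
    return m, m - half, m + half


def t_test_unpaired(a, b, *, welch: bool = False) -> StatResult:
    """Unpaired two-tailed t-test.

    Pooled-variance Student's t by default; set ``welch=True`` for the
    unequal-variance form. Two identical constant groups return
    ``t = 0, p = 1`` with a ``zero-variance`` flag rather than NaN.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    flags: list[str] = []
    pooled_var = (
        (a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1)
    ) / (a.size + b.size - 2)
    if pooled_var == 0.0:
        if a.mean() == b.mean():
            flags.append("zero-variance")
            return StatResult(0.0, (float(a.size + b.size - 2),), 1.0,
                              "Student t (pooled)", tuple(flags))
        # zero variance but different means: infinitely significant
        return StatResult(float("inf"), (float(a.size + b.size - 2),), 0.0,
                          "Student t (pooled)", ("zero-variance",))
    t, p = sps.ttest_ind(a, b, equal_var=not welch)
    if welch:
        # Welch–Satterthwaite df
        va, vb = a.var(ddof=1) / a.size, b.var(ddof=1) / b.size
        df = (va + vb) ** 2 / (va**2 / (a.size - 1) + vb**2 / (b.size - 1))
        method = "Welch t"
    else:
        df = float(a.size + b.size - 2)
        method = "Student t (pooled)"
    return StatResult(float(t), (float(df),), float(p), method, tuple(flags))


def one_way_anova(*groups) -> StatResult:
    """One-way ANOVA across two or more groups.

    All-identical constant input is reported as ``F = 0, p = 1`` with a
    ``zero-variance`` flag (the 0/0 mean-square ratio convention).
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(
        groups[0][0]
    ):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("one_way_anova requires at least 2 groups")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    for g in arrs:
        if g.size < 2:
            raise ValueError("every group needs n >= 2")
    k = len(arrs)
    n_total = sum(g.size for g in arrs)
    df = (float(k - 1), float(n_total - k))
    if all(g.var() == 0.0 for g in arrs) and len({float(g[0]) for g in arrs}) == 1:
        return StatResult(0.0, df, 1.0, "one-way ANOVA", ("zero-variance",))
    f, p = sps.f_oneway(*arrs)
    return StatResult(float(f), df, float(p), "one-way ANOVA")


def _ols_sse(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Least-squares line fit; returns (slope, intercept, SSE)."""
    A = np.column_stack([x, np.ones_like(x)])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < 2:
        raise ValueError("degenerate design: x values are collinear/constant")
    resid = y - A @ coef
    return float(coef[0]), float(coef[1]), float(resid @ resid)


def slope_equality_ftest(groups: dict) -> SlopeComparison:
    """Test whether regression slopes differ between groups.

    Parameters
    ----------
    groups : dict
        Mapping of group name to ``(x, y)`` arrays. Each group needs at
        least 3 points with at least 2 distinct x values.

    Notes
    -----
    Full model: a separate slope and intercept per group. Reduced model: a
    common slope with per-group intercepts. The F statistic is the
    extra-sum-of-squares ratio between the two nested fits; under slope
    homogeneity it is F-distributed with ``(k−1, N−2k)`` degrees of
    freedom. Points are pooled within each group (no per-cell averaging).
    """
    if len(groups) < 2:
        raise ValueError("slope comparison requires at least 2 groups")
    names = list(groups)
    xs, ys = [], []
    for name in names:
        x, y = groups[name]
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size < 3 or np.unique(x).size < 2:
            raise ValueError(
                f"group {name!r} needs >=3 points with >=2 distinct x values"
            )
        xs.append(x)
        ys.append(y)

    slopes: dict[str, float] = {}
    intercepts: dict[str, float] = {}
    sse_full = 0.0
    for name, x, y in zip(names, xs, ys):
        b, a, sse = _ols_sse(x, y)
        slopes[name] = b
        intercepts[name] = a
        sse_full += sse

    # reduced model: shared slope, group-specific intercepts
    k = len(names)
    n_total = int(sum(x.size for x in xs))
    X = np.zeros((n_total, k + 1))
    yy = np.concatenate(ys)
    row = 0
    for j, x in enumerate(xs):
        X[row : row + x.size, 0] = x
        X[row : row + x.size, 1 + j] = 1.0
        row += x.size
    coef, _, rank, _ = np.linalg.lstsq(X, yy, rcond=None)
    if rank < k + 1:
        raise ValueError("degenerate design in reduced model")
    resid = yy - X @ coef
    sse_reduced = float(resid @ resid)

    df_num = k - 1
    df_den = n_total - 2 * k
    if df_den <= 0:
        raise ValueError("not enough points for the denominator df")
    f = max(0.0, (sse_reduced - sse_full) / df_num) / (sse_full / df_den)
    p = float(sps.f.sf(f, df_num, df_den))
    return SlopeComparison(
        slopes=slopes,
        intercepts=intercepts,
        common_slope=float(coef[0]),
        f_statistic=float(f),
        df_num=df_num,
        df_den=df_den,
        p_value=p,
        sse_full=sse_full,
        sse_reduced=sse_reduced,
    )
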