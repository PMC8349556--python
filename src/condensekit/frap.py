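"""FRAP trace normalization and recovery fitting.

A bleach-recovery experiment yields an intensity time series with one or
more pre-bleach samples. After normalizing to the pre-bleach mean, the
post-bleach segment is fitted with the single-exponential recovery model

    F(t) = f_post + (f_inf − f_post) · (1 − exp(−k·t)),   t from bleach,

with the floor ``f_post`` fixed at the first post-bleach sample and
``f_inf ≥ f_post``, ``k > 0`` free. The two headline quantities are the
percentage recovery 100·(f_inf − f_post)/(1 − f_post) — the mobile
fraction relative to the bleached depth — and the half-time t½ = ln2/k.
Confidence intervals come from the fit covariance, propagated to the
derived quantities by the delta method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = ["FrapTrace", "FrapFit", "normalize_trace", "fit_recovery"]


@dataclass(frozen=True)
class FrapTrace:
    """A bleach-recovery intensity time series.

    ``bleach_index`` is the index of the first post-bleach sample; samples
    before it are pre-bleach. Times are seconds and strictly increasing.
    """

    times: np.ndarray
    intensities: np.ndarray
    bleach_index: int
    background: float | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if t.shape != y.shape or t.ndim != 1:
            raise ValueError("times and intensities must be 1-D and equal length")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if not (1 <= self.bleach_index < t.size):
            raise ValueError("need at least one pre-bleach and one post-bleach sample")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "intensities", y)

    @classmethod
    def from_csv(cls, path, bleach_index: int, background: float | None = None):
        df = pd.read_csv(path)
        return cls(
            times=df["time_s"].to_numpy(),
            intensities=df["intensity"].to_numpy(),
            bleach_index=bleach_index,
            background=background,
        )


@dataclass(frozen=True)
class FrapFit:
    """Fitted recovery parameters with uncertainties.

    ``percent_recovery`` above 100 is reported as-is but flagged
    ``growing-structure`` (an assembly that gains material during the
    recovery window can overshoot full recovery). A flat trace where the
    rate is unidentifiable carries t½ = inf and a ``no-recovery`` flag.
    """

    percent_recovery: float
    t_half: float
    k: float
    f_inf: float
    f_post: float
    percent_recovery_ci: tuple[float, float]
    t_half_ci: tuple[float, float]
    residual_sd: float
    flags: tuple[str, ...] = ()
    n_post: int = 0

    def to_dict(self) -> dict:
        return {
            "percent_recovery": self.percent_recovery,
            "percent_recovery_ci": list(self.percent_recovery_ci),
            "t_half_s": self.t_half,
            "t_half_ci_s": list(self.t_half_ci),
            "k_per_s": self.k,
            "f_inf": self.f_inf,
            "f_post": self.f_post,
            "residual_sd": self.residual_sd,
            "n_post": self.n_post,
            "flags": list(self.flags),
        }

    def summary(self) -> str:
        lo, hi = self.percent_recovery_ci
        tl, th = self.t_half_ci
        out = [
            "FRAP recovery fit (single exponential)",
            f"  percent recovery: {self.percent_recovery:.1f}% "
            f"[{lo:.1f}, {hi:.1f}]",
            f"  t1/2: {self.t_half:.2f} s [{tl:.2f}, {th:.2f}]",
            f"  k: {self.k:.4g} /s   f_post: {self.f_post:.3f}   "
            f"f_inf: {self.f_inf:.3f}",
            f"  residual sd: {self.residual_sd:.4g}   n(post) = {self.n_post}",
        ]
        if self.flags:
            out.append(f"  flags: {', '.join(self.flags)}")
        return "\n".join(out)


def normalize_trace(trace: FrapTrace) -> FrapTrace:
    """Background-subtract and scale so the pre-bleach mean is 1."""
    y = trace.intensities.astype(float)
    bg = trace.background or 0.0
    pre = y[: trace.bleach_index].mean()
    if pre - bg <= 0:
        raise ValueError("pre-bleach mean does not exceed background")
    y_norm = (y - bg) / (pre - bg)
    return FrapTrace(trace.times.copy(), y_norm, trace.bleach_index, background=None)


def _model(t, f_inf, k, f_post):
    return f_post + (f_inf - f_post) * (1.0 - np.exp(-k * t))


def fit_recovery(trace: FrapTrace, *, ci_level: float = 0.95) -> FrapFit:
    """Fit the exponential recovery model to a normalized trace.

    Requires at least 5 post-bleach samples. The post-bleach time axis is
    re-zeroed at the bleach, so the fit is invariant to time-origin shifts.
    """
    t_post = trace.times[trace.bleach_index :]
    y_post = trace.intensities[trace.bleach_index :]
    if t_post.size < 5:
        raise ValueError("need at least 5 post-bleach samples")
    t_rel = t_post - t_post[0]
    f_post = float(y_post[0])
    flags: list[str] = []

    span = float(y_post.max() - f_post)
    if span <= 0 or np.allclose(y_post, f_post):
        # no measurable recovery: rate unidentifiable
        resid_sd = float(np.std(y_post - f_post, ddof=0))
        return FrapFit(
            percent_recovery=0.0,
            t_half=math.inf,
            k=0.0,
            f_inf=f_post,
            f_post=f_post,
            percent_recovery_ci=(0.0, 0.0),
            t_half_ci=(math.inf, math.inf),
            residual_sd=resid_sd,
            flags=("no-recovery",),
            n_post=int(t_post.size),
        )

    t_span = float(t_rel[-1]) if t_rel[-1] > 0 else 1.0
    p0 = (min(f_post + span, 1.0), 1.0 / max(t_span / 4.0, 1e-9))
    try:
        popt, pcov = curve_fit(
            lambda t, f_inf, k: _model(t, f_inf, k, f_post),
            t_rel,
            y_post,
            p0=p0,
            bounds=([f_post, 1e-12], [np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        resid = y_post - _model(t_rel, *p0, f_post)
        raise RuntimeError(
            f"recovery fit did not converge (residual sd at start "
            f"{np.std(resid):.4g})"
        ) from err

    f_inf, k = (float(v) for v in popt)
    if k <= 2e-12:
        flags.append("rate-at-bound")
    depth = 1.0 - f_post
    if depth <= 0:
        raise ValueError("trace is not bleached below the pre-bleach level")
    pct = 100.0 * (f_inf - f_post) / depth
    if pct > 100.0:
        flags.append("growing-structure")
    t_half = math.log(2.0) / k

    # delta method on (f_inf, k, f_post); f_post is fixed at one measured
    # sample, so it carries the measurement noise (≈ residual sd) as an
    # independent variance component
    from scipy.stats import norm

    z = float(norm.ppf(0.5 + ci_level / 2.0))
    var_finf = float(pcov[0, 0])
    var_k = float(pcov[1, 1])
    resid = y_post - _model(t_rel, f_inf, k, f_post)
    var_fpost = float(np.var(resid, ddof=0))
    d_pct_dfinf = 100.0 / depth
    d_pct_dfpost = 100.0 * (f_inf - 1.0) / depth**2
    se_pct = math.sqrt(
        d_pct_dfinf**2 * max(var_finf, 0.0) + d_pct_dfpost**2 * var_fpost
    )
    se_thalf = math.log(2.0) / k**2 * math.sqrt(max(var_k, 0.0))
    return FrapFit(
        percent_recovery=pct,
        t_half=t_half,
        k=k,
        f_inf=f_inf,
        f_post=f_post,
        percent_recovery_ci=(pct - z * se_pct, pct + z * se_pct),
        t_half_ci=(t_half - z * se_thalf, t_half + z * se_thalf),
        residual_sd=float(np.std(resid, ddof=0)),
        flags=tuple(flags),
        n_post=int(t_post.size),
    )
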