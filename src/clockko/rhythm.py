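"""Cosinor rhythmometry of bioluminescence reporter traces.

The core fit is the single-component cosinor: ordinary least squares of

    y(t) = M + b*t + beta_c*cos(2*pi*t/tau) + beta_s*sin(2*pi*t/tau)

giving mesor M (rhythm-adjusted mean), amplitude A = sqrt(beta_c^2 +
beta_s^2) (half peak-to-trough), and acrophase phi = (tau/2pi)*
atan2(beta_s, beta_c) mapped into [0, tau) (peak time). Rhythmicity is the
F-test of (beta_c, beta_s) jointly zero; relative amplitude (100*A/M, the
"% of mesor" readout) is reported only when that test is significant and
M > 0.

The period tau is fixed at 24 h by default, or grid-searched over a
bounded window with ``free_period``. An optional exponentially damped fit
(``damped=True``) profiles a decay constant lambda over a grid, solving
the linear subproblem at each lambda; its amplitude is the t=0 envelope
value. The default fit is undamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

__all__ = ["CosinorFit", "detrend", "cosinor_fit", "normalize_reporter"]


@dataclass
class CosinorFit:
    """Cosinor parameter estimates for one trace.

    ``relative_amplitude`` (percent of mesor) is NaN when the fit is not
    ``applicable`` (non-significant rhythm or non-positive mesor).
    """

    mesor: float
    amplitude: float
    acrophase: float
    period: float
    trend_slope: float
    rhythmicity_p: float
    applicable: bool
    relative_amplitude: float
    damping_rate: float = 0.0
    rss: float = float("nan")

    def as_dict(self) -> dict[str, float | bool]:
        return {
            "mesor": self.mesor,
            "amplitude": self.amplitude,
            "acrophase": self.acrophase,
            "period": self.period,
            "trend_slope": self.trend_slope,
            "rhythmicity_p": self.rhythmicity_p,
            "applicable": self.applicable,
            "relative_amplitude": self.relative_amplitude,
            "damping_rate": self.damping_rate,
        }


def _check_series(time: np.ndarray, signal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if time.ndim != 1 or time.shape != signal.shape:
        raise ValueError("time and signal must be 1-D arrays of equal length")
    if np.any(np.diff(time) <= 0):
        raise ValueError("time must be strictly increasing")
    return time, signal


def detrend(
    time: np.ndarray, signal: np.ndarray, window: float = 24.0
) -> pd.DataFrame:
    """Subtract a centred moving average of width ``window`` hours.

    Requires a uniform sampling grid. The half-window at each edge, where
    the centred average is undefined, is trimmed from the output; the time
    grid is otherwise preserved. Returns a (time_h, signal) frame.
    """
    time, signal = _check_series(time, signal)
    duration = time[-1] - time[0]
    if window <= 0 or window >= duration:
        raise ValueError(f"window must be in (0, duration={duration}), got {window}")
    steps = np.diff(time)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("detrend requires a uniform time grid")
    dt = steps[0]
    n_int = int(round(window / dt))
    if n_int % 2:
        n_int += 1  # centred kernel needs an even interval count
    half = n_int // 2
    # trapezoid weights: a full-period average of a periodic signal is exactly
    # zero (uniform weights double-count the window endpoints)
    kernel = np.full(n_int + 1, 1.0 / n_int)
    kernel[0] = kernel[-1] = 0.5 / n_int
    baseline = np.convolve(signal, kernel, mode="valid")
    return pd.DataFrame(
        {"time_h": time[half:-half], "signal": signal[half:-half] - baseline}
    )


def _ols_cosinor(
    t: np.ndarray, y: np.ndarray, period: float, fit_trend: bool, damping: float
) -> tuple[np.ndarray, float, float, int]:
    """Solve the linear cosinor at fixed period/damping.

    Returns (coefficients [M, (b,) beta_c, beta_s], rss, rss_reduced, n_params).
    """
    env = np.exp(-damping * t)
    cols = [np.ones_like(t)]
    if fit_trend:
        cols.append(t)
    cols.extend([env * np.cos(2 * np.pi * t / period), env * np.sin(2 * np.pi * t / period)])
    X = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    X0 = X[:, :-2]
    beta0, *_ = np.linalg.lstsq(X0, y, rcond=None)
    rss0 = float(np.sum((y - X0 @ beta0) ** 2))
    return beta, rss, rss0, X.shape[1]


def cosinor_fit(
    time: np.ndarray,
    signal: np.ndarray,
    period: float = 24.0,
    fit_trend: bool = True,
    free_period: bool = False,
    period_grid: tuple[float, float, float] = (20.0, 28.0, 0.1),
    damped: bool = False,
    damping_grid: tuple[float, float, float] = (0.0, 0.1, 0.002),
    p_applicable: float = 0.05,
) -> CosinorFit:
    """Least-squares cosinor fit of one trace.

    With ``free_period`` the period minimising the residual sum of squares
    over ``period_grid`` (start, stop, step; inclusive) is selected. With
    ``damped`` an exponential envelope exp(-lambda*t) multiplies the
    oscillatory terms, lambda profiled over ``damping_grid``; the reported
    amplitude is then the envelope value at t=0. The trace must cover at
    least two full periods.
    """
    t, y = _check_series(time, signal)
    if period <= 0:
        raise ValueError("period must be positive")
    if t.size < 4 + int(fit_trend):
        raise ValueError("too few points for a cosinor fit")
    duration = t[-1] - t[0]
    if duration < 2 * period:
        raise ValueError(
            f"trace covers {duration:.1f} h; need >= 2 periods ({2 * period:.1f} h)"
        )

    periods = [period]
    if free_period:
        lo, hi, step = period_grid
        periods = list(np.arange(lo, hi + step / 2, step))
    dampings = [0.0]
    if damped:
        lo, hi, step = damping_grid
        dampings = list(np.arange(lo, hi + step / 2, step))

    best = None
    for tau in periods:
        for lam in dampings:
            beta, rss, rss0, n_par = _ols_cosinor(t, y, tau, fit_trend, lam)
            if best is None or rss < best[1]:
                best = (beta, rss, rss0, n_par, tau, lam)
    beta, rss, rss0, n_par, tau, lam = best

    mesor = float(beta[0])
    slope = float(beta[1]) if fit_trend else 0.0
    bc, bs = float(beta[-2]), float(beta[-1])
    amplitude = float(np.hypot(bc, bs))
    acrophase = float((tau / (2 * np.pi)) * np.arctan2(bs, bc) % tau)

    df_resid = t.size - n_par
    if df_resid <= 0:
        raise ValueError("not enough residual degrees of freedom")
    # guard the F-test against pure round-off residuals: a reduced model that
    # already fits to machine precision is non-rhythmic, a full model that
    # does (while the reduced one does not) is perfectly rhythmic
    tol = 1e-12 * float(np.sum(y**2) + 1.0)
    if rss0 <= tol:
        p = 1.0
    elif rss <= tol:
        p = 0.0
    else:
        F = ((rss0 - rss) / 2.0) / (rss / df_resid)
        p = float(f_dist.sf(max(F, 0.0), 2, df_resid))

    applicable = bool(p < p_applicable and mesor > 0)
    rel_amp = 100.0 * amplitude / mesor if applicable else float("nan")
    return CosinorFit(
        mesor=mesor,
        amplitude=amplitude,
        acrophase=acrophase,
        period=float(tau),
        trend_slope=slope,
        rhythmicity_p=p,
        applicable=applicable,
        relative_amplitude=rel_amp,
        damping_rate=float(lam),
        rss=rss,
    )


def normalize_reporter(
    assay: pd.DataFrame, reference_group: str = "WT"
) -> pd.DataFrame:
    """Dual-luciferase normalisation with the reference-group mean set to 1.

    ``assay`` needs columns ``well``, ``group``, ``firefly``, ``renilla``.
    Each well's firefly activity is divided by its renilla activity (the
    co-transfection control); ratios are then scaled so the reference
    group's mean ratio is 1. Wells with non-positive renilla are excluded
    with a warning.
    """
    required = {"well", "group", "firefly", "renilla"}
    missing = required - set(assay.columns)
    if missing:
        raise ValueError(f"assay table missing columns: {sorted(missing)}")
    out = assay.copy()
    bad = ~(out["renilla"] > 0)
    if bad.any():
        warnings.warn(
            f"excluding {int(bad.sum())} well(s) with non-positive renilla: "
            f"{out.loc[bad, 'well'].tolist()}",
            stacklevel=2,
        )
        out = out.loc[~bad].copy()
    ref = out[out["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} has no usable wells")
    out["ratio"] = out["firefly"] / out["renilla"]
    ref_mean = out.loc[out["group"] == reference_group, "ratio"].mean()
    out["normalized"] = out["ratio"] / ref_mean
    return out.reset_index(drop=True)
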