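"""Estimation procedures: exponential time-course fits, constant fits,
melting-temperature extraction, and the two-sample comparison test.

Time courses of product formation / membrane release are fitted with the
rise-to-plateau model ``y = y0 + (y_inf - y0) (1 - exp(-k x))``; substrate
consumption with the pure decay ``y = y0 exp(-k x)``; flat reference
channels with the constant model ``y = k``.  Melting temperatures come from
the second derivative of the denaturation curve.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from lmfit import Model
from scipy import stats
from scipy.signal import savgol_filter

K_MAX = 1e3  # min^-1, upper bound for exponential rate fits


class NoTransitionError(RuntimeError):
    """Raised when a melt curve shows no detectable unfolding transition."""


@dataclass(frozen=True)
class ExponentialFitResult:
    y0: float
    y_inf: float
    k: float
    y0_stderr: float
    y_inf_stderr: float
    k_stderr: float
    residual_rms: float
    converged: bool
    at_bound: bool = False
    initial_guess: tuple = ()


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    n1: int
    n2: int
    mean_difference: float
    welch: bool = False


def _check_xy(x, y, min_points):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < min_points:
        raise ValueError(f"need at least {min_points} points")
    if np.any(np.diff(x) <= 0) or x[0] < 0:
        raise ValueError("x must be non-negative and strictly increasing")
    return x, y


def _rise(x, y0, y_inf, k):
    return y0 + (y_inf - y0) * (1.0 - np.exp(-k * x))


def _decay(x, y0, k):
    return y0 * np.exp(-k * x)


def _guess_k(x, y):
    """1 / (time to half-range), the robust starting point for both shapes."""
    half = (y[0] + y[-1]) / 2.0
    crossing = np.nonzero((y - half) * (y[0] - half) <= 0)[0]
    t_half = x[crossing[0]] if crossing.size and x[crossing[0]] > 0 else x[-1] / 2.0
    return 1.0 / max(t_half, 1e-9)


def fit_rise(x, y) -> ExponentialFitResult:
    """Least-squares fit of the single-exponential rise-to-plateau model.

    Handles decays as well (fitted ``y_inf`` below ``y0``).  Initial
    guesses: y0 = first point, y_inf = last point, k = 1/(time to
    half-range); k is bounded to [0, 1e3 min^-1].
    """
    x, y = _check_xy(x, y, 4)
    guess = (float(y[0]), float(y[-1]), _guess_k(x, y))
    model = Model(_rise)
    params = model.make_params(y0=guess[0], y_inf=guess[1], k=guess[2])
    params["k"].set(min=0.0, max=K_MAX)
    res = model.fit(y, params, x=x)
    k = float(res.params["k"].value)
    at_bound = _k_degenerate(k, x)
    rng = max(np.ptp(y), 1e-30)
    return ExponentialFitResult(
        y0=float(res.params["y0"].value),
        y_inf=float(res.params["y_inf"].value),
        k=k,
        y0_stderr=_se(res, "y0"),
        y_inf_stderr=_se(res, "y_inf"),
        k_stderr=_se(res, "k"),
        residual_rms=float(np.sqrt(np.mean(res.residual**2)) / rng),
        converged=bool(res.success),
        at_bound=at_bound,
        initial_guess=guess,
    )


def fit_decay(x, y) -> ExponentialFitResult:
    """Pure exponential decay fit (plateau fixed at zero)."""
    x, y = _check_xy(x, y, 4)
    guess = (float(y[0]), _guess_k(x, y))
    model = Model(_decay)
    params = model.make_params(y0=guess[0], k=guess[1])
    params["k"].set(min=0.0, max=K_MAX)
    res = model.fit(y, params, x=x)
    k = float(res.params["k"].value)
    rng = max(np.ptp(y), np.max(np.abs(y)), 1e-30)
    return ExponentialFitResult(
        y0=float(res.params["y0"].value),
        y_inf=0.0,
        k=k,
        y0_stderr=_se(res, "y0"),
        y_inf_stderr=0.0,
        k_stderr=_se(res, "k"),
        residual_rms=float(np.sqrt(np.mean(res.residual**2)) / rng),
        converged=bool(res.success),
        at_bound=_k_degenerate(k, x),
        initial_guess=guess,
    )


def _k_degenerate(k, x):
    """Rate at the bound or unresolvable over the observation window."""
    span = x[-1] - x[0]
    return bool(k * span < 1e-6 or k >= K_MAX * (1 - 1e-9))


def _se(res, name):
    se = res.params[name].stderr
    return float(se) if se is not None else float("nan")


def fit_constant(x, y):
    """Constant fit y = k: returns (mean, standard error of the mean)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if y.size < 2:
        raise ValueError("need at least 2 points")
    k = float(np.mean(y))
    se = float(np.std(y, ddof=1) / np.sqrt(y.size))
    return k, se


def tm_second_derivative(curve, min_points: int = 15, refine: bool = True) -> float:
    """Melting temperature from the second derivative of a denaturation curve.

    The curve is smoothed with a local cubic polynomial (window auto-scaled
    to 5-11 points) and differentiated twice; the zero crossing of the
    second derivative between its two lobes (the steepest point of the
    transition) locates the transition.  Because a bimolecular two-state
    melt is asymmetric - its steepest point lies above the half-folded
    temperature - the landmark then seeds a fit of the two-state
    equimolar-dimer unfolding model (``refine=True``, the default), and the
    fitted midpoint (fraction folded = 0.5) is returned; ``refine=False``
    returns the raw second-derivative landmark.  Raises
    :class:`NoTransitionError` when no transition rises above the curve's
    amplitude floor.  Invariant to affine rescaling of the MRE axis.
    """
    T = np.asarray(curve.temperature_c, dtype=float)
    y = np.asarray(curve.mre222, dtype=float)
    if T.size < min_points:
        raise ValueError(f"need at least {min_points} points across the transition")
    if np.any(np.diff(T) <= 0):
        raise ValueError("temperatures must be strictly increasing")
    y_range = np.ptp(y)
    if y_range <= 1e-12 * max(np.max(np.abs(y)), 1.0):
        raise NoTransitionError("flat curve: no transition detected")
    # orient so the transition rises with temperature; normalization makes
    # the extraction invariant to affine rescaling of the MRE axis
    sign = 1.0 if y[-1] >= y[0] else -1.0
    z = sign * y / y_range
    dT = float(np.median(np.diff(T)))
    window = int(np.clip(2 * (T.size // 16) + 1, 5, 11))
    z_s = savgol_filter(z, window, 3)
    d1 = savgol_filter(z_s, window, 3, deriv=1, delta=dT)
    d2 = savgol_filter(z_s, window, 3, deriv=2, delta=dT)
    # polynomial edge frames amplify noise: keep lobe detection interior
    core = slice(window, T.size - window)
    i_max = window + int(np.argmax(d2[core]))
    i_min = window + int(np.argmin(d2[core]))
    lo, hi = sorted((i_max, i_min))
    span = T[-1] - T[0]
    # a genuine sigmoid has both d2 lobes well above the amplitude floor
    lobe = min(abs(d2[i_max]), abs(d2[i_min]))
    if lo == hi or lobe * span**2 < 1e-2:
        raise NoTransitionError("second derivative below the detection floor")
    seg = slice(lo, hi + 1)
    # zero crossing of d2 = peak of d1 inside the bracket
    i_peak = lo + int(np.argmax(d1[seg]))
    crossings = np.nonzero(np.diff(np.sign(d2[seg])))[0]
    if crossings.size == 0:
        landmark = float(T[i_peak])
    else:
        j = lo + crossings[0]
        # linear interpolation across the sign change
        t0, t1 = T[j], T[j + 1]
        v0, v1 = d2[j], d2[j + 1]
        landmark = float(t0 - v0 * (t1 - t0) / (v1 - v0))
    if not refine:
        return landmark
    # additional starting points: half-amplitude crossing of the smoothed
    # curve and the span quartiles, guarding against noise-driven landmarks
    level = (np.median(z_s[:5]) + np.median(z_s[-5:])) / 2.0
    above = np.nonzero(z_s >= level)[0]
    starts = [landmark]
    if above.size:
        starts.append(float(T[above[0]]))
    span = T[-1] - T[0]
    starts += [float(T[0] + 0.25 * span), float(T[0] + 0.75 * span)]
    return _refine_dimer_tm(T, y, starts)


def _refine_dimer_tm(T, y, starts):
    """Fit the two-state equimolar-dimer melt model from several starting
    midpoints, keeping the best fit; the normalized curve shape depends
    only on (Tm, dH), so the fitted Tm is concentration-free."""
    from .stability import MeltParams, fraction_folded

    def model(t, tm, dh, bf, bu):
        f = fraction_folded(t, MeltParams(tm_celsius=tm, dh_kcal=dh))
        return bf + (bu - bf) * (1.0 - f)

    m = Model(model)
    best = None
    for tm0 in dict.fromkeys(round(s, 6) for s in starts):
        params = m.make_params(tm=tm0, dh=40.0,
                               bf=float(np.median(y[:5])),
                               bu=float(np.median(y[-5:])))
        # a midpoint outside the measured ramp is a no-call, not a fit
        params["tm"].set(min=float(T[0]), max=float(T[-1]))
        params["dh"].set(min=2.0, max=500.0)
        res = m.fit(y, params, t=T)
        if res.success and (best is None or res.chisqr < best.chisqr):
            best = res
    if best is None:
        return float(starts[0])
    return float(best.params["tm"].value)


def unpaired_t_test(group1, group2, welch: bool = False) -> TTestResult:
    """Two-sample two-tailed t test (pooled Student's by default)."""
    g1 = np.asarray(group1, dtype=float)
    g2 = np.asarray(group2, dtype=float)
    if g1.size < 2 or g2.size < 2:
        raise ValueError("each group needs at least 2 values")
    diff = float(np.mean(g1) - np.mean(g2))
    if np.var(g1, ddof=1) == 0.0 and np.var(g2, ddof=1) == 0.0:
        if diff == 0.0:
            return TTestResult(0.0, 1.0, g1.size, g2.size, 0.0, welch)
        return TTestResult(float(np.sign(diff) * np.inf), 0.0,
                           g1.size, g2.size, diff, welch)
    t, p = stats.ttest_ind(g1, g2, equal_var=not welch)
    return TTestResult(float(t), float(p), g1.size, g2.size, diff, welch)
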