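"""Main-sequence models of saccade dynamics.

Two stereotyped relations link saccade amplitude A (deg, absolute) to its
dynamics: peak velocity saturates exponentially,

    Vpeak(A) = Vmax * (1 - exp(-A / c)),

with ``Vmax`` the asymptotic peak velocity (deg/s) and ``c`` the amplitude
constant (deg); and duration grows linearly,

    Duration(A) = k + b * A,

with intercept ``k`` (ms) and slope ``b`` (ms/deg).  Both are fitted by
unweighted least squares, amplitudes pooled across directions and
eccentricities.  95% prediction bounds for a new observation use the exact
OLS formula for the linear model and a first-order (delta-method)
approximation for the exponential one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "MainSequenceFit",
    "PredictionBounds",
    "FitConvergenceError",
    "DegenerateDataError",
    "exp_velocity_model",
    "fit_exponential_vpeak",
    "fit_linear_duration",
    "prediction_bounds",
    "outside_bounds_fraction",
]


class FitConvergenceError(RuntimeError):
    pass


class DegenerateDataError(ValueError):
    pass


@dataclass
class MainSequenceFit:
    """Fitted main-sequence relation with parameter uncertainties.

    ``params`` maps parameter names (('vmax', 'c') or ('k', 'b')) to
    estimates; ``se`` to their standard errors from the local curvature at
    the optimum.  ``cov`` is the parameter covariance, ``residual_sd`` the
    noise SD estimate with n - 2 degrees of freedom.
    """

    model: str  # "exp_velocity" | "linear_duration"
    params: dict[str, float]
    se: dict[str, float]
    cov: np.ndarray
    residual_sd: float
    n_points: int
    amp_min: float
    amp_max: float
    converged: bool = True
    # linear-model sufficient statistics for exact prediction intervals
    amp_mean: float = float("nan")
    amp_sxx: float = float("nan")

    def predict(self, amplitudes: np.ndarray) -> np.ndarray:
        a = np.abs(np.asarray(amplitudes, dtype=float))
        if self.model == "exp_velocity":
            return exp_velocity_model(a, self.params["vmax"], self.params["c"])
        return self.params["k"] + self.params["b"] * a


@dataclass
class PredictionBounds:
    amplitudes: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    level: float
    extrapolated: np.ndarray  # True where amplitude is outside the fitted range


def exp_velocity_model(a: np.ndarray, vmax: float, c: float) -> np.ndarray:
    return vmax * (1.0 - np.exp(-a / c))


def fit_exponential_vpeak(
    amplitudes: np.ndarray,
    vpeaks: np.ndarray,
    max_restarts: int = 5,
    tol: float = 1e-10,
) -> MainSequenceFit:
    """Least-squares fit of the saturating-exponential peak-velocity relation.

    Initialised at Vmax0 = 1.05 * max(vpeaks), c0 = median(amplitudes); on
    non-convergence the start is jittered up to ``max_restarts`` times
    (deterministically) before an explicit failure.
    """
    a = np.abs(np.asarray(amplitudes, dtype=float))
    v = np.asarray(vpeaks, dtype=float)
    if a.size != v.size:
        raise ValueError("amplitudes and vpeaks must have equal length")
    if a.size < 3:
        raise DegenerateDataError("need at least 3 points for the exponential fit")
    if np.any(a <= 0) or np.any(v <= 0):
        raise ValueError("amplitudes and peak velocities must be positive")
    p0 = np.array([1.05 * float(np.max(v)), float(np.median(a))])
    rng = np.random.default_rng(12345)  # jitter stream for restarts only
    last_err: Exception | None = None
    for attempt in range(max_restarts + 1):
        start = p0 if attempt == 0 else p0 * rng.uniform(0.5, 1.5, size=2)
        try:
            popt, pcov = optimize.curve_fit(
                exp_velocity_model,
                a,
                v,
                p0=start,
                maxfev=20000,
                ftol=tol,
                xtol=tol,
            )
            if not np.all(np.isfinite(pcov)) or popt[0] <= 0 or popt[1] <= 0:
                raise RuntimeError("ill-conditioned optimum")
            resid = v - exp_velocity_model(a, *popt)
            dof = max(a.size - 2, 1)
            residual_sd = float(np.sqrt(resid @ resid / dof))
            se = np.sqrt(np.diag(pcov))
            return MainSequenceFit(
                model="exp_velocity",
                params={"vmax": float(popt[0]), "c": float(popt[1])},
                se={"vmax": float(se[0]), "c": float(se[1])},
                cov=pcov,
                residual_sd=residual_sd,
                n_points=int(a.size),
                amp_min=float(np.min(a)),
                amp_max=float(np.max(a)),
            )
        except RuntimeError as err:  # curve_fit signals non-convergence this way
            last_err = err
    raise FitConvergenceError(
        f"exponential main-sequence fit failed after {max_restarts} restarts: {last_err}"
    )


def fit_linear_duration(
    amplitudes: np.ndarray, durations: np.ndarray
) -> MainSequenceFit:
    """Ordinary least squares for the amplitude-duration relation."""
    a = np.abs(np.asarray(amplitudes, dtype=float))
    d = np.asarray(durations, dtype=float)
    if a.size != d.size:
        raise ValueError("amplitudes and durations must have equal length")
    if a.size < 2:
        raise DegenerateDataError("need at least 2 points for the linear fit")
    if np.ptp(a) == 0:
        raise DegenerateDataError("all amplitudes identical; slope is undefined")
    n = a.size
    amean = float(np.mean(a))
    sxx = float(np.sum((a - amean) ** 2))
    b = float(np.sum((a - amean) * (d - np.mean(d))) / sxx)
    k = float(np.mean(d) - b * amean)
    resid = d - (k + b * a)
    dof = max(n - 2, 1)
    s2 = float(resid @ resid / dof)
    # cov of (k, b) from the normal equations
    cov = s2 * np.array(
        [[1.0 / n + amean**2 / sxx, -amean / sxx], [-amean / sxx, 1.0 / sxx]]
    )
    return MainSequenceFit(
        model="linear_duration",
        params={"k": k, "b": b},
        se={"k": float(np.sqrt(cov[0, 0])), "b": float(np.sqrt(cov[1, 1]))},
        cov=cov,
        residual_sd=float(np.sqrt(s2)),
        n_points=int(n),
        amp_min=float(np.min(a)),
        amp_max=float(np.max(a)),
        amp_mean=amean,
        amp_sxx=sxx,
    )


def prediction_bounds(
    fit: MainSequenceFit,
    amplitude_grid: np.ndarray,
    level: float = 0.95,
) -> PredictionBounds:
    """Pointwise prediction intervals for a new observation.

    Exact for the linear model; first-order approximation (gradient of the
    mean function through the parameter covariance) for the exponential.
    Amplitudes outside the fitted range are flagged as extrapolation.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    a = np.abs(np.asarray(amplitude_grid, dtype=float))
    tq = stats.t.ppf(0.5 + level / 2.0, max(fit.n_points - 2, 1))
    center = fit.predict(a)
    if fit.model == "linear_duration":
        var_mean = fit.residual_sd**2 * (
            1.0 / fit.n_points + (a - fit.amp_mean) ** 2 / fit.amp_sxx
        )
    else:
        vmax, c = fit.params["vmax"], fit.params["c"]
        g = np.column_stack(
            [1.0 - np.exp(-a / c), -vmax * a / c**2 * np.exp(-a / c)]
        )
        var_mean = np.einsum("ij,jk,ik->i", g, fit.cov, g)
    half = tq * np.sqrt(var_mean + fit.residual_sd**2)
    return PredictionBounds(
        amplitudes=a,
        lower=center - half,
        upper=center + half,
        level=level,
        extrapolated=(a < fit.amp_min) | (a > fit.amp_max),
    )


def outside_bounds_fraction(
    fit: MainSequenceFit,
    amplitudes: np.ndarray,
    values: np.ndarray,
    level: float = 0.95,
) -> float:
    """Fraction of points strictly outside the fit's prediction bounds."""
    a = np.asarray(amplitudes, dtype=float)
    v = np.asarray(values, dtype=float)
    if a.size != v.size:
        raise ValueError("amplitudes and values must have equal length")
    if a.size == 0:
        return 0.0
    pb = prediction_bounds(fit, a, level)
    return float(np.mean((v < pb.lower) | (v > pb.upper)))
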