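"""Three-parameter logistic response modeling.

The on/off kinetics and irradiance dependence of the optogenetic tools
are summarized with the three-parameter logistic (3PL)

    y(x) = c / (1 + exp(-a (x - b)))

with the lower asymptote fixed at 0: ``y`` is the dark-subtracted,
GFP-normalized effector signal (AU), ``x`` is time (min) or irradiance
(W/m²), ``a`` the growth rate (per x-unit), ``b`` the inflection point
(x-units) and ``c`` the upper asymptote (AU).

From a fitted curve the characteristic points are obtained by inversion:

* rise (tON_p, I_p):  x where y = p·c     →  x = b − ln((1−p)/p) / a
* decay (tOFF_p):     x where y = (1−p)·c →  x = b − ln(p/(1−p)) / a

so p = 0.5 always returns the inflection point b exactly.  Confidence
intervals for derived parameters come from a seeded residual bootstrap;
per-parameter (a, b, c) intervals are also available from the delta
method (Jacobian-based covariance of the least-squares fit).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "ResponsePoint",
    "LogisticFit",
    "DerivedParam",
    "logistic3",
    "fit_logistic3",
    "derived_x",
    "derived_ci",
    "derived_param",
]

Direction = Literal["on", "off", "dose"]
Mode = Literal["rise", "decay"]

#: Growth-rate starting values for the deterministic multi-start grid.
_A_STARTS = (0.05, 0.5, 5.0)


@dataclass(frozen=True)
class ResponsePoint:
    """One dark-subtracted observation; y may be negative (undershoot)."""

    x: float
    y: float
    bio_replicate: str = ""

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ValueError("x must be >= 0")


@dataclass
class LogisticFit:
    """Fitted 3PL parameters with goodness of fit and delta-method CIs."""

    a: float
    b: float
    c: float
    r_squared: float
    param_cis: dict[str, tuple[float, float]]
    n_points: int
    converged: bool
    degenerate: bool = False
    sse: float = float("nan")
    direction: Direction = "on"

    def predict(self, x: np.ndarray | float) -> np.ndarray | float:
        return logistic3(np.asarray(x, dtype=float), self.a, self.b, self.c)


@dataclass
class DerivedParam:
    """A tON_p / tOFF_p / I_p estimate with its defining fraction p."""

    kind: Literal["tON", "tOFF", "I"]
    p: float
    estimate: float
    ci: tuple[float, float] | None = None
    ci_unreliable: bool = False


def logistic3(x: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Evaluate c / (1 + exp(-a(x - b))) with overflow-safe exponentials."""
    z = np.clip(-a * (np.asarray(x, dtype=float) - b), -700, 700)
    return c / (1.0 + np.exp(z))


def _as_xy(points: Iterable[ResponsePoint] | pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(points, pd.DataFrame):
        return points["x"].to_numpy(float), points["y"].to_numpy(float)
    pts = list(points)
    return (
        np.array([p.x for p in pts], dtype=float),
        np.array([p.y for p in pts], dtype=float),
    )


def _residuals(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b, c = theta
    return logistic3(x, a, b, c) - y


def _jacobian(theta: np.ndarray, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    a, b, c = theta
    z = np.clip(-a * (x - b), -700, 700)
    s = 1.0 / (1.0 + np.exp(z))  # sigmoid; e/(1+e)^2 == s(1-s)
    w = s * (1.0 - s)
    dyda = c * (x - b) * w
    dydb = -c * a * w
    return np.column_stack([dyda, dydb, s])


def _start_candidates(x: np.ndarray, y: np.ndarray, direction: Direction) -> list[np.ndarray]:
    c0 = max(float(np.max(y)), 1e-8)
    # b0: x nearest the half-maximum crossing of y
    half = c0 / 2.0
    b0 = float(x[np.argmin(np.abs(y - half))])
    b_mid = float(np.median(x))
    signs = (1.0,) if direction in ("on", "dose") else (-1.0,)
    starts = []
    for s in signs:
        for a0 in _A_STARTS:
            for b_start in (b0, b_mid):
                starts.append(np.array([s * a0, b_start, c0]))
    return starts


def fit_logistic3(
    points: Iterable[ResponsePoint] | pd.DataFrame,
    direction: Direction = "on",
) -> LogisticFit:
    """Least-squares 3PL fit with a deterministic multi-start grid.

    Requires at least 4 points spanning at least 3 distinct x values.
    The upper asymptote is constrained non-negative; the sign of the
    growth rate is steered by the multi-start grid (positive for
    ``on``/``dose``, negative for ``off``) but not hard-bounded.
    For ``off`` fits, x is expected to already be time since light
    removal (re-origin handled by the pipeline).
    """
    x, y = _as_xy(points)
    if x.size < 4:
        raise ValueError(f"need >= 4 points, got {x.size}")
    if np.unique(x).size < 3:
        raise ValueError(f"need >= 3 distinct x values, got {np.unique(x).size}")

    best = None
    for theta0 in _start_candidates(x, y, direction):
        try:
            res = least_squares(
                _residuals,
                theta0,
                jac=_jacobian,
                args=(x, y),
                bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                method="trf",
                xtol=1e-12,
                ftol=1e-12,
                gtol=1e-12,
                max_nfev=2000,
            )
        except Exception:
            continue
        sse = float(2.0 * res.cost)
        if best is None or sse < best[0] - 1e-15:
            best = (sse, res)
    if best is None:
        return LogisticFit(
            a=np.nan, b=np.nan, c=np.nan, r_squared=np.nan, param_cis={},
            n_points=int(x.size), converged=False, direction=direction,
        )

    sse, res = best
    a, b, c = (float(v) for v in res.x)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r_squared = 1.0 - sse / ss_tot if ss_tot > 0 else float("nan")

    # delta-method 95% CIs from the Jacobian at the optimum
    dof = max(x.size - 3, 1)
    s2 = sse / dof
    J = res.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(3, np.nan)
    from scipy.stats import t as t_dist

    tcrit = float(t_dist.ppf(0.975, dof))
    cis = {
        name: (val - tcrit * s, val + tcrit * s)
        for name, val, s in zip(("a", "b", "c"), (a, b, c), se)
    }
    scale = float(np.max(np.abs(y))) if y.size and np.max(np.abs(y)) > 0 else 1.0
    degenerate = c <= 1e-6 * max(1.0, scale)
    return LogisticFit(
        a=a, b=b, c=c, r_squared=r_squared, param_cis=cis,
        n_points=int(x.size), converged=bool(res.success), degenerate=degenerate,
        sse=sse, direction=direction,
    )


def derived_x(fit: LogisticFit, p: float, mode: Mode = "rise") -> float:
    """Invert the fitted curve at fraction p of the upper asymptote.

    ``rise`` solves y = p·c (tON_p / I_p); ``decay`` solves the
    p-fractional *decrease* y = (1−p)·c (tOFF_p).  The p = 0.5 case is
    the inflection point b in both modes.  Values may be negative and
    are reported as-is.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if not np.isfinite(fit.a) or fit.a == 0:
        raise ValueError("derived parameter undefined for a = 0 or non-finite fit")
    if fit.c <= 0:
        raise ValueError("derived parameter undefined for c <= 0")
    if mode == "rise":
        return fit.b - math.log((1.0 - p) / p) / fit.a
    if mode == "decay":
        return fit.b - math.log(p / (1.0 - p)) / fit.a
    raise ValueError("mode must be 'rise' or 'decay'")


def derived_ci(
    points: Iterable[ResponsePoint] | pd.DataFrame,
    fit: LogisticFit,
    p: float,
    mode: Mode = "rise",
    n_boot: int = 500,
    seed: int = 0,
) -> tuple[tuple[float, float], bool]:
    """Residual-bootstrap 95% CI for a derived parameter.

    Residuals about the fitted curve are resampled with replacement,
    synthetic responses are refit (warm-started at the point estimate)
    and the derived parameter recomputed; the interval is the 2.5/97.5
    percentile range.  Returns ``(interval, unreliable)`` where
    ``unreliable`` is True when more than 20% of refits failed.
    """
    if not fit.converged:
        raise ValueError("bootstrap requires a converged fit")
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200")
    x, y = _as_xy(points)
    yhat = np.asarray(fit.predict(x), dtype=float)
    resid = y - yhat
    # inflate residuals for the 3 fitted dof so their variance matches
    # the error variance (standard residual-bootstrap correction)
    if x.size > 3:
        resid = resid * np.sqrt(x.size / (x.size - 3))
    rng = np.random.default_rng(seed)
    theta_hat = np.array([fit.a, fit.b, fit.c])
    estimates = []
    failures = 0
    for _ in range(n_boot):
        y_star = yhat + rng.choice(resid, size=resid.size, replace=True)
        try:
            res = least_squares(
                _residuals,
                theta_hat,
                jac=_jacobian,
                args=(x, y_star),
                bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
                method="trf",
                xtol=1e-10,
                ftol=1e-10,
                max_nfev=500,
            )
            boot_fit = LogisticFit(
                a=float(res.x[0]), b=float(res.x[1]), c=float(res.x[2]),
                r_squared=np.nan, param_cis={}, n_points=x.size,
                converged=bool(res.success),
            )
            if not res.success or boot_fit.c <= 0 or boot_fit.a == 0:
                failures += 1
                continue
            estimates.append(derived_x(boot_fit, p, mode))
        except (ValueError, np.linalg.LinAlgError):
            failures += 1
    unreliable = failures > 0.2 * n_boot or len(estimates) < 0.5 * n_boot
    if not estimates:
        return (np.nan, np.nan), True
    lo, hi = np.percentile(estimates, [2.5, 97.5])
    return (float(lo), float(hi)), unreliable


def derived_param(
    points: Iterable[ResponsePoint] | pd.DataFrame,
    fit: LogisticFit,
    p: float,
    kind: Literal["tON", "tOFF", "I"],
    n_boot: int = 500,
    seed: int = 0,
) -> DerivedParam:
    """Convenience wrapper: point estimate + bootstrap CI in one record."""
    mode: Mode = "decay" if kind == "tOFF" else "rise"
    est = derived_x(fit, p, mode)
    ci, unreliable = derived_ci(points, fit, p, mode, n_boot=n_boot, seed=seed)
    return DerivedParam(kind=kind, p=p, estimate=est, ci=ci, ci_unreliable=unreliable)
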