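"""Diffusion-law extraction from MSD series.

The anomalous-diffusion exponent alpha is the slope of log MSD vs log t
(MSD ~ t^alpha, walk dimension d_w = 2/alpha).  Diffusion coefficients come
from the two-dimensional Einstein relation <dr^2> = 4 D t, fitted over a
short-time window (default t in [1, 1e2]) and a long-time window (default
the last decade of the data).  D is reported as gated only if alpha on the
same window falls inside the normal-diffusion gate (default 0.9 < alpha <=
1.1; the strict one-sided gate 0.9 < alpha < 1 is selectable).  The
short-time coefficient decays exponentially with obstacle concentration,
D_SH = D0 * exp(-a c), which :func:`fit_exponential_decay` extracts by a
log-linear least-squares fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .observables import ObservableSeries

__all__ = [
    "DiffusionFit",
    "DecayFit",
    "fit_alpha",
    "fit_diffusion_coefficient",
    "fit_exponential_decay",
    "diffusion_ratio",
    "efolding_time",
    "DEFAULT_GATE",
    "STRICT_GATE",
    "SHORT_TIME_WINDOW",
]

DEFAULT_GATE = (0.9, 1.1)
STRICT_GATE = (0.9, 1.0)
SHORT_TIME_WINDOW = (1.0, 1.0e2)


@dataclass
class DiffusionFit:
    alpha: float
    d_w: float
    D: float | None             # lattice^2 / step; None when the gate fails
    D_stderr: float | None
    window: tuple[float, float]
    r_squared: float
    species: str = ""
    gated: bool = True
    flags: dict = field(default_factory=dict)


@dataclass
class DecayFit:
    D0: float
    a: float
    residuals: np.ndarray
    r_squared: float


def _window_slice(series: ObservableSeries, window) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(series.times, dtype=float)
    v = np.asarray(series.values, dtype=float)
    lo, hi = window
    mask = (t >= lo) & (t <= hi)
    return t[mask], v[mask]


def last_decade_window(series: ObservableSeries) -> tuple[float, float]:
    """The final factor-of-ten span of the sampled times."""
    t_hi = float(series.times[-1])
    return (t_hi / 10.0, t_hi)


def fit_alpha(series: ObservableSeries, window: tuple[float, float]) -> DiffusionFit:
    """Least-squares slope of log MSD vs log t over ``window``."""
    t, v = _window_slice(series, window)
    if len(t) < 4:
        raise ValueError(f"need >= 4 points in window {window}, got {len(t)}")
    if np.any(v <= 0) or np.any(t <= 0):
        raise ValueError("log-log fit requires positive times and MSD in the window")
    res = stats.linregress(np.log(t), np.log(v))
    alpha = float(res.slope)
    return DiffusionFit(
        alpha=alpha,
        d_w=2.0 / alpha if alpha > 0 else math.inf,
        D=None,
        D_stderr=None,
        window=(float(window[0]), float(window[1])),
        r_squared=float(res.rvalue**2),
        species=series.species,
        flags={"alpha_stderr": float(res.stderr)},
    )


def fit_diffusion_coefficient(
    series: ObservableSeries,
    window: tuple[float, float] = SHORT_TIME_WINDOW,
    gate: tuple[float, float] = DEFAULT_GATE,
    strict: bool = False,
) -> DiffusionFit:
    """Einstein-relation coefficient D = slope(MSD vs t) / 4 over ``window``.

    D is defined only when the log-log exponent over the same window passes
    the gate; a gate failure is a normal outcome reported as ``D=None``.
    """
    fit = fit_alpha(series, window)
    t, v = _window_slice(series, window)
    res = stats.linregress(t, v)
    D = float(res.slope) / 4.0
    lo, hi = STRICT_GATE if strict else gate
    ok = (lo < fit.alpha < hi) if strict else (lo < fit.alpha <= hi)
    return DiffusionFit(
        alpha=fit.alpha,
        d_w=fit.d_w,
        D=D if ok else None,
        D_stderr=float(res.stderr) / 4.0 if ok else None,
        window=fit.window,
        r_squared=float(res.rvalue**2),
        species=series.species,
        gated=ok,
        flags={**fit.flags, "gate": (lo, hi), "strict": strict},
    )


def fit_exponential_decay(c_values, D_values) -> DecayFit:
    """Fit D(c) = D0 * exp(-a c) by least squares of log D on c."""
    c = np.asarray(c_values, dtype=float)
    D = np.asarray(D_values, dtype=float)
    if len(c) < 3:
        raise ValueError("need >= 3 (c, D) pairs")
    if np.any(D <= 0):
        raise ValueError("all diffusion coefficients must be positive")
    res = stats.linregress(c, np.log(D))
    pred = res.intercept + res.slope * c
    return DecayFit(
        D0=float(np.exp(res.intercept)),
        a=float(-res.slope),
        residuals=np.log(D) - pred,
        r_squared=float(res.rvalue**2),
    )


def diffusion_ratio(fit_solvent: DiffusionFit, fit_dimer: DiffusionFit) -> tuple[float, float]:
    """Ratio D_solvent / D_dimer with the propagated standard error."""
    if fit_solvent.D is None or fit_dimer.D is None:
        raise ValueError("both fits must be gated-valid (D defined)")
    r = fit_solvent.D / fit_dimer.D
    rel2 = 0.0
    for f in (fit_solvent, fit_dimer):
        if f.D_stderr is not None and f.D != 0:
            rel2 += (f.D_stderr / f.D) ** 2
    return r, abs(r) * math.sqrt(rel2)


def efolding_time(series: ObservableSeries) -> float:
    """First time at which the series decays to 1/e of its t = 0 value,
    log-linearly interpolated between samples."""
    t = np.asarray(series.times, dtype=float)
    v = np.asarray(series.values, dtype=float)
    target = v[0] / math.e
    below = np.flatnonzero(v <= target)
    if below.size == 0:
        return math.inf
    j = below[0]
    if j == 0:
        return float(t[0])
    t0, t1 = t[j - 1], t[j]
    v0, v1 = v[j - 1], v[j]
    if v0 == v1:
        return float(t1)
    frac = (v0 - target) / (v0 - v1)
    if t0 > 0:
        return float(t0 * (t1 / t0) ** frac)
    return float(t0 + frac * (t1 - t0))
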