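"""Sigmoid and peak characterization of dissipation curves.

Two model families:

* a two-state Boltzmann sigmoid for the cumulative curve NR(t), with the
  half response time t0 and the dissipation rate constant
  NR' = (NR2 - NR1) / (4 dt) as the headline parameters;
* a Lorentzian peak for variant-minus-wild-type difference curves, with
  peak height h = NR0 + 2 A / (pi w).

Both fits are unweighted least squares; standard errors come from the
asymptotic covariance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError, InputError
from .response import DissipationCurve


def boltzmann_nr(t, nr1: float, nr2: float, t0: float, dt: float):
    """Two-state Boltzmann sigmoid.

    NR(t) = NR2 + (NR1 - NR2) / (1 + exp((t - t0) / dt)); limits NR1 at
    t -> -inf and NR2 at t -> +inf, midpoint (NR1 + NR2)/2 at t = t0.
    """
    if dt <= 0:
        raise InputError("dt must be > 0")
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):  # exp overflow -> inf -> correct limit
        return nr2 + (nr1 - nr2) / (1.0 + np.exp((t - t0) / dt))


def dissipation_rate_constant(nr1: float, nr2: float, dt: float) -> float:
    """First derivative of the sigmoid at its center: (NR2 - NR1) / (4 dt)."""
    if dt <= 0:
        raise InputError("dt must be > 0")
    return (nr2 - nr1) / (4.0 * dt)


def lorentz_delta(t, nr0: float, tc: float, w: float, a: float):
    """Lorentzian peak: dNR(t) = NR0 + (2 A / pi) * w / (4 (t - tc)^2 + w^2)."""
    if w <= 0:
        raise InputError("w must be > 0")
    t = np.asarray(t, dtype=float)
    return nr0 + (2.0 * a / math.pi) * w / (4.0 * (t - tc) ** 2 + w ** 2)


def lorentz_height(nr0: float, w: float, a: float) -> float:
    """Peak value of the Lorentzian: h = NR0 + 2 A / (pi w)."""
    if w <= 0:
        raise InputError("w must be > 0")
    return nr0 + 2.0 * a / (math.pi * w)


def adjusted_r2(ss_res: float, ss_tot: float, n: int, p: int) -> float:
    """1 - (ss_res/ss_tot) * (n - 1) / (n - p - 1)."""
    if n <= p + 1:
        raise InputError("need n > p + 1 for adjusted R^2")
    if ss_tot <= 0:
        raise InputError("ss_tot must be > 0")
    return 1.0 - (ss_res / ss_tot) * (n - 1) / (n - p - 1)


@dataclass
class BoltzmannFit:
    """Fitted sigmoid parameters; NR1/NR2 are held fixed, not estimated."""

    nr1: float
    nr2: float
    t0: float
    t0_se: float
    dt: float
    dt_se: float
    adj_r2: float
    n_points: int

    @property
    def nr_prime(self) -> float:
        """Dissipation rate constant, residues/fs, from the stored dt."""
        return dissipation_rate_constant(self.nr1, self.nr2, self.dt)

    def to_dict(self) -> dict:
        return {
            "model": "two-state-boltzmann",
            "nr1": self.nr1, "nr2": self.nr2,
            "t0": self.t0, "t0_se": self.t0_se,
            "dt": self.dt, "dt_se": self.dt_se,
            "nr_prime": self.nr_prime,
            "adj_r2": self.adj_r2, "n_points": self.n_points,
        }


@dataclass
class LorentzFit:
    nr0: float
    nr0_se: float
    tc: float
    tc_se: float
    w: float
    w_se: float
    a: float
    a_se: float
    adj_r2: float
    n_points: int

    @property
    def h(self) -> float:
        """Peak height from the stored parameters."""
        return lorentz_height(self.nr0, self.w, self.a)

    def to_dict(self) -> dict:
        return {
            "model": "lorentz-peak",
            "nr0": self.nr0, "nr0_se": self.nr0_se,
            "tc": self.tc, "tc_se": self.tc_se,
            "w": self.w, "w_se": self.w_se,
            "a": self.a, "a_se": self.a_se,
            "h": self.h,
            "adj_r2": self.adj_r2, "n_points": self.n_points,
        }


def _goodness(y: np.ndarray, yhat: np.ndarray, p: int) -> float:
    ss_res = float(((y - yhat) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise FitError("degenerate curve: zero total variance")
    return adjusted_r2(ss_res, ss_tot, len(y), p)


def fit_boltzmann(curve: DissipationCurve, nr1: float, nr2: float) -> BoltzmannFit:
    """Least-squares (t0, dt) with the asymptotes NR1, NR2 held fixed."""
    t = np.asarray(curve.times, dtype=float)
    y = np.asarray(curve.nr, dtype=float)
    if len(t) < 5:
        raise FitError("need at least 5 points to fit the sigmoid")
    if np.ptp(y) == 0:
        raise FitError("degenerate curve: NR is constant")
    if not nr2 > nr1:
        raise InputError("NR2 must exceed NR1")

    mid = 0.5 * (nr1 + nr2)
    t0_init = float(t[np.argmin(np.abs(y - mid))])
    dt_init = max(np.ptp(t) / 10.0, 1e-6)

    def model(tt, t0, dt):
        return boltzmann_nr(tt, nr1, nr2, t0, abs(dt) + 1e-30)

    try:
        popt, pcov = curve_fit(model, t, y, p0=[t0_init, dt_init],
                               maxfev=20000, xtol=1e-10, ftol=1e-10)
    except RuntimeError as exc:
        raise FitError(
            f"sigmoid fit did not converge (init t0={t0_init}, dt={dt_init})"
        ) from exc
    t0, dt = float(popt[0]), float(abs(popt[1]))
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan, np.nan]
    yhat = boltzmann_nr(t, nr1, nr2, t0, dt)
    return BoltzmannFit(nr1=nr1, nr2=nr2, t0=t0, t0_se=float(se[0]),
                        dt=dt, dt_se=float(se[1]),
                        adj_r2=_goodness(y, yhat, p=2), n_points=len(t))


def _lorentz_init(t: np.ndarray, y: np.ndarray) -> list[float]:
    # moving-average smoothing before locating the extremum
    win = max(3, len(y) // 40) | 1
    kernel = np.ones(win) / win
    smooth = np.convolve(y, kernel, mode="same")
    tail = max(1, len(y) // 10)
    nr0 = float(np.median(np.concatenate([smooth[:tail], smooth[-tail:]])))
    dev = smooth - nr0
    k = int(np.argmax(np.abs(dev)))
    tc = float(t[k])
    h = float(smooth[k])
    half = nr0 + 0.5 * (h - nr0)
    above = np.abs(dev) >= np.abs(half - nr0)
    if above.any():
        w = float(max(t[above][-1] - t[above][0], np.ptp(t) / 50.0))
    else:
        w = float(np.ptp(t) / 10.0)
    a = (h - nr0) * w * math.pi / 2.0
    return [nr0, tc, w, a]


def fit_lorentz(diff) -> LorentzFit:
    """Least-squares Lorentzian fit of a (t, dNR) difference curve.

    Accepts any object with `times` and a `delta_nr`/`nr` array, or a
    (t, y) tuple of arrays.
    """
    if isinstance(diff, tuple):
        t, y = diff
    else:
        t = diff.times
        y = getattr(diff, "delta_nr", None)
        if y is None:
            y = diff.nr
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 6:
        raise FitError("need at least 6 points to fit the peak")
    if np.ptp(y) == 0:
        raise FitError("flat difference curve: nothing to fit")

    p0 = _lorentz_init(t, y)

    def model(tt, nr0, tc, w, a):
        return lorentz_delta(tt, nr0, tc, abs(w) + 1e-30, a)

    try:
        popt, pcov = curve_fit(model, t, y, p0=p0, maxfev=40000,
                               xtol=1e-10, ftol=1e-10)
    except RuntimeError as exc:
        raise FitError(f"peak fit did not converge (init {p0})") from exc
    nr0, tc, w, a = popt
    w = abs(float(w))
    if w < 1e-9 * max(np.ptp(t), 1.0):
        raise FitError("peak width collapsed to zero (boundary-stuck fit)")
    se = np.sqrt(np.diag(pcov)) if np.all(np.isfinite(pcov)) else [np.nan] * 4
    yhat = lorentz_delta(t, float(nr0), float(tc), w, float(a))
    return LorentzFit(nr0=float(nr0), nr0_se=float(se[0]),
                      tc=float(tc), tc_se=float(se[1]),
                      w=w, w_se=float(se[2]),
                      a=float(a), a_se=float(se[3]),
                      adj_r2=_goodness(y, yhat, p=4), n_points=len(t))
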