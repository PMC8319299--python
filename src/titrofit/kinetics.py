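"""Background-corrected Michaelis–Menten analysis of methyltransferase assays.

The luminescent HMTase readout needs two control reactions per condition:

* *no-substrate* wells (enzyme + SAM, no nucleosomes) capture enzyme
  automethylation **plus** the spontaneous SAM-to-SAH conversion;
* *no-enzyme* wells (substrate + SAM, no enzyme) capture the spontaneous
  conversion alone.

Only the no-substrate control is subtracted from the reaction signal: the
spontaneous term is common to both and cancels, so subtracting both controls
would remove it twice.  The no-enzyme control is reported as a QC number; a
warning is raised when it exceeds 20% of the no-substrate control, since a
large spontaneous signal erodes the dynamic range.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .fitting import (
    FitResult,
    _log_spaced_starts,
    _run_multistart,
    _wald_intervals,
    _k_flags,
)

__all__ = [
    "KineticsDataset",
    "ProgressCurve",
    "CorrectedVelocities",
    "LinearityResult",
    "background_correct",
    "fit_mm",
    "check_linearity",
]

logger = logging.getLogger(__name__)

QC_NO_ENZYME_FRACTION = 0.20


@dataclass
class KineticsDataset:
    """One substrate titration of a methyltransferase, with controls.

    ``S``: substrate series in molar, counted per nucleosome core particle
    (octamer concentration).  ``raw``: luminescence, shape
    ``(n_S, n_replicates)``.  ``ctrl_no_substrate`` / ``ctrl_no_enzyme``:
    replicate control signals.  ``t``: reaction time; ``E0``: enzyme molar;
    ``signal_to_product``: optional product-per-signal-unit conversion.
    """

    S: np.ndarray
    raw: np.ndarray
    ctrl_no_substrate: np.ndarray
    ctrl_no_enzyme: np.ndarray
    E0: float
    t: float
    signal_to_product: float | None = None
    condition: str = ""

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        self.raw = np.atleast_2d(np.asarray(self.raw, dtype=float))
        if self.raw.shape[0] != self.S.shape[0]:
            if self.raw.shape[1] == self.S.shape[0]:
                self.raw = self.raw.T
            else:
                raise ValueError("raw must have one row per substrate concentration")
        self.ctrl_no_substrate = np.asarray(self.ctrl_no_substrate, dtype=float)
        self.ctrl_no_enzyme = np.asarray(self.ctrl_no_enzyme, dtype=float)
        if self.ctrl_no_substrate.size == 0 or self.ctrl_no_enzyme.size == 0:
            raise ValueError("both control well sets are required")
        if np.any(self.S < 0):
            raise ValueError("substrate concentrations must be >= 0")
        if not self.E0 > 0:
            raise ValueError("E0 must be > 0")
        if not self.t > 0:
            raise ValueError("reaction time must be > 0")


@dataclass
class ProgressCurve:
    """Signal vs time at fixed (top) substrate concentration."""

    t_points: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        self.t_points = np.asarray(self.t_points, dtype=float)
        self.signal = np.atleast_2d(np.asarray(self.signal, dtype=float))
        if self.signal.shape[0] != self.t_points.shape[0]:
            if self.signal.shape[1] == self.t_points.shape[0]:
                self.signal = self.signal.T
            else:
                raise ValueError("signal must have one row per time point")
        if self.t_points.size < 4:
            raise ValueError("progress curve needs >= 4 time points")
        if np.any(np.diff(self.t_points) <= 0):
            raise ValueError("time points must be strictly increasing")


@dataclass
class CorrectedVelocities:
    """Output of :func:`background_correct`."""

    S: np.ndarray
    velocities: np.ndarray  # (n_S, n_rep); product/time, or signal/time
    blank_mean: float
    qc_no_enzyme_mean: float
    qc_ratio: float
    qc_warning: bool
    units_are_signal: bool

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        n_rep = self.velocities.shape[1]
        return np.repeat(self.S, n_rep), self.velocities.ravel()


def background_correct(data: KineticsDataset) -> CorrectedVelocities:
    """Convert raw luminescence to velocities, subtracting the no-substrate control.

    ``v(S) = (raw(S) - mean(no_substrate)) * signal_to_product / t``.
    Without a conversion factor the velocities are in signal units per time
    and are flagged as such.
    """
    blank_mean = float(data.ctrl_no_substrate.mean())
    no_enz_mean = float(data.ctrl_no_enzyme.mean())
    ratio = no_enz_mean / blank_mean if blank_mean != 0 else np.inf
    qc_warning = ratio > QC_NO_ENZYME_FRACTION
    if qc_warning:
        warnings.warn(
            f"no-enzyme control is {100 * ratio:.0f}% of the no-substrate "
            "control (> 20%); spontaneous SAM conversion dominates the blank",
            UserWarning,
            stacklevel=2,
        )
    conv = 1.0 if data.signal_to_product is None else float(data.signal_to_product)
    velocities = (data.raw - blank_mean) * conv / data.t
    return CorrectedVelocities(
        S=data.S,
        velocities=velocities,
        blank_mean=blank_mean,
        qc_no_enzyme_mean=no_enz_mean,
        qc_ratio=ratio,
        qc_warning=qc_warning,
        units_are_signal=data.signal_to_product is None,
    )


def fit_mm(S, velocities, E0: float, units_are_signal: bool = False) -> FitResult:
    """Fit the Michaelis–Menten model; report ``k_cat``, ``K_M`` and k_cat/K_M.

    ``S``/``velocities`` may be 1-D matched arrays or ``velocities`` may be
    ``(n_S, n_rep)``.  The fit estimates ``(Vmax, K_M)``; ``k_cat = Vmax/E0``
    and the catalytic efficiency carry delta-method standard errors using
    the full parameter covariance.
    """
    S = np.asarray(S, dtype=float)
    v = np.asarray(velocities, dtype=float)
    if v.ndim == 2:
        x = np.repeat(S, v.shape[1])
        y = v.ravel()
    else:
        x, y = S, v
    if np.unique(S).size < 5:
        raise ValueError("need >= 5 distinct substrate concentrations")
    if not E0 > 0:
        raise ValueError("E0 must be > 0")

    def model(theta):
        Vmax, K_M = theta
        return Vmax * x / (K_M + x)

    vmax0 = float(np.nanmax(y)) if np.nanmax(y) > 0 else 1.0
    xpos = x[x > 0]
    starts = [np.array([vmax0, k0]) for k0 in _log_spaced_starts(xpos)]
    bounds = (
        np.array([0.0, xpos.min() * 1e-6]),
        np.array([max(10.0 * vmax0, 1e-12), xpos.max() * 1e6]),
    )
    best, n_starts = _run_multistart(model, y, starts, bounds,
                                     ("Vmax", "K_M"), 1)
    se, ci95, rss, dof, cov = _wald_intervals(best, y, ("Vmax", "K_M"))
    Vmax, K_M = (float(v_) for v_ in best.x)
    k_cat = Vmax / E0
    se_kcat = se["Vmax"] / E0
    eff = k_cat / K_M
    # delta method with the (Vmax, K_M) covariance
    g = np.array([1.0 / (E0 * K_M), -Vmax / (E0 * K_M**2)])
    se_eff = float(np.sqrt(max(g @ cov @ g, 0.0)))
    tq = stats.t.ppf(0.975, dof)

    flags = _k_flags(ci95, ("K_M",), float(xpos.max()))
    if K_M > 5.0 * float(xpos.max()):
        flags["K_M"] = "extrapolated beyond data"
    elif K_M * 100.0 < float(xpos.min()):
        # saturated at every measured S: only an upper bound on K_M exists
        flags["K_M"] = "below data range (non-identifiable)"
    if units_are_signal:
        flags["k_cat"] = "signal units per time (no conversion factor supplied)"

    estimates = {"Vmax": Vmax, "K_M": K_M, "k_cat": k_cat, "kcat_over_KM": eff}
    se_all = {**se, "k_cat": se_kcat, "kcat_over_KM": se_eff}
    ci_all = {
        **ci95,
        "k_cat": (k_cat - tq * se_kcat, k_cat + tq * se_kcat),
        "kcat_over_KM": (eff - tq * se_eff, eff + tq * se_eff),
    }
    return FitResult(
        model="michaelis-menten",
        estimates=estimates,
        se=se_all,
        ci95=ci_all,
        residuals=best.fun * getattr(best, "yscale", 1.0),
        rss=rss,
        dof=dof,
        converged=True,
        n_starts_used=n_starts,
        flags=flags,
        fixed={"E0": float(E0)},
    )


@dataclass
class LinearityResult:
    slope: float
    intercept: float
    r_squared: float
    is_linear: bool
    window: tuple[int, int]  # [start, stop) indices into t_points


def _line_stats(t: np.ndarray, y: np.ndarray):
    """Least-squares line with R^2 robust to zero-variance signals."""
    res = stats.linregress(t, y)
    yhat = res.intercept + res.slope * t
    ssr = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 1e-30 * max(1.0, float(np.max(np.abs(y)) ** 2)):
        r2 = 1.0 if ssr <= 1e-24 * max(1.0, float(np.max(np.abs(y)) ** 2)) else 0.0
    else:
        r2 = 1.0 - ssr / sst
    return res, r2


def check_linearity(curve: ProgressCurve, window: tuple[int, int] | None = None,
                    r2_min: float = 0.98) -> LinearityResult:
    """Find the longest initial window where product formation is linear in time.

    A prefix ``t[0:n]`` qualifies when the least-squares line has
    ``R^2 >= r2_min`` and its intercept lies within 2 standard errors of the
    first observed point.  ``is_linear`` is True when the full curve
    qualifies.  An explicit ``window`` skips the search and evaluates that
    range only.
    """
    t = curve.t_points
    y = curve.signal.mean(axis=1)
    if window is not None:
        lo, hi = window
        if hi - lo < 4:
            raise ValueError("window must span >= 4 points")
        res, r2 = _line_stats(t[lo:hi], y[lo:hi])
        ok = _window_ok(res, r2, y[lo], r2_min)
        return LinearityResult(float(res.slope), float(res.intercept), r2,
                               ok and hi - lo == t.size, (lo, hi))

    best_n = None
    for n in range(4, t.size + 1):
        res, r2 = _line_stats(t[:n], y[:n])
        if _window_ok(res, r2, y[0], r2_min):
            best_n = n
    if best_n is None:
        best_n = 4  # report the minimal window's stats, flagged non-linear
        res, r2 = _line_stats(t[:best_n], y[:best_n])
        return LinearityResult(float(res.slope), float(res.intercept), r2,
                               False, (0, best_n))
    res, r2 = _line_stats(t[:best_n], y[:best_n])
    return LinearityResult(float(res.slope), float(res.intercept), r2,
                           best_n == t.size, (0, best_n))


def _window_ok(res, r2: float, first_point: float, r2_min: float) -> bool:
    se_int = res.intercept_stderr if np.isfinite(res.intercept_stderr) else 0.0
    intercept_ok = abs(res.intercept - first_point) <= 2.0 * se_int or se_int == 0.0 and np.isclose(res.intercept, first_point, rtol=1e-9, atol=1e-12)
    return r2 >= r2_min and intercept_ok
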