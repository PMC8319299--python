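"""Nonlinear least-squares estimation of binding parameters from titrations.

The three fitters (:func:`fit_direct`, :func:`fit_displacement`,
:func:`fit_hill`) share one engine: multi-start ordinary least squares with
asymptotic (Wald) standard errors from the Jacobian at the optimum and 95%
confidence intervals using Student-t quantiles at the residual degrees of
freedom.  Dissociation constants are started from 8 log-spaced guesses
across ``[min(x)/10, max(x)*10]`` because displacement objective surfaces
can be flat; the best residual sum of squares wins, with near-ties broken
toward the smaller K.

A dissociation constant whose 95% CI upper bound exceeds 100x the largest
titrant concentration is flagged ``"not determined"`` — the data only
support a lower bound on the affinity in that case, and the point estimate
should not be quoted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from .equilibria import (
    HillParams,
    complex_direct,
    free_protein_competitive,
)

__all__ = [
    "TitrationDataset",
    "FitResult",
    "FitConvergenceError",
    "subtract_background",
    "fit_direct",
    "fit_displacement",
    "fit_hill",
    "fraction_bound_from_densitometry",
    "fold_change",
    "ratio_with_se",
    "normalize_relative_activity",
]

logger = logging.getLogger(__name__)

N_STARTS = 8
NOT_DETERMINED_FACTOR = 100.0
_EPS = float(np.finfo(float).eps)


class FitConvergenceError(RuntimeError):
    """No start converged; carries the best-attempt diagnostics."""


@dataclass
class TitrationDataset:
    """One titration experiment.

    ``x`` is the titrant series in molar: total protein for ``mode="direct"``,
    total unlabelled competitor for ``mode="displacement"``, protein (or any
    titrant) for ``mode="hill"``.  ``signals`` holds replicate observables,
    shape ``(n_x, n_replicates)`` — background-subtracted anisotropy change
    for anisotropy modes, fraction bound for EMSA-style data.
    ``probe_conc`` is the labelled-probe total concentration L0 (molar);
    ``fixed`` carries constants held during fitting (``K_L`` and ``P0`` for
    displacement, molar).
    """

    mode: str
    x: np.ndarray
    signals: np.ndarray
    probe_conc: float | None = None
    fixed: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("direct", "displacement", "hill"):
            raise ValueError(f"unknown mode {self.mode!r}")
        self.x = np.asarray(self.x, dtype=float)
        self.signals = np.atleast_2d(np.asarray(self.signals, dtype=float))
        if self.signals.shape[0] != self.x.shape[0]:
            if self.signals.shape[1] == self.x.shape[0]:
                self.signals = self.signals.T
            else:
                raise ValueError("signals must have one row per x value")
        if np.any(self.x <= 0):
            raise ValueError("titrant series x must be strictly positive")
        if np.unique(self.x).size < 5:
            raise ValueError("need >= 5 distinct titrant concentrations")
        order = np.argsort(self.x)
        self.x = self.x[order]
        self.signals = self.signals[order]
        if self.mode == "displacement":
            for key in ("K_L", "P0"):
                if key not in self.fixed:
                    raise ValueError(f"displacement mode requires fixed {key!r}")
            if self.probe_conc is None:
                raise ValueError("displacement mode requires probe_conc (L0)")

    @property
    def n_replicates(self) -> int:
        return self.signals.shape[1]

    def flat(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) with x repeated per replicate, for least squares."""
        n_rep = self.signals.shape[1]
        return np.repeat(self.x, n_rep), self.signals.ravel()


@dataclass
class FitResult:
    """Point estimates with uncertainty and convergence diagnostics."""

    model: str
    estimates: dict
    se: dict
    ci95: dict
    residuals: np.ndarray
    rss: float
    dof: int
    converged: bool
    n_starts_used: int
    dialect: str | None = None
    flags: dict = field(default_factory=dict)
    fixed: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "dialect": self.dialect,
            "estimates": dict(self.estimates),
            "se": dict(self.se),
            "ci95": {k: list(v) for k, v in self.ci95.items()},
            "rss": float(self.rss),
            "dof": int(self.dof),
            "converged": bool(self.converged),
            "n_starts_used": int(self.n_starts_used),
            "flags": dict(self.flags),
            "fixed": {k: float(v) for k, v in self.fixed.items()},
        }


# ---------------------------------------------------------------------------
# shared least-squares engine
# ---------------------------------------------------------------------------

def _run_multistart(
    model_fn: Callable[[np.ndarray], np.ndarray],
    y: np.ndarray,
    starts: Sequence[np.ndarray],
    bounds: tuple[np.ndarray, np.ndarray],
    names: Sequence[str],
    k_index: int | None,
    weights: np.ndarray | None = None,
):
    """Least squares from several starts; best RSS wins, ties to smaller K.

    Residuals are normalised by the data scale so the solver's stopping
    tolerances behave identically for anisotropy-unit and molar-velocity
    data; the normalisation cancels in the covariance and is undone in the
    reported RSS/residuals (see :func:`_wald_intervals`).
    """
    w = np.ones_like(y) if weights is None else weights
    yscale = float(np.nanmax(np.abs(y * w)))
    if not np.isfinite(yscale) or yscale == 0:
        yscale = 1.0

    def residual(theta):
        return (model_fn(theta) - y) * w / yscale

    results = []
    for theta0 in starts:
        try:
            res = optimize.least_squares(
                residual, theta0, bounds=bounds, method="trf", x_scale="jac",
                ftol=_EPS, xtol=_EPS, gtol=_EPS, diff_step=_EPS ** 0.5,
            )
        except Exception:  # singular model at this start; try the next
            continue
        # status 0 (max function evaluations) still yields a usable point:
        # with machine-epsilon tolerances the solver rarely reports formal
        # convergence, and the best-cost selection below arbitrates anyway
        if np.all(np.isfinite(res.x)) and np.isfinite(res.cost):
            results.append(res)
    if not results:
        raise FitConvergenceError(
            f"no start converged for parameters {list(names)}; "
            f"starts tried: {len(starts)}"
        )
    best_cost = min(r.cost for r in results)
    near = [r for r in results if r.cost <= best_cost * (1 + 1e-9) + 1e-300]
    if k_index is not None and len(near) > 1:
        near.sort(key=lambda r: r.x[k_index])
    best = near[0]
    # polish with a 3-point Jacobian at a truly relative step (the molar-scale
    # parameters make scipy's default max(1, |x|) step rule useless): sharpens
    # the optimum in flat valleys and yields the Jacobian the Wald covariance
    # is computed from
    try:
        polished = optimize.least_squares(
            residual, best.x, bounds=bounds, method="trf", x_scale="jac",
            jac="3-point", diff_step=_EPS ** (1.0 / 3.0),
            ftol=_EPS, xtol=_EPS, gtol=_EPS,
        )
        if np.all(np.isfinite(polished.x)) and polished.cost <= best.cost:
            best = polished
    except Exception:
        pass
    best.yscale = yscale
    logger.info(
        "fit converged: params=%s rss=%.6g starts=%d",
        dict(zip(names, best.x)), 2 * best.cost * yscale**2, len(starts),
    )
    return best, len(starts)


def _wald_intervals(res, y: np.ndarray, names: Sequence[str]):
    """(se, ci95, rss, dof, cov) from the Jacobian at the optimum.

    ``res`` holds residuals/Jacobian in data-scale-normalised units (see
    :func:`_run_multistart`); the normalisation cancels in the covariance
    and is undone for the reported RSS.
    """
    n, p = y.size, res.x.size
    dof = n - p
    if dof <= 0:
        raise ValueError("fit needs more observations than parameters")
    yscale = getattr(res, "yscale", 1.0)
    rss_scaled = float(2 * res.cost)
    rss = rss_scaled * yscale**2
    J = res.jac  # scaled by 1/yscale, which cancels against rss_scaled below
    try:
        cov = np.linalg.inv(J.T @ J) * rss_scaled / dof
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(J.T @ J) * rss_scaled / dof
    se_arr = np.sqrt(np.maximum(np.diag(cov), 0.0))
    tq = stats.t.ppf(0.975, dof)
    se = dict(zip(names, (float(s) for s in se_arr)))
    ci = {
        name: (float(est - tq * s), float(est + tq * s))
        for name, est, s in zip(names, res.x, se_arr)
    }
    return se, ci, rss, dof, cov


def _k_flags(ci95: Mapping, k_names: Sequence[str], x_max: float) -> dict:
    flags = {}
    for name in k_names:
        hi = ci95[name][1]
        if not np.isfinite(hi) or hi > NOT_DETERMINED_FACTOR * x_max:
            flags[name] = "not determined"
    return flags


def _log_spaced_starts(x: np.ndarray, n: int = N_STARTS) -> np.ndarray:
    return np.geomspace(x.min() / 10.0, x.max() * 10.0, n)


def _finish(model, names, k_names, best, n_starts, y, x_max, dialect=None,
            fixed=None, extra_flags=None):
    se, ci95, rss, dof, _ = _wald_intervals(best, y, names)
    estimates = dict(zip(names, (float(v) for v in best.x)))
    flags = _k_flags(ci95, k_names, x_max)
    if extra_flags:
        flags.update(extra_flags)
    return FitResult(
        model=model,
        estimates=estimates,
        se=se,
        ci95=ci95,
        residuals=best.fun * getattr(best, "yscale", 1.0),
        rss=rss,
        dof=dof,
        converged=True,
        n_starts_used=n_starts,
        dialect=dialect,
        flags=flags,
        fixed=dict(fixed or {}),
    )


# ---------------------------------------------------------------------------
# pre-processing
# ---------------------------------------------------------------------------

def subtract_background(signals, blank_signals) -> tuple[np.ndarray, float]:
    """Subtract the mean blank (probe-only well) from every signal.

    Returns ``(corrected, blank_mean)``.  Negative corrected values are
    allowed (they happen at low signal-to-noise) and are logged.
    """
    blank = np.asarray(blank_signals, dtype=float)
    if blank.size < 1:
        raise ValueError("need at least one blank replicate")
    signals = np.asarray(signals, dtype=float)
    blank_mean = float(blank.mean())
    corrected = signals - blank_mean
    if np.all(corrected < 0) and signals.size:
        logger.warning(
            "blank mean %.4g exceeds every signal; corrected values are negative",
            blank_mean,
        )
    return corrected, blank_mean


# ---------------------------------------------------------------------------
# model fits
# ---------------------------------------------------------------------------

def fit_direct(data: TitrationDataset, weighting: str | None = None) -> FitResult:
    """Fit ``{K_L, delta_r}`` to a direct titration.

    The forward model composes the exact two-species equilibrium with the
    anisotropy observable: ``dRobs(P0) = dr * [PL](P0; K_L) / L0``.
    """
    if data.mode != "direct":
        raise ValueError("fit_direct requires mode='direct'")
    if data.probe_conc is None:
        raise ValueError("fit_direct requires probe_conc (L0)")
    L0 = float(data.probe_conc)
    x, y = data.flat()
    weights = _weights(weighting, y)

    def model(theta):
        K_L, dr = theta
        return dr * complex_direct(x, L0, K_L) / L0

    span = float(np.nanmax(y) - min(np.nanmin(y), 0.0))
    dr0 = span if span > 0 else 1.0
    starts = [np.array([k0, dr0]) for k0 in _log_spaced_starts(data.x)]
    bounds = (
        np.array([data.x.min() * 1e-6, 0.0]),
        np.array([data.x.max() * 1e6, max(10.0 * np.nanmax(np.abs(y)), 1e-6)]),
    )
    best, n_starts = _run_multistart(model, y, starts, bounds,
                                     ("K_L", "delta_r"), 0, weights)
    return _finish("direct", ("K_L", "delta_r"), ("K_L",), best, n_starts, y,
                   data.x.max(), fixed={"L0": L0})


def fit_displacement(data: TitrationDataset, dialect: str = "complete",
                     weighting: str | None = None) -> FitResult:
    """Fit ``{K_N, delta_r}`` to a displacement titration.

    At each competitor concentration the forward model solves the
    three-species cubic for free protein, converts it to the bound-probe
    concentration and then to the observable anisotropy change.  ``K_L``,
    ``P0`` (from ``data.fixed``) and ``L0`` (``data.probe_conc``) are held
    constant; ``K_L`` normally comes from a prior :func:`fit_direct`.
    """
    if data.mode != "displacement":
        raise ValueError("fit_displacement requires mode='displacement'")
    K_L = float(data.fixed["K_L"])
    P0 = float(data.fixed["P0"])
    L0 = float(data.probe_conc)
    x, y = data.flat()
    weights = _weights(weighting, y)

    def model(theta):
        K_N, dr = theta
        p_free = free_protein_competitive(P0, L0, x, K_L, K_N, dialect)
        pl = L0 * p_free / (K_L + p_free)
        return dr * pl / L0

    # no-competitor bound fraction sets the delta_r start
    f0 = float(complex_direct(P0, L0, K_L) / L0)
    dr0 = float(np.nanmax(y)) / f0 if f0 > 0 else 1.0
    if not np.isfinite(dr0) or dr0 <= 0:
        dr0 = 1.0
    starts = [np.array([k0, dr0]) for k0 in _log_spaced_starts(data.x)]
    bounds = (
        np.array([data.x.min() * 1e-6, 0.0]),
        np.array([data.x.max() * 1e6, max(10.0 * np.nanmax(np.abs(y)) / max(f0, 1e-3), 1e-6)]),
    )
    best, n_starts = _run_multistart(model, y, starts, bounds,
                                     ("K_N", "delta_r"), 0, weights)
    return _finish("displacement", ("K_N", "delta_r"), ("K_N",), best,
                   n_starts, y, data.x.max(), dialect=dialect,
                   fixed={"K_L": K_L, "P0": P0, "L0": L0})


def fit_hill(data: TitrationDataset, fix_h: float | None = None,
             fix_floor: float | None = 0.0,
             weighting: str | None = None) -> FitResult:
    """Fit the specific-binding Hill model ``{K_d, h, B_max, floor}``.

    By default the baseline is fixed at 0 (plain "specific binding with Hill
    slope"); pass ``fix_floor=None`` to free it, ``fix_h=1`` for the
    rectangular hyperbola.
    """
    if data.mode != "hill":
        raise ValueError("fit_hill requires mode='hill'")
    x, y = data.flat()
    weights = _weights(weighting, y)

    free: list[str] = ["K_d"]
    if fix_h is None:
        free.append("h")
    if fix_floor is None:
        free.append("floor")
    free.append("B_max")

    def unpack(theta):
        vals = dict(zip(free, theta))
        return HillParams(
            K_d=vals["K_d"],
            h=vals.get("h", fix_h if fix_h is not None else 1.0),
            B_max=vals["B_max"],
            floor=vals.get("floor", fix_floor if fix_floor is not None else 0.0),
        )

    def model(theta):
        vals = dict(zip(free, theta))
        h = vals.get("h", fix_h if fix_h is not None else 1.0)
        floor = vals.get("floor", fix_floor if fix_floor is not None else 0.0)
        xh = np.power(x, h)
        return floor + (vals["B_max"] - floor) * xh / (vals["K_d"] ** h + xh)

    b_max0 = float(np.nanmax(y)) if np.nanmax(y) > 0 else 1.0
    starts = []
    for k0 in _log_spaced_starts(data.x):
        theta0 = {"K_d": k0, "h": 1.0, "floor": float(np.nanmin(y)), "B_max": b_max0}
        starts.append(np.array([theta0[name] for name in free]))
    lo = {"K_d": data.x.min() * 1e-6, "h": 0.05,
          "floor": -10.0 * abs(b_max0), "B_max": 0.0}
    hi = {"K_d": data.x.max() * 1e6, "h": 10.0,
          "floor": 10.0 * abs(b_max0), "B_max": 10.0 * abs(b_max0)}
    bounds = (np.array([lo[n] for n in free]), np.array([hi[n] for n in free]))
    best, n_starts = _run_multistart(model, y, starts, bounds, free, 0, weights)
    fixed = {}
    if fix_h is not None:
        fixed["h"] = float(fix_h)
    if fix_floor is not None:
        fixed["floor"] = float(fix_floor)
    result = _finish("hill", free, ("K_d",), best, n_starts, y, data.x.max(),
                     fixed=fixed)
    # make the full parameter set available regardless of what was fixed
    params = unpack(best.x)
    result.estimates.setdefault("h", params.h)
    result.estimates.setdefault("floor", params.floor)
    return result


def _weights(weighting: str | None, y: np.ndarray) -> np.ndarray | None:
    """OLS by default; ``"1/y2"`` gives relative (1/yhat^2-style) weighting."""
    if weighting is None:
        return None
    if weighting == "1/y2":
        scale = np.maximum(np.abs(y), 1e-3 * np.nanmax(np.abs(y)))
        return 1.0 / scale
    raise ValueError(f"unknown weighting {weighting!r}")


# ---------------------------------------------------------------------------
# densitometry and comparisons
# ---------------------------------------------------------------------------

def fraction_bound_from_densitometry(
    lane_intensities,
    reference: str = "unbound",
    reference_value: float | None = None,
):
    """Per-lane bound fraction from gel-band densitometry.

    ``reference="unbound"`` quantifies depletion of the free-probe band:
    ``1 - I / I_ref`` where ``I_ref`` is the unbound-band intensity of the
    zero-protein lane (the first lane if ``reference_value`` is not given).
    ``reference="bound"`` quantifies the shifted band directly:
    ``I / I_ref`` with ``I_ref`` the saturated bound-band (or total-probe)
    intensity, defaulting to the brightest lane.  Values are clamped to
    [0, 1]; clamping is logged.
    """
    I = np.asarray(lane_intensities, dtype=float)
    if I.size == 0:
        raise ValueError("no lane intensities supplied")
    if np.any(I < 0):
        raise ValueError("lane intensities must be >= 0")
    if reference == "unbound":
        ref = float(I[0]) if reference_value is None else float(reference_value)
        if ref <= 0:
            raise ValueError("unbound reference (zero-protein lane) must be > 0")
        frac = 1.0 - I / ref
    elif reference == "bound":
        ref = float(I.max()) if reference_value is None else float(reference_value)
        if ref <= 0:
            raise ValueError("bound reference intensity must be > 0")
        frac = I / ref
    else:
        raise ValueError(f"unknown reference mode {reference!r}")
    clipped = np.clip(frac, 0.0, 1.0)
    n_clamped = int(np.sum(clipped != frac))
    if n_clamped:
        logger.info("fraction_bound: clamped %d lane(s) into [0, 1]", n_clamped)
    return clipped


def ratio_with_se(a: float, se_a: float, b: float, se_b: float) -> tuple[float, float]:
    """``a/b`` with first-order (delta-method) propagated standard error."""
    if b == 0:
        raise ZeroDivisionError("denominator estimate is zero")
    r = a / b
    se = abs(r) * np.sqrt((se_a / a) ** 2 + (se_b / b) ** 2) if a != 0 else se_a / abs(b)
    return float(r), float(se)


def fold_change(fit_a: FitResult, fit_b: FitResult, param: str,
                threshold: float | None = None) -> dict:
    """Ratio of a parameter between two fits, with propagated SE.

    Serves affinity or K_M comparisons such as "complex A binds >50-fold
    tighter than complex B".  Returns ``{"ratio", "se", "param",
    "exceeds_threshold"}`` (the last is None when no threshold is given).
    """
    for f in (fit_a, fit_b):
        if not f.converged:
            raise ValueError("fold_change requires converged fits")
        if param not in f.estimates:
            raise KeyError(f"parameter {param!r} missing from fit {f.model!r}")
    a, b = fit_a.estimates[param], fit_b.estimates[param]
    r, se = ratio_with_se(a, fit_a.se.get(param, 0.0), b, fit_b.se.get(param, 0.0))
    return {
        "param": param,
        "ratio": r,
        "se": se,
        "exceeds_threshold": (r > threshold) if threshold is not None else None,
    }


def normalize_relative_activity(values, reference_values) -> dict:
    """Normalise replicate activities to the mean of a reference condition.

    Returns ``{"mean", "sd", "points"}`` of the normalised replicates —
    the standard way densitometry activities are reported relative to a
    wild-type control.
    """
    ref = np.asarray(reference_values, dtype=float)
    ref_mean = float(ref.mean())
    if ref_mean <= 0:
        raise ValueError("reference mean must be > 0")
    pts = np.asarray(values, dtype=float) / ref_mean
    return {
        "mean": float(pts.mean()),
        "sd": float(pts.std(ddof=1)) if pts.size > 1 else 0.0,
        "points": pts,
    }
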