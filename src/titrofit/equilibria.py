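"""Closed-form binding equilibria and the forward models built on them.

This module is the pure model layer of the package.  It solves the
two-species (protein + labelled ligand) and three-species (protein +
labelled ligand + unlabelled competitor) binding equilibria exactly, and
exposes the observable models that the fitting layer composes with them:

* direct titration — the protein--probe complex concentration follows a
  quadratic mass-balance closed form;
* competitive (displacement) titration — free protein is a root of a monic
  cubic in ``[P]``; two coefficient *dialects* are supported (see
  :func:`cubic_coefficients`);
* :func:`predicted_anisotropy` — maps an equilibrium composition to the
  observable anisotropy change ``dRobs = dr * [PL] / ([PL] + [L])``;
* :func:`hill_signal` — specific binding with a Hill slope;
* :func:`mm_rate` — the Michaelis–Menten velocity.

All concentrations are molar throughout this module; unit conversion is the
I/O layer's job (:mod:`titrofit.io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DomainError",
    "EquilibriumError",
    "AffinityParams",
    "MixtureComposition",
    "SpeciesState",
    "CubicCoefficients",
    "HillParams",
    "MMParams",
    "solve_direct",
    "predicted_anisotropy",
    "cubic_coefficients",
    "solve_competitive",
    "oracle_solve",
    "hill_signal",
    "mm_rate",
]

Dialect = Literal["paper", "complete"]


class DomainError(ValueError):
    """Raised for physically invalid inputs (negative concentrations, K <= 0)."""


class EquilibriumError(RuntimeError):
    """Raised when no physical root can be located; carries diagnostics."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise DomainError(msg)


@dataclass(frozen=True)
class AffinityParams:
    """Equilibrium constants and anisotropy amplitude for one probe system.

    Parameters
    ----------
    K_L : float
        Dissociation constant of the protein--labelled-ligand complex (M).
    delta_r : float
        Anisotropy amplitude ``dr`` — the anisotropy change at full probe
        saturation (anisotropy units).
    K_N : float, optional
        Dissociation constant of the protein--unlabelled-competitor complex
        (M).  Required only for competitive equilibria.
    """

    K_L: float
    delta_r: float = 0.0
    K_N: float | None = None

    def __post_init__(self) -> None:
        _require(self.K_L > 0, f"K_L must be > 0, got {self.K_L}")
        if self.K_N is not None:
            _require(self.K_N > 0, f"K_N must be > 0, got {self.K_N}")
        _require(math.isfinite(self.delta_r), "delta_r must be finite")


@dataclass(frozen=True)
class MixtureComposition:
    """Total (analytic) concentrations in one titration well, molar.

    ``P0`` total protein, ``L0`` total labelled ligand, ``N0`` total
    unlabelled competitor (0 for a direct titration).
    """

    P0: float
    L0: float
    N0: float = 0.0

    def __post_init__(self) -> None:
        for name in ("P0", "L0", "N0"):
            _require(getattr(self, name) >= 0, f"{name} must be >= 0")


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations of all five species, molar."""

    P_free: float
    L_free: float
    N_free: float
    PL: float
    PN: float

    @property
    def P0(self) -> float:
        return self.P_free + self.PL + self.PN

    @property
    def L0(self) -> float:
        return self.L_free + self.PL

    @property
    def N0(self) -> float:
        return self.N_free + self.PN


@dataclass(frozen=True)
class CubicCoefficients:
    """Coefficients of the monic cubic in free protein, ``[P]^3 + c2 [P]^2 + c1 [P] + c0``."""

    c2: float
    c1: float
    c0: float
    dialect: Dialect


@dataclass(frozen=True)
class HillParams:
    """Specific-binding-with-Hill-slope parameters.

    ``signal(x) = floor + (B_max - floor) * x**h / (K_d**h + x**h)``
    """

    K_d: float
    h: float
    B_max: float
    floor: float = 0.0

    def __post_init__(self) -> None:
        _require(self.K_d > 0, "K_d must be > 0")
        _require(self.h > 0, "Hill coefficient h must be > 0")
        _require(self.B_max >= self.floor, "B_max must be >= floor")


@dataclass(frozen=True)
class MMParams:
    """Michaelis–Menten parameters: turnover k_cat (1/time), K_M (M), enzyme E0 (M)."""

    k_cat: float
    K_M: float
    E0: float

    def __post_init__(self) -> None:
        _require(self.k_cat > 0, "k_cat must be > 0")
        _require(self.K_M > 0, "K_M must be > 0")
        _require(self.E0 > 0, "E0 must be > 0")

    @property
    def efficiency(self) -> float:
        """Catalytic efficiency k_cat / K_M."""
        return self.k_cat / self.K_M


# ---------------------------------------------------------------------------
# two-species (direct titration) equilibrium
# ---------------------------------------------------------------------------

def complex_direct(P0, L0, K_L):
    """Vectorised [PL] for the two-species equilibrium.

    Uses the subtraction-free form ``2*P0*L0 / (b + sqrt(b^2 - 4*P0*L0))``
    with ``b = K_L + P0 + L0``, which is numerically stable when the complex
    concentration is far below ``b`` (the usual case at low probe
    concentration).
    """
    P0 = np.asarray(P0, dtype=float)
    L0 = np.asarray(L0, dtype=float)
    if np.any(P0 < 0) or np.any(L0 < 0):
        raise DomainError("total concentrations must be >= 0")
    if not K_L > 0:
        raise DomainError("K_L must be > 0")
    b = K_L + P0 + L0
    disc = b * b - 4.0 * P0 * L0
    root = np.sqrt(np.maximum(disc, 0.0))
    pl = np.where(b + root > 0, 2.0 * P0 * L0 / (b + root), 0.0)
    # the complex can never exceed the limiting species
    return np.minimum(pl, np.minimum(P0, L0))


def solve_direct(comp: MixtureComposition, params: AffinityParams) -> SpeciesState:
    """Exact two-species equilibrium for a direct titration (no competitor)."""
    _require(comp.N0 == 0, "solve_direct requires N0 = 0; use solve_competitive")
    pl = float(complex_direct(comp.P0, comp.L0, params.K_L))
    return SpeciesState(
        P_free=max(comp.P0 - pl, 0.0),
        L_free=max(comp.L0 - pl, 0.0),
        N_free=0.0,
        PL=pl,
        PN=0.0,
    )


def predicted_anisotropy(state: SpeciesState, delta_r: float) -> float:
    """Observable anisotropy change ``dRobs = dr * [PL] / ([PL] + [L])``.

    Because ``[PL] + [L] = L0``, this is ``dr`` times the bound fraction of
    the labelled ligand.
    """
    denom = state.PL + state.L_free
    if denom <= 0:
        raise DomainError("predicted_anisotropy undefined for L0 = 0")
    return delta_r * state.PL / denom


# ---------------------------------------------------------------------------
# three-species (competitive) equilibrium
# ---------------------------------------------------------------------------

def cubic_coefficients(
    comp: MixtureComposition,
    params: AffinityParams,
    dialect: Dialect = "complete",
) -> CubicCoefficients:
    """Coefficients of the monic cubic whose physical root is free protein.

    ``dialect="complete"`` uses the exact competitive-binding coefficient
    ``c1 = K_L*K_N + K_N*L0 - K_N*P0 + K_L*N0 - K_L*P0``.

    ``dialect="paper"`` drops the ``K_N*L0`` term from ``c1``.  That form
    circulates in the displacement-titration literature and is an excellent
    approximation whenever the labelled probe is present in trace amounts
    (``L0`` much below ``K_L``, ``K_N`` and ``P0``), but it violates the
    ligand mass balance when ``L0`` is comparable to the other scales.
    """
    if params.K_N is None:
        raise DomainError("cubic_coefficients requires K_N")
    K_L, K_N = params.K_L, params.K_N
    P0, L0, N0 = comp.P0, comp.L0, comp.N0
    c2 = K_L + K_N + N0 + L0 - P0
    if dialect == "complete":
        c1 = K_L * K_N + K_N * L0 - K_N * P0 + K_L * N0 - K_L * P0
    elif dialect == "paper":
        c1 = K_L * K_N - K_N * P0 + K_L * N0 - K_L * P0
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    c0 = -K_L * K_N * P0
    return CubicCoefficients(c2=c2, c1=c1, c0=c0, dialect=dialect)


def _solve_cubic_physical(c2, c1, c0, P0):
    """Vectorised physical root of ``x^3 + c2 x^2 + c1 x + c0`` in [0, P0].

    All three roots are computed in closed form (trigonometric branch for
    three real roots, Cardano for one), the unique candidate in
    ``[-tol, P0 + tol]`` is selected, polished with a few Newton steps on
    the original cubic, and clamped to ``[0, P0]``.  Returns an array of the
    broadcast shape; entries are NaN where no candidate was found.
    """
    c2, c1, c0, P0 = np.broadcast_arrays(
        *(np.atleast_1d(np.asarray(a, dtype=float)) for a in (c2, c1, c0, P0))
    )
    p = c1 - c2 * c2 / 3.0
    q = 2.0 * c2**3 / 27.0 - c2 * c1 / 3.0 + c0
    disc = (q / 2.0) ** 2 + (p / 3.0) ** 3

    roots = np.full(c2.shape + (3,), np.nan)

    three_real = disc <= 0
    with np.errstate(invalid="ignore", divide="ignore"):
        m = 2.0 * np.sqrt(np.maximum(-p / 3.0, 0.0))
        pm = p * m
        arg = np.where(pm != 0, 3.0 * q / np.where(pm != 0, pm, 1.0), 0.0)
        theta = np.arccos(np.clip(arg, -1.0, 1.0)) / 3.0
        for k in range(3):
            tk = m * np.cos(theta - 2.0 * np.pi * k / 3.0)
            roots[..., k] = np.where(three_real, tk - c2 / 3.0, np.nan)

    one_real = ~three_real
    if np.any(one_real):
        sq = np.sqrt(np.maximum(disc, 0.0))
        # subtraction-free Cardano: A = cbrt(-q/2 - sign(q)*sqrt(disc))
        u = -q / 2.0 - np.sign(q) * sq
        A = np.cbrt(u)
        with np.errstate(invalid="ignore", divide="ignore"):
            B = np.where(A != 0, -p / (3.0 * np.where(A != 0, A, 1.0)), 0.0)
        t = A + B
        roots[..., 0] = np.where(one_real, t - c2 / 3.0, roots[..., 0])

    scale = np.maximum(P0, 1e-300)
    tol = 1e-6 * scale
    lo = -tol[..., None]
    hi = (P0 + tol)[..., None]
    ok = (roots >= lo) & (roots <= hi)
    cand = np.where(ok, roots, -np.inf)
    x = np.max(cand, axis=-1)
    x = np.where(np.isfinite(x), x, np.nan)

    def cubic(v):
        return ((v + c2) * v + c1) * v + c0

    def polish(v, n=4):
        # Newton on the original cubic: quadratic convergence near the
        # simple physical root; leaves NaNs untouched
        for _ in range(n):
            f = cubic(v)
            fp = (3.0 * v + 2.0 * c2) * v + c1
            with np.errstate(invalid="ignore", divide="ignore"):
                step = np.where(fp != 0, f / np.where(fp != 0, fp, 1.0), 0.0)
            v = v - step
        return v

    x = polish(x)

    # The closed form loses the small root when the three roots span many
    # orders of magnitude (e.g. an enormously weak competitor).  The physical
    # root is always bracketed by [0, P0] (cubic(0) = c0 <= 0), so fall back
    # to vectorised bisection wherever the closed-form answer fails a
    # residual check.
    gscale = np.abs(c0) + np.abs(c1) * scale + np.abs(c2) * scale**2 + scale**3
    with np.errstate(invalid="ignore"):
        bad = ~np.isfinite(x) | (np.abs(cubic(x)) > 1e-8 * gscale)
    if np.any(bad):
        blo = np.zeros_like(P0)
        bhi = P0.copy()
        no_bracket = cubic(bhi) < 0  # root just above P0 (truncated dialect)
        for _ in range(90):
            mid = 0.5 * (blo + bhi)
            take_hi = cubic(mid) > 0
            bhi = np.where(take_hi, mid, bhi)
            blo = np.where(take_hi, blo, mid)
        xb = polish(0.5 * (blo + bhi), n=3)
        xb = np.where(no_bracket, P0, xb)
        x = np.where(bad, xb, x)

    return np.clip(x, 0.0, P0)


def free_protein_competitive(P0, L0, N0, K_L, K_N, dialect: Dialect = "complete"):
    """Vectorised free-protein concentration for the three-species system."""
    P0 = np.asarray(P0, dtype=float)
    L0 = np.asarray(L0, dtype=float)
    N0 = np.asarray(N0, dtype=float)
    c2 = K_L + K_N + N0 + L0 - P0
    if dialect == "complete":
        c1 = K_L * K_N + K_N * L0 - K_N * P0 + K_L * N0 - K_L * P0
    elif dialect == "paper":
        c1 = K_L * K_N - K_N * P0 + K_L * N0 - K_L * P0
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    c0 = -K_L * K_N * P0
    return _solve_cubic_physical(c2, c1, c0, P0)


def _state_from_free_protein(p_free: float, comp: MixtureComposition,
                             K_L: float, K_N: float) -> SpeciesState:
    pl = comp.L0 * p_free / (K_L + p_free)
    pn = comp.N0 * p_free / (K_N + p_free)
    return SpeciesState(
        P_free=p_free,
        L_free=max(comp.L0 - pl, 0.0),
        N_free=max(comp.N0 - pn, 0.0),
        PL=pl,
        PN=pn,
    )


def solve_competitive(
    comp: MixtureComposition,
    params: AffinityParams,
    dialect: Dialect = "complete",
) -> SpeciesState:
    """Exact three-species equilibrium via the cubic in free protein.

    With ``dialect="complete"`` the returned state satisfies every mass
    balance and mass-action relation to solver precision.  With
    ``dialect="paper"`` the ligand balance holds only approximately unless
    ``L0`` is trace-level (the regime the approximation was built for).
    """
    if params.K_N is None:
        raise DomainError("solve_competitive requires K_N")
    if comp.P0 == 0:
        return SpeciesState(0.0, comp.L0, comp.N0, 0.0, 0.0)
    coeffs = cubic_coefficients(comp, params, dialect)
    p_free = float(
        _solve_cubic_physical(coeffs.c2, coeffs.c1, coeffs.c0, comp.P0)[0]
    )
    if not np.isfinite(p_free):
        raise EquilibriumError(
            "no physical root in [0, P0] for cubic "
            f"c2={coeffs.c2:.6g}, c1={coeffs.c1:.6g}, c0={coeffs.c0:.6g}, "
            f"P0={comp.P0:.6g}, dialect={dialect}"
        )
    return _state_from_free_protein(p_free, comp, params.K_L, params.K_N)


def oracle_solve(comp: MixtureComposition, params: AffinityParams) -> SpeciesState:
    """Independent reference solver: bracketed 1-D root finding on free protein.

    Solves ``P + L0*P/(K_L+P) + N0*P/(K_N+P) - P0 = 0`` with Brent's method.
    The left-hand side is strictly increasing in ``P``, so the root is unique
    and always bracketed by ``[0, P0]``.  This solver never touches the cubic
    and serves as the oracle that :func:`solve_competitive` is validated
    against.
    """
    K_L = params.K_L
    K_N = params.K_N if params.K_N is not None else 1.0  # unused when N0 = 0
    if comp.N0 > 0 and params.K_N is None:
        raise DomainError("oracle_solve requires K_N when N0 > 0")
    if comp.P0 == 0:
        return SpeciesState(0.0, comp.L0, comp.N0, 0.0, 0.0)

    def balance(p: float) -> float:
        return (
            p
            + comp.L0 * p / (K_L + p)
            + comp.N0 * p / (K_N + p)
            - comp.P0
        )

    if balance(comp.P0) <= 0:  # only when L0 = N0 = 0
        p_free = comp.P0
    else:
        p_free = brentq(balance, 0.0, comp.P0, xtol=1e-300, rtol=8.9e-16,
                        maxiter=200)
    return _state_from_free_protein(p_free, comp, K_L, K_N)


# ---------------------------------------------------------------------------
# empirical observable models
# ---------------------------------------------------------------------------

def hill_signal(x, params: HillParams):
    """Specific binding with a Hill slope; monotone nondecreasing in x."""
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        raise DomainError("titrant concentration must be >= 0")
    xh = np.power(x, params.h)
    out = params.floor + (params.B_max - params.floor) * xh / (params.K_d ** params.h + xh)
    return out if out.ndim else float(out)


def mm_rate(S, params: MMParams):
    """Michaelis–Menten velocity ``v = k_cat * E0 * S / (K_M + S)``."""
    S = np.asarray(S, dtype=float)
    if np.any(S < 0):
        raise DomainError("substrate concentration must be >= 0")
    out = params.k_cat * params.E0 * S / (params.K_M + S)
    return out if out.ndim else float(out)
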