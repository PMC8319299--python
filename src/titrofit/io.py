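"""Tabular readers/writers, unit handling and small quantification utilities.

Concentration units are declared **once** per file (``units`` key in the
config or ``--units`` on the CLI), never per row; everything downstream of
the readers is molar.  Supported unit symbols: ``M``, ``mM``, ``uM``
(``µM`` accepted), ``nM``, ``pM``.

Titration CSV layout: columns ``x, signal, replicate`` plus an optional
truthy ``blank`` column marking probe-only wells; blank rows are averaged
and subtracted from the signals at load time (the blank mean is recorded in
``dataset.meta``).

Kinetics CSV layout: columns ``S_nM, signal, replicate, well_type`` with
``well_type`` one of ``reaction``, ``no_substrate``, ``no_enzyme``;
config keys ``E0_nM``, ``time_min``, ``condition``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .fitting import FitResult, TitrationDataset, subtract_background
from .kinetics import KineticsDataset

__all__ = [
    "InputError",
    "UNIT_FACTORS",
    "to_molar",
    "from_molar",
    "read_titration_csv",
    "read_kinetics_csv",
    "write_report",
    "QpcrSample",
    "percent_input",
]


class InputError(ValueError):
    """Malformed input file or configuration."""


UNIT_FACTORS = {
    "M": 1.0,
    "mM": 1e-3,
    "uM": 1e-6,
    "µM": 1e-6,
    "nM": 1e-9,
    "pM": 1e-12,
}


def _factor(units: str) -> float:
    try:
        return UNIT_FACTORS[units]
    except KeyError:
        raise InputError(
            f"unknown concentration unit {units!r}; use one of {sorted(UNIT_FACTORS)}"
        ) from None


def to_molar(value, units: str):
    """Convert from declared units to molar."""
    return np.asarray(value, dtype=float) * _factor(units)


def from_molar(value, units: str):
    """Convert from molar to declared units."""
    return np.asarray(value, dtype=float) / _factor(units)


def _numeric_column(df: pd.DataFrame, col: str, path) -> np.ndarray:
    vals = pd.to_numeric(df[col], errors="coerce")
    bad = df.index[vals.isna() & df[col].notna()]
    if len(bad):
        # +2: header line plus 1-based indexing
        lines = ", ".join(str(i + 2) for i in bad[:5])
        raise InputError(
            f"{path}: non-numeric value in column {col!r} at line(s) {lines}"
        )
    if vals.isna().any():
        lines = ", ".join(str(i + 2) for i in df.index[vals.isna()][:5])
        raise InputError(f"{path}: missing value in column {col!r} at line(s) {lines}")
    return vals.to_numpy(dtype=float)


def read_titration_csv(path, config: dict) -> TitrationDataset:
    """Load and validate one titration experiment from CSV.

    ``config`` keys: ``mode`` (direct/displacement/hill), ``units``,
    ``probe_conc`` (in declared units; required for direct/displacement),
    ``fixed`` (dict in declared units, e.g. ``{"K_L": 8.07, "P0": 10}``
    with µM declared), optional ``meta``.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise InputError(f"no such file: {path}") from None
    except Exception as exc:
        raise InputError(f"{path}: could not parse CSV ({exc})") from None

    required = {"x", "signal", "replicate"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing column(s) {sorted(missing)}")

    units = config.get("units", "M")
    mode = config.get("mode")
    if mode is None:
        raise InputError("config must declare 'mode'")

    if "blank" in df.columns:
        is_blank = df["blank"].fillna(0).astype(bool).to_numpy()
    else:
        is_blank = np.zeros(len(df), dtype=bool)

    x_all = _numeric_column(df, "x", path)
    y_all = _numeric_column(df, "signal", path)
    rep_all = _numeric_column(df, "replicate", path).astype(int)

    blank_mean = None
    y_use = y_all[~is_blank]
    if is_blank.any():
        y_use, blank_mean = subtract_background(y_use, y_all[is_blank])
    x_use, rep_use = x_all[~is_blank], rep_all[~is_blank]

    xs = np.unique(x_use)
    if xs.size < 5:
        raise InputError(f"{path}: need >= 5 distinct x values, found {xs.size}")
    reps = np.unique(rep_use)
    signals = np.full((xs.size, reps.size), np.nan)
    for i, xv in enumerate(xs):
        for j, rv in enumerate(reps):
            sel = (x_use == xv) & (rep_use == rv)
            if sel.sum() != 1:
                raise InputError(
                    f"{path}: expected exactly one row for x={xv:g}, "
                    f"replicate={rv} (found {int(sel.sum())})"
                )
            signals[i, j] = y_use[sel][0]

    fixed_cfg = config.get("fixed", {})
    fixed = {k: float(to_molar(v, units)) for k, v in fixed_cfg.items()}
    probe = config.get("probe_conc")
    probe_conc = float(to_molar(probe, units)) if probe is not None else None

    meta = dict(config.get("meta", {}))
    meta.update({"source": str(path), "units": units,
                 "sha256": _sha256(path)})
    if blank_mean is not None:
        meta["blank_mean"] = blank_mean

    try:
        return TitrationDataset(
            mode=mode, x=to_molar(xs, units), signals=signals,
            probe_conc=probe_conc, fixed=fixed, meta=meta,
        )
    except ValueError as exc:
        raise InputError(f"{path}: {exc}") from None


def read_kinetics_csv(path, config: dict) -> KineticsDataset:
    """Load one kinetics substrate titration with its control wells."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except FileNotFoundError:
        raise InputError(f"no such file: {path}") from None
    required = {"S_nM", "signal", "replicate", "well_type"}
    missing = required - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing column(s) {sorted(missing)}")

    s_all = _numeric_column(df, "S_nM", path)
    y_all = _numeric_column(df, "signal", path)
    well = df["well_type"].astype(str).str.strip()
    known = {"reaction", "no_substrate", "no_enzyme"}
    bad = ~well.isin(known)
    if bad.any():
        lines = ", ".join(str(i + 2) for i in df.index[bad][:5])
        raise InputError(f"{path}: unknown well_type at line(s) {lines}")

    rx = well == "reaction"
    S_nM = np.unique(s_all[rx])
    rep = _numeric_column(df, "replicate", path).astype(int)
    reps = np.unique(rep[rx])
    raw = np.full((S_nM.size, reps.size), np.nan)
    for i, sv in enumerate(S_nM):
        for j, rv in enumerate(reps):
            sel = rx.to_numpy() & (s_all == sv) & (rep == rv)
            if sel.sum() != 1:
                raise InputError(
                    f"{path}: expected exactly one reaction row for "
                    f"S_nM={sv:g}, replicate={rv}"
                )
            raw[i, j] = y_all[sel][0]

    try:
        e0_nM = float(config["E0_nM"])
        t_min = float(config["time_min"])
    except KeyError as exc:
        raise InputError(f"config missing required key {exc}") from None

    try:
        return KineticsDataset(
            S=S_nM * 1e-9,
            raw=raw,
            ctrl_no_substrate=y_all[(well == "no_substrate").to_numpy()],
            ctrl_no_enzyme=y_all[(well == "no_enzyme").to_numpy()],
            E0=e0_nM * 1e-9,
            t=t_min,
            signal_to_product=config.get("signal_to_product"),
            condition=str(config.get("condition", "")),
        )
    except ValueError as exc:
        raise InputError(f"{path}: {exc}") from None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_report(fits: list[FitResult], path, fmt: str = "json",
                 seed: int | None = None, inputs: list | None = None) -> Path:
    """Serialise fits to JSON (full) or TSV (one flat row per fit).

    The JSON report records the package version, the seed and the input
    checksums so a run can be reproduced bit-for-bit.
    """
    if not fits:
        raise ValueError("write_report needs at least one fit")
    path = Path(path)
    if fmt == "json":
        payload = {
            "titrofit_version": __version__,
            "seed": seed,
            "inputs": inputs or [],
            "fits": [f.to_dict() for f in fits],
        }
        path.write_text(json.dumps(payload, indent=2))
    elif fmt == "tsv":
        rows = []
        for f in fits:
            row: dict = {"model": f.model, "dialect": f.dialect,
                         "converged": f.converged, "rss": f.rss, "dof": f.dof}
            for k, v in f.estimates.items():
                row[k] = v
                if k in f.se:
                    row[f"{k}_se"] = f.se[k]
                if k in f.ci95:
                    row[f"{k}_ci_lo"], row[f"{k}_ci_hi"] = f.ci95[k]
            for k, v in f.flags.items():
                row[f"flag_{k}"] = v
            rows.append(row)
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")
    return path


# ---------------------------------------------------------------------------
# ChIP-qPCR percent input
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QpcrSample:
    """Cq values (technical replicates pre-averaged) and volumes for one ChIP sample."""

    cq_ip: float
    cq_input: float
    v_input: float
    v_ip: float

    def __post_init__(self) -> None:
        if not (self.v_input > 0 and self.v_ip > 0):
            raise ValueError("volumes must be > 0")
        if not (math.isfinite(self.cq_ip) and math.isfinite(self.cq_input)):
            raise ValueError("Cq values must be finite")


def percent_input(sample: QpcrSample | None = None, *,
                  cq_ip=None, cq_input=None,
                  v_input: float | None = None, v_ip: float | None = None) -> float:
    """Fraction of input chromatin recovered in the IP.

    ``2**(-(Cq[IP] - Cq[input])) * (v_input / v_ip)``.  Technical-replicate
    Cq arrays may be passed directly; they are averaged before the formula.
    """
    if sample is None:
        if cq_ip is None or cq_input is None or v_input is None or v_ip is None:
            raise ValueError("supply a QpcrSample or all keyword arguments")
        sample = QpcrSample(
            cq_ip=float(np.mean(cq_ip)),
            cq_input=float(np.mean(cq_input)),
            v_input=float(v_input),
            v_ip=float(v_ip),
        )
    return 2.0 ** (-(sample.cq_ip - sample.cq_input)) * (sample.v_input / sample.v_ip)
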