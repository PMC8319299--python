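"""Synthetic titration and kinetics datasets with the assays' statistical structure.

Every generator is a deterministic function of ``(preset, seed)``: the same
seed always yields the same dataset.  Noise is additive Gaussian on the
observable (anisotropy change, fraction bound or luminescence) and
homoscedastic, matching the unweighted least-squares objective used by the
fitting layer.

The shipped presets mirror the assay designs the analysis was built for:
2-fold serial dilutions with 3 replicates; a 40 nM labelled methyl-lysine
peptide probe with 10 µM receptor for displacement titrations; a 5 nM
labelled DNA or nucleosome probe for Hill-type titrations; and 8-point
substrate series for enzyme kinetics.  Affinity truths are µM-scale for the
peptide--EED system, nM-scale for DNA/nucleosome binding, and K_M of a few
hundred nM for the methyltransferase.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np

from .equilibria import (
    AffinityParams,
    HillParams,
    MMParams,
    complex_direct,
    free_protein_competitive,
    hill_signal,
    mm_rate,
)
from .fitting import TitrationDataset
from .kinetics import KineticsDataset

__all__ = [
    "ScenarioPreset",
    "PRESETS",
    "get_preset",
    "list_presets",
    "gen_direct_titration",
    "gen_displacement",
    "gen_hill_titration",
    "gen_mm_kinetics",
    "generate",
]

Truth = Union[AffinityParams, HillParams, MMParams]


@dataclass(frozen=True)
class ScenarioPreset:
    """A named simulation scenario: truth + titration design + noise level.

    ``design`` keys: ``top`` (highest concentration, M), ``fold`` (serial
    dilution factor), ``n_points``, ``n_replicates``.  ``fixed`` carries the
    constants of the assay (``L0``; plus ``P0`` for displacement; ``E0``,
    ``t``, background offsets for kinetics), all molar / minutes.
    ``noise_sd`` is the Gaussian SD on the observable, in signal units.
    """

    name: str
    kind: str  # direct | displacement | hill | mm
    truth: Truth
    design: dict
    fixed: dict = field(default_factory=dict)
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("direct", "displacement", "hill", "mm"):
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        if self.design.get("n_points", 0) < 5:
            raise ValueError("designs need >= 5 titration points")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def series(self) -> np.ndarray:
        """Descending serial-dilution series defined by the design."""
        top = self.design["top"]
        fold = self.design.get("fold", 2.0)
        n = self.design["n_points"]
        return top / fold ** np.arange(n)


def _rng(seed: int | None) -> np.random.Generator:
    return np.random.default_rng(seed)


def _noisy(clean: np.ndarray, n_rep: int, sd: float,
           rng: np.random.Generator) -> np.ndarray:
    base = np.tile(clean[:, None], (1, n_rep))
    if sd > 0:
        base = base + rng.normal(0.0, sd, size=base.shape)
    return base


def gen_direct_titration(preset: ScenarioPreset, seed: int | None = None,
                         noise_sd: float | None = None) -> TitrationDataset:
    """Direct titration: protein series against a fixed labelled probe."""
    if preset.kind != "direct":
        raise ValueError("preset is not a direct-titration scenario")
    truth: AffinityParams = preset.truth
    L0 = preset.fixed["L0"]
    sd = preset.noise_sd if noise_sd is None else noise_sd
    p_series = preset.series()
    clean = truth.delta_r * complex_direct(p_series, L0, truth.K_L) / L0
    rng = _rng(seed)
    signals = _noisy(clean, preset.design.get("n_replicates", 3), sd, rng)
    return TitrationDataset(
        mode="direct", x=p_series, signals=signals, probe_conc=L0,
        meta={"scenario": preset.name, "truth_K_L": truth.K_L,
              "truth_delta_r": truth.delta_r, "seed": seed, "noise_sd": sd},
    )


def gen_displacement(preset: ScenarioPreset, seed: int | None = None,
                     noise_sd: float | None = None) -> TitrationDataset:
    """Displacement titration: competitor series against fixed protein + probe."""
    if preset.kind != "displacement":
        raise ValueError("preset is not a displacement scenario")
    truth: AffinityParams = preset.truth
    L0 = preset.fixed["L0"]
    P0 = preset.fixed["P0"]
    sd = preset.noise_sd if noise_sd is None else noise_sd
    n_series = preset.series()
    p_free = free_protein_competitive(P0, L0, n_series, truth.K_L, truth.K_N,
                                      dialect="complete")
    pl = L0 * p_free / (truth.K_L + p_free)
    clean = truth.delta_r * pl / L0
    rng = _rng(seed)
    signals = _noisy(clean, preset.design.get("n_replicates", 3), sd, rng)
    return TitrationDataset(
        mode="displacement", x=n_series, signals=signals, probe_conc=L0,
        fixed={"K_L": truth.K_L, "P0": P0},
        meta={"scenario": preset.name, "truth_K_N": truth.K_N,
              "truth_delta_r": truth.delta_r, "seed": seed, "noise_sd": sd},
    )


def gen_hill_titration(preset: ScenarioPreset, seed: int | None = None,
                       noise_sd: float | None = None) -> TitrationDataset:
    """Hill-type titration (FA on DNA probes, or EMSA fraction bound)."""
    if preset.kind != "hill":
        raise ValueError("preset is not a hill scenario")
    truth: HillParams = preset.truth
    sd = preset.noise_sd if noise_sd is None else noise_sd
    x = preset.series()
    clean = hill_signal(x, truth)
    rng = _rng(seed)
    signals = _noisy(np.asarray(clean), preset.design.get("n_replicates", 3),
                     sd, rng)
    return TitrationDataset(
        mode="hill", x=x, signals=signals,
        probe_conc=preset.fixed.get("L0"),
        meta={"scenario": preset.name, "truth_K_d": truth.K_d,
              "truth_h": truth.h, "truth_B_max": truth.B_max, "seed": seed,
              "noise_sd": sd},
    )


def gen_mm_kinetics(preset: ScenarioPreset, seed: int | None = None,
                    noise_sd: float | None = None) -> KineticsDataset:
    """Endpoint luminescence kinetics with automethylation and spontaneous offsets.

    Reaction wells accumulate ``v(S)*t`` product signal on top of the
    enzyme-automethylation and spontaneous-conversion backgrounds; the
    no-substrate control carries both backgrounds, the no-enzyme control
    only the spontaneous one — exactly the structure
    :func:`titrofit.kinetics.background_correct` assumes.
    """
    if preset.kind != "mm":
        raise ValueError("preset is not a kinetics scenario")
    truth: MMParams = preset.truth
    sd = preset.noise_sd if noise_sd is None else noise_sd
    t = preset.fixed["t"]
    auto = preset.fixed.get("auto_offset", 0.0)
    spont = preset.fixed.get("spont_offset", 0.0)
    n_rep = preset.design.get("n_replicates", 3)
    S = preset.series()
    clean = mm_rate(S, truth) * t + auto + spont
    rng = _rng(seed)
    raw = _noisy(np.asarray(clean), n_rep, sd, rng)
    ctrl_no_sub = auto + spont + (rng.normal(0.0, sd, n_rep) if sd > 0 else np.zeros(n_rep))
    ctrl_no_enz = spont + (rng.normal(0.0, sd, n_rep) if sd > 0 else np.zeros(n_rep))
    return KineticsDataset(
        S=S, raw=raw, ctrl_no_substrate=ctrl_no_sub, ctrl_no_enzyme=ctrl_no_enz,
        E0=truth.E0, t=t, signal_to_product=1.0,
        condition=preset.name,
    )


_GENERATORS = {
    "direct": gen_direct_titration,
    "displacement": gen_displacement,
    "hill": gen_hill_titration,
    "mm": gen_mm_kinetics,
}


def generate(preset: ScenarioPreset, seed: int | None = None,
             noise_sd: float | None = None):
    """Dispatch to the generator matching ``preset.kind``."""
    return _GENERATORS[preset.kind](preset, seed=seed, noise_sd=noise_sd)


# ---------------------------------------------------------------------------
# preset registry
# ---------------------------------------------------------------------------

_uM = 1e-6
_nM = 1e-9

# peptide fluorescence-anisotropy assays: 40 nM labelled probe, 10 µM
# receptor for displacement, delta_r = 0.1 anisotropy units, replicate
# noise at 1% of delta_r
_PEPTIDE_FA = dict(L0=40 * _nM)
_DISPLACEMENT_FIXED = dict(L0=40 * _nM, P0=10 * _uM)
_PEP_NOISE = 0.001
_K_L_PROBE = 8.07 * _uM  # labelled JARID2-K116me3 probe vs EED


def _displacement_preset(name: str, K_N_uM: float, top_uM: float = 400.0):
    return ScenarioPreset(
        name=name,
        kind="displacement",
        truth=AffinityParams(K_L=_K_L_PROBE, K_N=K_N_uM * _uM, delta_r=0.1),
        design=dict(top=top_uM * _uM, fold=2.0, n_points=12, n_replicates=3),
        fixed=dict(_DISPLACEMENT_FIXED),
        noise_sd=_PEP_NOISE,
    )


def _hill_preset(name: str, K_d_nM: float, h: float, B_max: float,
                 top_uM: float, probe_nM: float = 5.0):
    return ScenarioPreset(
        name=name,
        kind="hill",
        truth=HillParams(K_d=K_d_nM * _nM, h=h, B_max=B_max),
        design=dict(top=top_uM * _uM, fold=2.0, n_points=12, n_replicates=3),
        fixed=dict(L0=probe_nM * _nM),
        noise_sd=0.01 * B_max,
    )


def _mm_preset(name: str, K_M_nM: float, k_cat_per_min: float, E0_nM: float,
               top_nM: float = 2000.0):
    truth = MMParams(k_cat=k_cat_per_min, K_M=K_M_nM * _nM, E0=E0_nM * _nM)
    vmax_signal = truth.k_cat * truth.E0 * 120.0  # endpoint signal at saturation
    return ScenarioPreset(
        name=name,
        kind="mm",
        truth=truth,
        design=dict(top=top_nM * _nM, fold=2.0, n_points=8, n_replicates=3),
        fixed=dict(t=120.0, auto_offset=0.05 * vmax_signal,
                   spont_offset=0.02 * vmax_signal),
        noise_sd=0.02 * vmax_signal,
    )


PRESETS: dict[str, ScenarioPreset] = {
    # direct titration of EED against the labelled JARID2-K116me3 probe
    "JARID2-K116me3": ScenarioPreset(
        name="JARID2-K116me3",
        kind="direct",
        truth=AffinityParams(K_L=_K_L_PROBE, delta_r=0.1),
        design=dict(top=100 * _uM, fold=2.0, n_points=12, n_replicates=3),
        fixed=dict(_PEPTIDE_FA),
        noise_sd=_PEP_NOISE,
    ),
    # displacement panel: unlabelled methyl-lysine peptides vs EED
    "PALI1-K1241me3": _displacement_preset("PALI1-K1241me3", 7.49),
    "PALI1-K1241me2": _displacement_preset("PALI1-K1241me2", 19.0),
    # weak mono-methyl binder: wider series so the curve reaches ~4x K_N
    "PALI1-K1241me1": _displacement_preset("PALI1-K1241me1", 241.0, top_uM=1000.0),
    "H3K27me3": _displacement_preset("H3K27me3", 41.7, top_uM=1000.0),
    "PALI1-K1219me3": _displacement_preset("PALI1-K1219me3", 7.59),
    "PALI2-K1558me3": _displacement_preset("PALI2-K1558me3", 8.81),
    # inert unmethylated peptide: affinity far beyond the titration range
    "PALI1-K1241me0": _displacement_preset("PALI1-K1241me0", 1e6, top_uM=1000.0),
    # DNA fluorescence anisotropy (5 nM fluorescein probe, anisotropy a.u.)
    "CpG46": _hill_preset("CpG46", 155.0, h=1.0, B_max=0.15, top_uM=2.0),
    "CpG46-mt": _hill_preset("CpG46-mt", 73.7, h=1.0, B_max=0.15, top_uM=2.0),
    # EMSA fraction-bound titrations (Cy5 nucleosome probes)
    "NCP147-PRC2": _hill_preset("NCP147-PRC2", 2560.0, h=1.5, B_max=1.0, top_uM=16.0),
    "NCP147-PRC2-PALI1": _hill_preset("NCP147-PRC2-PALI1", 48.5, h=1.5, B_max=1.0, top_uM=2.0),
    "NCP182-PRC2": _hill_preset("NCP182-PRC2", 330.0, h=1.5, B_max=1.0, top_uM=4.0),
    "NCP182-PRC2-PALI1": _hill_preset("NCP182-PRC2-PALI1", 17.1, h=1.5, B_max=1.0, top_uM=2.0),
    # methyltransferase kinetics on nucleosome arrays (substrate per octamer)
    "MM-35mM-KCl": _mm_preset("MM-35mM-KCl", K_M_nM=224.0, k_cat_per_min=0.1, E0_nM=15.0),
    "MM-100mM-KCl": _mm_preset("MM-100mM-KCl", K_M_nM=392.0, k_cat_per_min=0.1, E0_nM=15.0),
}


def get_preset(name: str) -> ScenarioPreset:
    try:
        return PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; available: {', '.join(sorted(PRESETS))}"
        ) from None


def list_presets() -> list[str]:
    return sorted(PRESETS)
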