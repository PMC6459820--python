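"""Oligomer-level analysis: predicted mobilities, per-cell fits, K_D.

This is the headline pipeline.  Predicted diffusion coefficients for each
oligomer come from the length-scale viscosity model; autocorrelation
curves from individual cells are fitted with the variant-appropriate
protocol (two free components for species expected to be a single
oligomer, or a three-component model with the dimer and tetramer
diffusion times fixed at their predicted values for the wild type); the
fitted amplitudes, the detected concentration and the tagged fraction p
combine into the per-cell tetramerization dissociation constant

    K_D = (C_FCS / p) * A_dimer^2 / A_tetramer

valid under four gates: dimer<->tetramer equilibrium, excess untagged
protein (p << 1), amplitude-concentration proportionality (equal
brightness across oligomers, checked via CPM spread), and no contribution
of the slow/bound pool to the equilibrium.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .acf import (
    ACFComponentSpec,
    ACFFitResult,
    ACFModelSpec,
    AutocorrelationCurve,
    FocalVolume,
    TripletSpec,
    concentration_from_N,
    diffusion_to_tau,
    fit_acf,
    tau_to_diffusion,
)
from .errors import FitConvergenceError
from .viscosity import ViscosityParams, predict_diffusion, predict_diffusion_constant_viscosity


@dataclass(frozen=True)
class OligomerSpec:
    """One oligomeric state: label, subunit count, hydrodynamic radius [nm]."""

    name: str
    stoichiometry: int
    r_p_nm: float

    def __post_init__(self) -> None:
        if self.stoichiometry < 1:
            raise ValueError("stoichiometry must be >= 1")
        if self.r_p_nm <= 0:
            raise ValueError("r_p_nm must be positive")


#: EGFP-tagged Drp1 oligomers, hydrodynamic radii from bead-model hydrodynamics.
DRP1_OLIGOMERS = (
    OligomerSpec("monomer", 1, 4.74),
    OligomerSpec("dimer", 2, 6.41),
    OligomerSpec("tetramer", 4, 8.43),
)


def _check_radii_ordering(specs: Sequence[OligomerSpec]) -> None:
    ordered = sorted(specs, key=lambda s: s.stoichiometry)
    radii = [s.r_p_nm for s in ordered]
    if any(b <= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must increase strictly with stoichiometry")


def predict_oligomer_table(
    specs: Sequence[OligomerSpec],
    params: ViscosityParams,
    rel_const_viscosity: float = 2.34,
) -> pd.DataFrame:
    """Predicted diffusion coefficients per oligomer, both viscosity models.

    Columns: name, stoichiometry, r_p_nm, D_model_um2s (length-scale
    model), D_const_um2s (constant relative viscosity, e.g. the value
    probed by free EGFP), and the percent difference to the next oligomer
    100*(D_i - D_{i+1})/D_i under each model.
    """
    specs = sorted(specs, key=lambda s: s.stoichiometry)
    _check_radii_ordering(specs)
    rows = []
    for s in specs:
        rows.append({
            "name": s.name,
            "stoichiometry": s.stoichiometry,
            "r_p_nm": s.r_p_nm,
            "D_model_um2s": predict_diffusion(s.r_p_nm, params),
            "D_const_um2s": predict_diffusion_constant_viscosity(
                s.r_p_nm, rel_const_viscosity, params.eta0_pa_s, params.T_K
            ),
        })
    df = pd.DataFrame(rows)
    for col, out in (("D_model_um2s", "pct_diff_model"), ("D_const_um2s", "pct_diff_const")):
        d = df[col].to_numpy()
        pct = 100.0 * (d[:-1] - d[1:]) / d[:-1]
        df[out] = np.append(pct, np.nan)
    return df


@dataclass
class CellAnalysis:
    """Per-cell result: concentration, amplitudes, derived K_D, diagnostics."""

    cell_id: str
    C_FCS_nM: float
    p: float
    amplitudes: dict[str, float]
    K_D_uM: float | None = None
    no_tetramer: bool = False
    D_fast_um2s: float | None = None
    protocol: str = ""
    flags: list[str] = field(default_factory=list)
    fit: ACFFitResult | None = None

    def __post_init__(self) -> None:
        if self.C_FCS_nM <= 0:
            raise ValueError("C_FCS must be positive")
        if not (0 < self.p <= 1):
            raise ValueError("p must lie in (0, 1]")
        total = sum(self.amplitudes.values())
        if any(not (-1e-9 <= a <= 1 + 1e-9) for a in self.amplitudes.values()):
            raise ValueError("amplitudes must lie in [0, 1]")
        if total > 1 + 1e-9:
            raise ValueError("amplitudes must sum to <= 1")
        if self.K_D_uM is not None and self.K_D_uM < 0:
            raise ValueError("K_D must be non-negative when defined")


def compute_KD(C_FCS_nM: float, p: float, A_dimer: float, A_tetramer: float) -> float | None:
    """Tetramerization dissociation constant [uM] from per-cell FCS outputs.

    K_D = (C_FCS/p) * A_dimer^2 / A_tetramer.  ``A_tetramer == 0`` means no
    detectable tetramer: the constant is undefined and ``None`` is
    returned (an explicit outcome, not an exception).  ``A_dimer == 0``
    with tetramer present gives 0.
    """
    if C_FCS_nM <= 0:
        raise ValueError("C_FCS must be positive")
    if not (0 < p <= 1):
        raise ValueError("p must lie in (0, 1]")
    if A_dimer < 0 or A_tetramer < 0:
        raise ValueError("amplitudes must be non-negative")
    if A_tetramer == 0.0:
        return None
    kd_nM = (C_FCS_nM / p) * A_dimer**2 / A_tetramer
    return kd_nM * 1e-3  # nM -> uM


def dimer_tetramer_ratio(A_dimer: float, A_tetramer: float) -> tuple[float, float]:
    """Relative quantity of dimers vs tetramers over the cytosolic pool.

    Returns the pair normalized to sum 1, e.g. (0.34, 0.15) -> ~(0.7, 0.3).
    Both zero is undefined -> (nan, nan).
    """
    if A_dimer < 0 or A_tetramer < 0:
        raise ValueError("amplitudes must be non-negative")
    tot = A_dimer + A_tetramer
    if tot == 0.0:
        return (math.nan, math.nan)
    return (A_dimer / tot, A_tetramer / tot)


def equal_brightness_check(cpms: Sequence[float], max_rel_spread: float = 0.25) -> bool:
    """Gate on the amplitude-concentration proportionality assumption.

    Passes when the relative spread (SD/mean) of per-cell molecular
    brightness (CPM) values stays below ``max_rel_spread`` — evidence that
    all detected oligomers carry one fluorophore's worth of brightness.
    """
    c = np.asarray(cpms, dtype=float)
    if c.size < 2:
        return True
    if np.any(c <= 0):
        raise ValueError("CPM values must be positive")
    return float(c.std(ddof=1) / c.mean()) < max_rel_spread


Protocol = Literal["two_component", "three_component_fixed", "auto"]


def analyze_variant_cell(
    curve: AutocorrelationCurve,
    protocol: Protocol,
    fv: FocalVolume,
    p: float = 1.0,
    predicted_D_um2s: dict[str, float] | None = None,
    cell_id: str = "",
    blinking: bool = True,
    slow_tau_init_s: float = 5e-2,
    free_alpha_slow: bool = False,
    slow_amplitude_flag: float = 0.8,
    chi2_improvement_factor: float = 1.2,
) -> CellAnalysis:
    """Fit one cell's curve with the variant-appropriate protocol.

    ``two_component``: one free fast component plus one free slow
    component (non-oligomerizing variants); reports the fast D and
    amplitude.  ``three_component_fixed``: dimer and tetramer diffusion
    times fixed from ``predicted_D_um2s`` via tau = w_xy^2/(4D),
    amplitudes and the slow component free (wild type).  ``auto`` runs
    both and prefers the fixed three-component fit when its reduced chi^2
    is better by ``chi2_improvement_factor`` AND the free two-component
    fast time falls strictly between the two fixed times — the signature
    of an unresolved dimer/tetramer mixture.

    C_FCS comes from the fitted N and the calibrated effective volume.
    A fit failure raises ``FitConvergenceError`` (callers flag and exclude
    the cell).  Cells dominated by the slow pool (amplitude above
    ``slow_amplitude_flag``) are flagged low-information, not dropped.
    """
    if protocol not in ("two_component", "three_component_fixed", "auto"):
        raise ValueError(f"unknown protocol {protocol!r}")
    trip = TripletSpec() if blinking else None

    def fit_two() -> ACFFitResult:
        spec = ACFModelSpec(
            components=(
                ACFComponentSpec(tau_d_init=diffusion_to_tau(10.0, fv)),
                ACFComponentSpec(
                    tau_d_init=slow_tau_init_s,
                    alpha=None if free_alpha_slow else 1.0,
                ),
            ),
            kappa=fv.kappa, triplet=trip,
        )
        return fit_acf(curve, spec)

    def fit_three() -> ACFFitResult:
        if predicted_D_um2s is None or not {"dimer", "tetramer"} <= predicted_D_um2s.keys():
            raise ValueError(
                "three_component_fixed requires predicted_D_um2s with 'dimer' and 'tetramer'"
            )
        spec = ACFModelSpec(
            components=(
                ACFComponentSpec(tau_d_s=diffusion_to_tau(predicted_D_um2s["dimer"], fv)),
                ACFComponentSpec(tau_d_s=diffusion_to_tau(predicted_D_um2s["tetramer"], fv)),
                ACFComponentSpec(
                    tau_d_init=slow_tau_init_s,
                    alpha=None if free_alpha_slow else 1.0,
                ),
            ),
            kappa=fv.kappa, triplet=trip,
        )
        return fit_acf(curve, spec)

    flags: list[str] = []
    chosen = protocol
    if protocol == "two_component":
        res = fit_two()
    elif protocol == "three_component_fixed":
        res = fit_three()
    else:
        res2 = fit_two()
        res3 = fit_three()
        tau_lo = min(diffusion_to_tau(predicted_D_um2s["dimer"], fv),
                     diffusion_to_tau(predicted_D_um2s["tetramer"], fv))
        tau_hi = max(diffusion_to_tau(predicted_D_um2s["dimer"], fv),
                     diffusion_to_tau(predicted_D_um2s["tetramer"], fv))
        in_between = tau_lo < res2.tau_ds_s[0] < tau_hi
        better = res2.redchi > chi2_improvement_factor * res3.redchi
        if in_between and better:
            res, chosen = res3, "three_component_fixed"
            flags.append("auto: mixture signature, fixed-time model selected")
        else:
            res, chosen = res2, "two_component"
            flags.append("auto: two-component model selected")

    c_fcs = concentration_from_N(res.N, fv)
    if chosen == "two_component":
        amplitudes = {"fast": float(res.amplitudes[0]), "slow": float(res.amplitudes[1])}
        d_fast = tau_to_diffusion(float(res.tau_ds_s[0]), fv)
        kd, no_tet = None, False
    else:
        amplitudes = {
            "dimer": float(res.amplitudes[0]),
            "tetramer": float(res.amplitudes[1]),
            "slow": float(res.amplitudes[2]),
        }
        d_fast = tau_to_diffusion(float(res.tau_ds_s[0]), fv)
        kd = compute_KD(c_fcs, p, amplitudes["dimer"], amplitudes["tetramer"])
        no_tet = kd is None
    if amplitudes.get("slow", 0.0) > slow_amplitude_flag:
        flags.append("low-information: slow fraction dominates")
    if p > 0.5 and chosen == "three_component_fixed":
        flags.append("excess-untagged assumption questionable: p > 0.5")
    flags.extend(res.warnings)
    return CellAnalysis(
        cell_id=cell_id, C_FCS_nM=c_fcs, p=p, amplitudes=amplitudes,
        K_D_uM=kd, no_tetramer=no_tet, D_fast_um2s=d_fast,
        protocol=chosen, flags=flags, fit=res,
    )


@dataclass
class PopulationSummary:
    """Population statistics of per-cell K_D values and amplitudes."""

    n_cells: int
    kd_mean_uM: float
    kd_sd_uM: float
    kd_percentiles_uM: tuple[float, float, float]  # 25 / 50 / 75
    kd_concentration_spearman_r: float
    kd_concentration_spearman_p: float
    amplitude_means: dict[str, float]
    amplitude_sds: dict[str, float]

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        q25, q50, q75 = self.kd_percentiles_uM
        if not (q25 <= q50 <= q75):
            raise ValueError("percentiles must be ordered")


def population_summary(cells: Sequence[CellAnalysis]) -> PopulationSummary:
    """Summarize a cell population: K_D statistics and the expression test.

    The Spearman rank correlation of K_D against C_FCS probes whether the
    apparent dissociation constant tracks expression level — at
    equilibrium it must not (a significant correlation indicates a
    violated assumption, e.g. non-equilibrium or brightness artefacts).
    """
    defined = [c for c in cells if c.K_D_uM is not None]
    if not defined:
        raise ValueError("need at least one cell with a defined K_D")
    kd = np.array([c.K_D_uM for c in defined])
    conc = np.array([c.C_FCS_nM for c in defined])
    if kd.size >= 3 and np.ptp(kd) > 0 and np.ptp(conc) > 0:
        rho, pval = stats.spearmanr(kd, conc)
    else:
        rho, pval = math.nan, math.nan
    keys = sorted({k for c in defined for k in c.amplitudes})
    amp_mean, amp_sd = {}, {}
    for k in keys:
        vals = np.array([c.amplitudes[k] for c in defined if k in c.amplitudes])
        amp_mean[k] = float(vals.mean())
        amp_sd[k] = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
    q25, q50, q75 = np.percentile(kd, [25, 50, 75])
    return PopulationSummary(
        n_cells=len(defined),
        kd_mean_uM=float(kd.mean()),
        kd_sd_uM=float(kd.std(ddof=1)) if kd.size > 1 else 0.0,
        kd_percentiles_uM=(float(q25), float(q50), float(q75)),
        kd_concentration_spearman_r=float(rho),
        kd_concentration_spearman_p=float(pval),
        amplitude_means=amp_mean,
        amplitude_sds=amp_sd,
    )
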