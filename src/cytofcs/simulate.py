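"""Brownian-dynamics FCS simulator and synthetic-data generators.

Ground-truth engine for the whole pipeline: point particles diffuse in a
periodic cube, a 3D-Gaussian detection profile (the same geometry the
analytical model assumes) converts positions to an intensity expectation,
and photon counts are drawn as Poisson variates per time bin.  A standard
multi-tau correlator turns traces into autocorrelation curves, so the
full chain simulate -> correlate -> fit can be validated against known
inputs.

Also here: a fast analytic fixture generator (model curve + seeded noise),
the dimer<->tetramer mass-action equilibrium solver, a per-cell population
generator for K_D-recovery studies, and the end-to-end wild-type mixture
experiment (three species, three-component fixed-time refit).

Performance note: the displacement/detection loop is compiled with numba.
Species with small D may internally take time steps that are an integer
multiple of the base ``dt`` — the largest multiple that still keeps the
per-step RMS displacement below w_xy/10 for that species — which changes
nothing statistically at the lags the correlator can resolve but keeps
minute-long traces tractable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from numba import njit

from .acf import (
    ACFComponentSpec,
    ACFFitResult,
    ACFModelSpec,
    AutocorrelationCurve,
    FocalVolume,
    diffusion_to_tau,
    fit_acf,
    model_acf,
)


# --------------------------------------------------------------------------
# configuration containers


@dataclass(frozen=True)
class SpeciesSpec:
    """One simulated species: mobility, copy number, photophysics."""

    name: str
    D_um2s: float
    count: int
    brightness_cps: float
    blinking: dict | None = None  # {"dark_fraction": f, "dark_dwell_s": t}

    def __post_init__(self) -> None:
        if self.D_um2s <= 0:
            raise ValueError("D must be positive")
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.brightness_cps < 0:
            raise ValueError("brightness must be >= 0")
        if self.blinking is not None:
            f = self.blinking.get("dark_fraction")
            t = self.blinking.get("dark_dwell_s")
            if not (0 < f < 1) or not (t > 0):
                raise ValueError("blinking needs 0 < dark_fraction < 1 and dark_dwell_s > 0")


@dataclass(frozen=True)
class SimulationConfig:
    """Full specification of one trace simulation (the embedded ground truth)."""

    species: tuple[SpeciesSpec, ...]
    w_xy_um: float = 0.3
    kappa: float = 5.0
    box_edge_um: float | None = None      # None -> 10 * kappa * w_xy
    dt_s: float = 1e-6
    duration_s: float = 10.0
    bin_time_s: float = 2e-6
    background_cps: float = 0.0
    seed: int = 0
    adaptive_species_dt: bool = True
    far_field_accel: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        box = self.box_edge_um if self.box_edge_um is not None else 10.0 * self.kappa * self.w_xy_um
        object.__setattr__(self, "box_edge_um", float(box))
        self.validate()

    def validate(self) -> None:
        if not self.species:
            raise ValueError("at least one species required")
        if self.w_xy_um <= 0 or self.kappa <= 1:
            raise ValueError("need w_xy > 0 and kappa > 1")
        if self.box_edge_um < 10.0 * self.kappa * self.w_xy_um - 1e-12:
            raise ValueError("box_edge must be >= 10 * kappa * w_xy")
        d_max = max(s.D_um2s for s in self.species)
        if math.sqrt(2.0 * d_max * self.dt_s) > self.w_xy_um / 10.0 + 1e-15:
            raise ValueError(
                "dt too coarse: per-step RMS displacement must be <= w_xy/10 for the "
                f"fastest species (D={d_max} um^2/s)"
            )
        if self.bin_time_s < self.dt_s:
            raise ValueError("bin_time must be >= dt")
        if abs(self.bin_time_s / self.dt_s - round(self.bin_time_s / self.dt_s)) > 1e-9:
            raise ValueError("bin_time must be an integer multiple of dt")
        if self.duration_s < self.bin_time_s:
            raise ValueError("duration must cover at least one bin")
        if self.background_cps < 0:
            raise ValueError("background must be >= 0")
        if self.seed is None:
            raise ValueError("seed must be explicit")

    @property
    def n_bins(self) -> int:
        return int(self.duration_s / self.bin_time_s)

    @property
    def w_z_um(self) -> float:
        return self.kappa * self.w_xy_um

    @property
    def focal_volume(self) -> FocalVolume:
        return FocalVolume(w_xy_um=self.w_xy_um, kappa=self.kappa)


@dataclass
class PhotonTrace:
    """Binned photon-count record plus the configuration that generated it."""

    bin_time_s: float
    counts: np.ndarray
    ground_truth: SimulationConfig | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be integers")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.bin_time_s <= 0:
            raise ValueError("bin_time must be positive")

    @property
    def duration_s(self) -> float:
        return self.counts.size * self.bin_time_s

    @property
    def mean_rate_cps(self) -> float:
        return float(self.counts.mean()) / self.bin_time_s


# --------------------------------------------------------------------------
# fast in-kernel RNG: xoshiro256+ uniforms, ziggurat normals
#
# The displacement loop draws ~1e9 Gaussian variates per minute-long trace;
# a ziggurat sampler over a xoshiro256+ stream is several times faster than
# the library generator inside the jitted loop.  Tables are built once at
# import (classic 128-layer Marsaglia-Tsang construction) and validated by
# the statistical tests of the simulator (moments, single-species ACF).


def _build_ziggurat_tables():
    m1 = 2147483648.0  # 2^31
    vn = 9.91256303526217e-3
    dn = 3.442619855899
    tn = dn
    q = vn / math.exp(-0.5 * dn * dn)
    kn = np.empty(128, dtype=np.uint32)
    wn = np.empty(128, dtype=np.float64)
    fn = np.empty(128, dtype=np.float64)
    kn[0] = np.uint32((dn / q) * m1)
    kn[1] = 0
    wn[0] = q / m1
    wn[127] = dn / m1
    fn[0] = 1.0
    fn[127] = math.exp(-0.5 * dn * dn)
    for i in range(126, 0, -1):
        dn = math.sqrt(-2.0 * math.log(vn / dn + math.exp(-0.5 * dn * dn)))
        kn[i + 1] = np.uint32((dn / tn) * m1)
        tn = dn
        fn[i] = math.exp(-0.5 * dn * dn)
        wn[i] = dn / m1
    return kn, wn, fn


_ZIG_KN, _ZIG_WN, _ZIG_FN = _build_ziggurat_tables()
_ZIG_R = 3.442619855899


@njit(cache=True, fastmath=True)
def _xoshiro_next(s):
    """xoshiro256+ step; s is a uint64[4] state array (mutated in place)."""
    result = s[0] + s[3]
    t = s[1] << np.uint64(17)
    s[2] ^= s[0]
    s[3] ^= s[1]
    s[1] ^= s[2]
    s[0] ^= s[3]
    s[2] ^= t
    s[3] = (s[3] << np.uint64(45)) | (s[3] >> np.uint64(19))
    return result


@njit(cache=True, fastmath=True)
def _seed_state(seed):
    """Expand a 64-bit seed into a xoshiro256 state via splitmix64."""
    s = np.empty(4, dtype=np.uint64)
    z = np.uint64(seed)
    for i in range(4):
        z = z + np.uint64(0x9E3779B97F4A7C15)
        t = z
        t = (t ^ (t >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        t = (t ^ (t >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        s[i] = t ^ (t >> np.uint64(31))
    return s


@njit(cache=True, fastmath=True)
def _rng_uniform(s):
    return (_xoshiro_next(s) >> np.uint64(11)) * 1.1102230246251565e-16  # 2^-53


@njit(cache=True, fastmath=True)
def _rng_normal(s, kn, wn, fn):
    """Standard normal via the 128-layer ziggurat (Marsaglia-Tsang)."""
    while True:
        u = _xoshiro_next(s)
        hz = np.int32(u & np.uint64(0xFFFFFFFF))
        iz = np.int64(hz & np.int32(127))
        if np.uint32(abs(np.int64(hz))) < kn[iz]:
            return hz * wn[iz]
        # slow path: tail or wedge
        if iz == 0:
            while True:
                x = -math.log(_rng_uniform(s) + 1e-300) / _ZIG_R
                y = -math.log(_rng_uniform(s) + 1e-300)
                if y + y >= x * x:
                    break
            return _ZIG_R + x if hz > 0 else -(_ZIG_R + x)
        x = hz * wn[iz]
        if fn[iz] + _rng_uniform(s) * (fn[iz - 1] - fn[iz]) < math.exp(-0.5 * x * x):
            return x


# --------------------------------------------------------------------------
# Brownian-dynamics kernel


@njit(cache=True, fastmath=True)
def _bd_psf_sum(nsteps, npart, sigma, box, w_xy, inv_kappa2, seed,
                blink, pi_bright, rate_sum_dt, farfield):
    """Per-step sum over particles of the 3D-Gaussian detection weight.

    Positions start uniform in the cube, move by Gaussian increments of SD
    ``sigma`` per axis per base step, with periodic wrapping.  In the
    scaled radial coordinate u^2 = x^2 + y^2 + z^2/kappa^2 the detection
    weight is exactly exp(-2 u^2 / w_xy^2), so a particle beyond
    u_near = 2.2 w_xy contributes < 1e-4 and need not be observed every
    step: when ``farfield`` is set, such particles take a single Gaussian
    jump of m base steps, with m chosen so that five jump-SDs stay short
    of u_near (the jump cannot reach the detection region undetected).
    Coarse jumps are exact Brownian increments, so entry statistics into
    the near region are preserved.

    Blinking (two-state bright/dark telegraph) is propagated with the
    exact finite-time transition probability over any step size.
    Returns W[t] = sum over bright particles of the detection weight.
    """
    rs = _seed_state(seed)
    kn, wn, fn = _ZIG_KN, _ZIG_WN, _ZIG_FN
    half = 0.5 * box
    u_near = 2.2 * w_xy  # detection weight < 1e-4 beyond this scaled radius
    u_near2 = u_near * u_near
    inv25s2 = 1.0 / (25.0 * sigma * sigma)
    inv_w2 = 1.0 / (w_xy * w_xy)
    m_cap = int((half * half) * inv25s2) + 1
    out = np.zeros(nsteps)
    for i in range(npart):
        x = (_rng_uniform(rs) - 0.5) * box
        y = (_rng_uniform(rs) - 0.5) * box
        z = (_rng_uniform(rs) - 0.5) * box
        bright = 1
        if blink and _rng_uniform(rs) < 1.0 - pi_bright:
            bright = 0
        t = 0
        while t < nsteps:
            u2 = x * x + y * y + z * z * inv_kappa2
            m = 1
            if u2 < u_near2:
                if bright == 1:
                    out[t] += np.exp(-2.0 * u2 * inv_w2)
            elif farfield:
                du = np.sqrt(u2) - u_near
                mf = du * du * inv25s2
                if mf >= 2.0:
                    m = int(mf)
                    if m > m_cap:
                        m = m_cap
                    if m > nsteps - t:
                        m = nsteps - t
            s = sigma * np.sqrt(m) if m > 1 else sigma
            x += s * _rng_normal(rs, kn, wn, fn)
            y += s * _rng_normal(rs, kn, wn, fn)
            z += s * _rng_normal(rs, kn, wn, fn)
            if x > half:
                x -= box
            elif x < -half:
                x += box
            if y > half:
                y -= box
            elif y < -half:
                y += box
            if z > half:
                z -= box
            elif z < -half:
                z += box
            if blink:
                decay = np.exp(-rate_sum_dt * m)
                p_bright = pi_bright + (bright - pi_bright) * decay
                bright = 1 if _rng_uniform(rs) < p_bright else 0
            t += m
    return out


def _species_step_multiple(config: SimulationConfig, D: float) -> int:
    """Largest integer m with sqrt(2 D m dt) <= w_xy/10 (>= 1)."""
    if not config.adaptive_species_dt:
        return 1
    m = int(config.w_xy_um**2 / (200.0 * D * config.dt_s))
    return max(1, m)


def simulate_trace(config: SimulationConfig) -> PhotonTrace:
    """Simulate one binned photon-count trace; fully reproducible from the seed."""
    config.validate()
    n_dt = int(round(config.duration_s / config.dt_s))
    inv_kappa2 = 1.0 / config.kappa**2

    ss = np.random.SeedSequence(config.seed)
    kernel_seeds = ss.generate_state(len(config.species) + 1)

    lam = np.zeros(n_dt)  # expected rate [cps] on the dt grid
    for s_idx, sp in enumerate(config.species):
        if sp.count == 0 or sp.brightness_cps == 0.0:
            continue
        m = _species_step_multiple(config, sp.D_um2s)
        dt_s = m * config.dt_s
        nsteps = (n_dt + m - 1) // m
        sigma = math.sqrt(2.0 * sp.D_um2s * dt_s)
        if sp.blinking is not None:
            f = sp.blinking["dark_fraction"]
            t_dark = sp.blinking["dark_dwell_s"]
            t_bright = t_dark * (1.0 - f) / f
            blink, pi_b = True, 1.0 - f
            rate_sum_dt = dt_s * (1.0 / t_bright + 1.0 / t_dark)
        else:
            blink, pi_b, rate_sum_dt = False, 1.0, 0.0
        w = _bd_psf_sum(
            nsteps, sp.count, sigma, config.box_edge_um, config.w_xy_um, inv_kappa2,
            int(kernel_seeds[s_idx] % (2**31 - 1)), blink, pi_b, rate_sum_dt,
            config.far_field_accel,
        )
        lam += sp.brightness_cps * np.repeat(w, m)[:n_dt]

    lam += config.background_cps
    per_bin = int(round(config.bin_time_s / config.dt_s))
    n_bins = n_dt // per_bin
    expected = lam[: n_bins * per_bin].reshape(n_bins, per_bin).sum(axis=1) * config.dt_s
    rng = np.random.default_rng(kernel_seeds[-1])
    counts = rng.poisson(expected).astype(np.int64)
    return PhotonTrace(bin_time_s=config.bin_time_s, counts=counts, ground_truth=config)


# --------------------------------------------------------------------------
# multi-tau correlator


def multitau_autocorrelate(trace: PhotonTrace, m: int = 16) -> AutocorrelationCurve:
    """Multi-tau autocorrelation with symmetric normalization.

    Standard progressive-binning estimator: the first 2m lags at the native
    bin time, then m lags per octave on a signal binned by 2 at each level.
    G(tau) = <dI(t) dI(t+tau)> / <I>^2 computed as
    mean(I_t I_{t+k}) / (mean_left * mean_right) - 1, where the two means
    run over the left/right windows actually entering the product
    (symmetric normalization, which removes the linear bias from finite
    traces).  Shot noise does not bias any lag k >= 1.
    """
    if m < 2:
        raise ValueError("m must be >= 2")
    x = np.asarray(trace.counts, dtype=float)
    if x.size < 4 * m:
        raise ValueError(f"trace too short for multi-tau with m={m}: {x.size} bins")
    lags: list[float] = []
    g: list[float] = []
    binwidth = trace.bin_time_s
    level = 0
    while True:
        n = x.size
        ks = range(1, 2 * m + 1) if level == 0 else range(m + 1, 2 * m + 1)
        advanced = False
        for k in ks:
            if n - k < 2 * m:
                break
            left = x[: n - k]
            right = x[k:]
            ml = left.mean()
            mr = right.mean()
            if ml == 0.0 or mr == 0.0:
                continue
            lags.append(k * binwidth)
            g.append(float(np.mean(left * right) / (ml * mr) - 1.0))
            advanced = True
        if not advanced or x.size // 2 < 4 * m:
            break
        x = 0.5 * (x[: (x.size // 2) * 2 : 2] + x[1 : (x.size // 2) * 2 : 2])
        binwidth *= 2.0
        level += 1
    meta = {"estimator": "multitau", "m": m, "bin_time_s": trace.bin_time_s}
    if trace.ground_truth is not None:
        meta["ground_truth"] = trace.ground_truth
    return AutocorrelationCurve(lags=np.array(lags), G=np.array(g), meta=meta)


# --------------------------------------------------------------------------
# fast analytic fixtures


def multitau_lag_grid(bin_time_s: float = 2e-6, n_octaves: int = 22, m: int = 16) -> np.ndarray:
    """Quasi-logarithmic lag grid mimicking the multi-tau layout."""
    lags = [k * bin_time_s for k in range(1, 2 * m + 1)]
    width = bin_time_s
    for _ in range(n_octaves):
        width *= 2.0
        lags.extend(k * width for k in range(m + 1, 2 * m + 1))
    return np.asarray(lags)


def analytic_curve_with_noise(
    spec: ACFModelSpec,
    N: float,
    noise_sd,
    seed: int,
    values: dict | None = None,
    lags: np.ndarray | None = None,
) -> AutocorrelationCurve:
    """Model curve on a multi-tau-style grid plus seeded Gaussian noise.

    ``noise_sd`` is either a scalar — interpreted as an absolute SD in
    units of G(0), applied uniformly — or an array of per-lag SDs
    (heteroscedastic).  The generating truth is embedded in ``meta``.
    """
    if lags is None:
        lags = multitau_lag_grid()
    g_true = model_acf(lags, spec, N, values)
    g0 = g_true[0]
    sd = np.asarray(noise_sd, dtype=float)
    if sd.ndim == 0:
        sd = np.full_like(g_true, float(sd) * g0)
    elif sd.shape != g_true.shape:
        raise ValueError("per-lag noise_sd must match the lag grid")
    rng = np.random.default_rng(seed)
    g = g_true + rng.normal(0.0, 1.0, size=g_true.shape) * sd
    weights = np.where(sd > 0, 1.0 / np.maximum(sd, 1e-300) ** 2, 0.0)
    return AutocorrelationCurve(
        lags=lags, G=g, weights=weights if np.any(sd > 0) else None,
        meta={"truth": {"spec": spec, "N": N, "values": values}, "seed": seed},
    )


# --------------------------------------------------------------------------
# population generator (mass-action equilibrium)


def dimer_tetramer_equilibrium(total_subunit_uM: float, kd_uM: float) -> tuple[float, float]:
    """Solve 2 dimer <-> tetramer mass action at fixed K_D.

    Given the total subunit concentration S = 2[dimer] + 4[tetramer] [uM]
    and K_D = [dimer]^2/[tetramer] [uM], returns ([dimer], [tetramer]) in
    uM from the positive root of the quadratic.
    """
    if total_subunit_uM <= 0 or kd_uM <= 0:
        raise ValueError("concentrations and K_D must be positive")
    s, k = total_subunit_uM, kd_uM
    d = 0.25 * k * (math.sqrt(1.0 + 4.0 * s / k) - 1.0)
    t = d * d / k
    return d, t


def simulate_cell_population(
    true_kd_uM: float,
    n_cells: int,
    seed: int,
    expression_lognorm: tuple[float, float] = (math.log(2.0), 0.7),
    p_tagged: float = 0.1,
    amplitude_noise_sd: tuple[float, float] = (0.09, 0.05),
    slow_fraction: float = 0.5,
):
    """Generate per-cell (C_FCS, amplitudes) for K_D-recovery studies.

    Per cell: the total Drp1 subunit concentration is drawn log-normally
    (``expression_lognorm`` = (mu, sigma) of ln(S/uM)); the dimer<->tetramer
    equilibrium is solved at ``true_kd_uM``; a slow/bound pool holding
    ``slow_fraction`` of detected oligomers is added; with one fluorescent
    subunit per detected oligomer, FCS amplitudes equal number fractions
    and the detected fluorescent-molecule concentration is
    C_FCS = p * (dimer + tetramer + slow).  Truncated (non-negative)
    Gaussian noise with SDs ``amplitude_noise_sd`` is then added to the
    dimer/tetramer amplitudes.  At zero noise, Eq.-style back-computation
    (C_FCS/p) * A_dimer^2 / A_tetramer returns ``true_kd_uM`` exactly.

    Returns a pandas DataFrame with columns cell_id, C_FCS_nM, p,
    A_dimer, A_tetramer, A_slow, plus the noise-free truth columns.
    """
    import pandas as pd

    if true_kd_uM <= 0:
        raise ValueError("true_kd_uM must be positive")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if not (0 < p_tagged <= 1):
        raise ValueError("p_tagged must lie in (0, 1]")
    if not (0 <= slow_fraction < 1):
        raise ValueError("slow_fraction must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    mu, sg = expression_lognorm
    rows = []
    for i in range(n_cells):
        s_tot = float(np.exp(rng.normal(mu, sg)))
        d, t = dimer_tetramer_equilibrium(s_tot, true_kd_uM)
        cyto = d + t
        slow = slow_fraction / (1.0 - slow_fraction) * cyto
        total = cyto + slow
        a_d_true, a_t_true, a_s_true = d / total, t / total, slow / total
        c_fcs_nM = p_tagged * total * 1e3  # uM -> nM

        def trunc_normal(mean, sd):
            if sd == 0:
                return mean
            while True:
                v = rng.normal(mean, sd)
                if v > 0:
                    return v

        a_d = trunc_normal(a_d_true, amplitude_noise_sd[0])
        a_t = trunc_normal(a_t_true, amplitude_noise_sd[1])
        rows.append({
            "cell_id": f"cell{i:03d}",
            "C_FCS_nM": c_fcs_nM,
            "p": p_tagged,
            "A_dimer": a_d,
            "A_tetramer": a_t,
            "A_slow": max(1.0 - a_d - a_t, 0.0),
            "A_dimer_true": a_d_true,
            "A_tetramer_true": a_t_true,
            "A_slow_true": a_s_true,
            "total_subunit_uM": s_tot,
        })
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# end-to-end wild-type experiment


@dataclass
class WildtypeSimResult:
    """Replicated simulate -> correlate -> fixed-time-refit experiment."""

    curves: list[AutocorrelationCurve]
    fits: list[ACFFitResult]
    amplitude_mean: np.ndarray   # (dimer, tetramer, slow)
    amplitude_sd: np.ndarray
    configs: list[SimulationConfig] = field(default_factory=list)


def simulate_wildtype_experiment(
    fractions: Sequence[float] = (0.34, 0.15, 0.51),
    D_um2s: Sequence[float] = (9.1, 5.7, 0.5),
    fv: FocalVolume | None = None,
    duration_s: float = 60.0,
    n_replicates: int = 10,
    seed: int = 0,
    n_particles: int = 45000,
    brightness_cps: float = 1e5,
    dt_s: float = 4e-5,
    bin_time_s: float = 4e-5,
    m: int = 16,
    fit_max_lag_s: float = 0.5,
    slow_tau_bounds_s: tuple[float, float] = (5e-3, 2.0),
) -> WildtypeSimResult:
    """Simulate the three-species cytosolic mixture and refit it.

    Particles are split across (dimer, tetramer, slow) species according
    to ``fractions`` (equal brightness, one label per oligomer), traces of
    ``duration_s`` are simulated per replicate, correlated, and fitted
    with the three-component model in which the dimer and tetramer
    diffusion times are fixed from the input D values via
    tau = w_xy^2/(4 D) while all amplitudes and the slow time stay free
    (the slow time bounded to the physically sensible ms-to-s window).
    Blinking is neither simulated nor fitted.

    The default particle number puts ~10 fluorescent molecules in the
    effective volume — the occupancy of the cell measurements this
    experiment emulates.  Lags beyond ``fit_max_lag_s`` carry almost no
    averaging at 60 s and are excluded from the fit.

    Returns per-replicate curves/fits plus the mean and SD of the fitted
    (dimer, tetramer, slow) amplitudes across replicates.
    """
    fractions = np.asarray(fractions, dtype=float)
    if fractions.ndim != 1 or fractions.size != len(D_um2s):
        raise ValueError("fractions and D_um2s must have equal length")
    if abs(fractions.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if fv is None:
        fv = FocalVolume(w_xy_um=0.3, kappa=5.0)

    counts = np.floor(fractions * n_particles).astype(int)
    # distribute the rounding remainder to the largest fractional parts
    rem = n_particles - counts.sum()
    order = np.argsort(-(fractions * n_particles - counts))
    counts[order[:rem]] += 1

    names = ["dimer", "tetramer", "slow"][: len(D_um2s)]
    species = tuple(
        SpeciesSpec(name=nm, D_um2s=float(d), count=int(c), brightness_cps=brightness_cps)
        for nm, d, c in zip(names, D_um2s, counts)
    )
    base = SimulationConfig(
        species=species, w_xy_um=fv.w_xy_um, kappa=fv.kappa,
        dt_s=dt_s, bin_time_s=bin_time_s, duration_s=duration_s, seed=seed,
    )
    spec = ACFModelSpec(
        components=tuple(
            [ACFComponentSpec(tau_d_s=diffusion_to_tau(float(D_um2s[i]), fv))
             for i in range(len(D_um2s) - 1)]
            + [ACFComponentSpec(tau_d_init=diffusion_to_tau(float(D_um2s[-1]), fv),
                                tau_d_bounds_s=slow_tau_bounds_s)]
        ),
        kappa=fv.kappa,
    )
    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.generate_state(n_replicates)
    curves, fits, configs = [], [], []
    for r in range(n_replicates):
        cfg = replace(base, seed=int(rep_seeds[r] % (2**31 - 1)))
        trace = simulate_trace(cfg)
        curve = multitau_autocorrelate(trace, m=m)
        keep = curve.lags <= fit_max_lag_s
        fit_curve = AutocorrelationCurve(curve.lags[keep], curve.G[keep], meta=curve.meta)
        fits.append(fit_acf(fit_curve, spec))
        curves.append(curve)
        configs.append(cfg)
    amps = np.array([f.amplitudes for f in fits])
    return WildtypeSimResult(
        curves=curves, fits=fits,
        amplitude_mean=amps.mean(axis=0), amplitude_sd=amps.std(axis=0, ddof=1),
        configs=configs,
    )
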