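"""FCS autocorrelation curves: model, fitting, calibration, conversions.

The autocorrelation of the fluorescence intensity from a 3D-Gaussian
confocal volume containing n diffusing species is modelled as

    G(tau) = (1/N) sum_i A_i [1 + (tau/tau_Di)^alpha_i]^-1
                         [1 + (tau/tau_Di)^alpha_i / kappa^2]^-1/2

optionally multiplied by a fast blinking (triplet) factor
``1 + f_T/(1-f_T) exp(-tau/tau_T)``.  N is the mean number of fluorescent
molecules in the effective volume, A_i are component amplitudes
(normalized to sum to 1, proportional to relative concentrations for
equally bright species), tau_Di the diffusion times, kappa = w_z/w_xy the
focal-volume aspect ratio, and alpha_i an anomalous exponent (1 for
normal diffusion).

Fitting is done by ``MultiComponentACFModel``, a scikit-learn style
estimator over lmfit; every amplitude/time/exponent can be declared free,
fixed, or bounded through :class:`ACFModelSpec`.  Internally amplitudes
are parameterized so that they sum to exactly 1, with the overall scale
absorbed into N.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import lmfit
import numpy as np
from sklearn.base import BaseEstimator

from .constants import N_A
from .errors import CalibrationError, FitConvergenceError


# --------------------------------------------------------------------------
# containers


@dataclass
class AutocorrelationCurve:
    """One FCS curve: lag times [s], G values, optional inverse-variance weights."""

    lags: np.ndarray
    G: np.ndarray
    weights: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lags.ndim != 1 or self.lags.shape != self.G.shape:
            raise ValueError("lags and G must be 1-D arrays of equal length")
        if np.any(self.lags <= 0):
            raise ValueError("lag times must be positive")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lag times must be strictly increasing")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.lags.shape or np.any(self.weights < 0):
                raise ValueError("weights must be non-negative, same length as lags")

    def __len__(self) -> int:
        return self.lags.size


@dataclass(frozen=True)
class ACFComponentSpec:
    """One diffusive component: each parameter is free (None) or fixed (value).

    ``alpha`` defaults to fixed normal diffusion (1.0); set to ``None`` to
    free the anomalous exponent in (0, 1].  ``tau_d_init`` seeds free
    diffusion times (None -> heuristic from the lag grid).
    """

    amplitude: float | None = None
    tau_d_s: float | None = None
    alpha: float | None = 1.0
    tau_d_init: float | None = None
    tau_d_bounds_s: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.amplitude is not None and not (0.0 <= self.amplitude <= 1.0):
            raise ValueError("fixed amplitude must lie in [0, 1]")
        if self.tau_d_s is not None and self.tau_d_s <= 0:
            raise ValueError("fixed tau_D must be positive")
        if self.alpha is not None and not (0.0 < self.alpha <= 1.0):
            raise ValueError("alpha must lie in (0, 1]")
        if self.tau_d_bounds_s is not None:
            lo, hi = self.tau_d_bounds_s
            if not (0 < lo < hi):
                raise ValueError("tau_D bounds must satisfy 0 < lo < hi")
            if self.tau_d_s is not None and not (lo <= self.tau_d_s <= hi):
                raise ValueError("fixed tau_D outside its bounds")


@dataclass(frozen=True)
class TripletSpec:
    """Blinking term: fraction free in [0, 1), tau_T bounded (Methods default 0.1-0.3 ms)."""

    fraction: float | None = None
    tau_s: float | None = None
    tau_bounds_s: tuple[float, float] = (1e-4, 3e-4)
    fraction_init: float = 0.1

    def __post_init__(self) -> None:
        lo, hi = self.tau_bounds_s
        if not (0 < lo < hi):
            raise ValueError("triplet tau bounds must satisfy 0 < lo < hi")
        if self.fraction is not None and not (0.0 <= self.fraction < 1.0):
            raise ValueError("triplet fraction must lie in [0, 1)")
        if self.tau_s is not None and not (lo <= self.tau_s <= hi):
            raise ValueError("fixed triplet tau outside its bounds")


@dataclass(frozen=True)
class ACFModelSpec:
    """Declarative multi-component model: components + geometry + blinking."""

    components: tuple[ACFComponentSpec, ...]
    kappa: float = 5.0
    triplet: TripletSpec | None = None
    kappa_vary: bool = False  # freed only during focal-volume calibration

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        if len(self.components) < 1:
            raise ValueError("need at least one component")
        if self.kappa <= 1.0:
            raise ValueError("kappa must exceed 1")

    @property
    def n_components(self) -> int:
        return len(self.components)


@dataclass
class ACFFitResult:
    """Outcome of a multi-component fit (fixed parameters pass through unchanged)."""

    N: float
    amplitudes: np.ndarray        # normalized, sum == 1
    tau_ds_s: np.ndarray
    alphas: np.ndarray
    kappa: float
    triplet_fraction: float | None
    triplet_tau_s: float | None
    stderr: dict[str, float]
    redchi: float
    residuals: np.ndarray
    success: bool
    message: str
    warnings: list[str] = field(default_factory=list)
    spec: ACFModelSpec | None = None

    def __post_init__(self) -> None:
        if self.N <= 0:
            raise ValueError("fitted N must be positive")
        if abs(float(np.sum(self.amplitudes)) - 1.0) > 1e-9:
            raise ValueError("amplitudes must sum to 1")


@dataclass(frozen=True)
class FocalVolume:
    """Calibrated confocal detection volume (3D Gaussian)."""

    w_xy_um: float
    kappa: float
    V_eff_fL: float | None = None

    def __post_init__(self) -> None:
        if self.w_xy_um <= 0:
            raise ValueError("w_xy must be positive")
        if self.kappa <= 1.0:
            raise ValueError("kappa must exceed 1")
        v = np.pi ** 1.5 * self.w_xy_um**3 * self.kappa  # um^3 == fL
        if self.V_eff_fL is None:
            object.__setattr__(self, "V_eff_fL", float(v))
        elif not np.isclose(self.V_eff_fL, v, rtol=1e-6):
            raise ValueError(
                f"V_eff inconsistent with pi^1.5 w^3 kappa: {self.V_eff_fL} vs {v}"
            )

    @property
    def w_z_um(self) -> float:
        return self.w_xy_um * self.kappa


# --------------------------------------------------------------------------
# model evaluation


def acf_components(lags, amplitudes, tau_ds_s, alphas, kappa):
    """Diffusive part of G(tau)*N: sum_i A_i / [(1+x_i) sqrt(1+x_i/kappa^2)]."""
    tau = np.asarray(lags, dtype=float)
    g = np.zeros_like(tau)
    for a_i, td, al in zip(amplitudes, tau_ds_s, alphas):
        x = (tau / td) ** al
        g += a_i / ((1.0 + x) * np.sqrt(1.0 + x / kappa**2))
    return g


def triplet_factor(lags, fraction: float, tau_s: float):
    """Multiplicative blinking factor 1 + f/(1-f) exp(-tau/tau_T)."""
    tau = np.asarray(lags, dtype=float)
    if fraction == 0.0:
        return np.ones_like(tau)
    return 1.0 + fraction / (1.0 - fraction) * np.exp(-tau / tau_s)


def model_acf(lags, spec: ACFModelSpec, N: float, values: dict | None = None):
    """Evaluate the multi-component model at ``lags`` for given parameter values.

    Free parameters in ``spec`` must be supplied through ``values`` with keys
    ``amp{i}``, ``tau{i}``, ``alpha{i}``, ``triplet_fraction``, ``triplet_tau``.
    Returns G(tau) including the blinking factor when enabled.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    values = values or {}

    def resolve(fixed, key, what):
        if fixed is not None:
            return fixed
        if key not in values:
            raise ValueError(f"{what} is free in the spec; supply values['{key}']")
        return values[key]

    amps, taus, alphas = [], [], []
    for i, c in enumerate(spec.components):
        amps.append(resolve(c.amplitude, f"amp{i}", f"amplitude of component {i}"))
        taus.append(resolve(c.tau_d_s, f"tau{i}", f"tau_D of component {i}"))
        alphas.append(resolve(c.alpha, f"alpha{i}", f"alpha of component {i}"))
    amps = np.asarray(amps, float)
    taus = np.asarray(taus, float)
    alphas = np.asarray(alphas, float)
    if np.any(amps < 0) or np.any(taus <= 0) or np.any(alphas <= 0) or np.any(alphas > 1):
        raise ValueError("parameter out of bounds (amplitudes >= 0, tau > 0, alpha in (0,1])")
    g = acf_components(lags, amps, taus, alphas, spec.kappa) / N
    if spec.triplet is not None:
        f = resolve(spec.triplet.fraction, "triplet_fraction", "triplet fraction")
        tt = resolve(spec.triplet.tau_s, "triplet_tau", "triplet tau")
        if not (0.0 <= f < 1.0):
            raise ValueError("triplet fraction out of [0, 1)")
        g = g * triplet_factor(lags, f, tt)
    return g


# --------------------------------------------------------------------------
# fitting


class MultiComponentACFModel(BaseEstimator):
    """Bounded least-squares fit of the multi-component FCS model.

    scikit-learn style: hyperparameters (the declarative ``spec`` and
    optional initial values) in the constructor, fitted quantities with a
    trailing underscore after :meth:`fit`.

    Amplitudes are parameterized as fractions summing to exactly 1, with
    the curve scale carried by ``G0 = 1/N``; fixed amplitudes/times are
    honored exactly, the fast-component amplitude bound [0, 1] and the
    triplet-time bounds (default 0.1-0.3 ms) are hard.

    Attributes
    ----------
    result_ : :class:`ACFFitResult`
    lmfit_result_ : the underlying :class:`lmfit.minimizer.MinimizerResult`
    """

    #: minimum number of lag points accepted by fit()
    MIN_POINTS = 30

    def __init__(self, spec: ACFModelSpec, init: dict | None = None, max_nfev: int = 20000):
        self.spec = spec
        self.init = init
        self.max_nfev = max_nfev

    # -- parameter construction -------------------------------------------------
    def _build_params(self, lags, G) -> lmfit.Parameters:
        spec = self.spec
        init = dict(self.init or {})
        n = spec.n_components
        p = lmfit.Parameters()
        g0_init = float(init.get("G0", max(G[: max(3, len(G) // 50)].mean(), 1e-6)))
        p.add("G0", value=max(g0_init, 1e-9), min=1e-12)

        fixed = [c.amplitude for c in spec.components]
        free_idx = [i for i, a in enumerate(fixed) if a is None]
        if free_idx:
            expr_i = free_idx[-1]  # one free fraction carries the sum-to-1 constraint
        else:
            if abs(sum(fixed) - 1.0) > 1e-9:
                raise ValueError("all amplitudes fixed but they do not sum to 1")
            expr_i = None
        default_free = None
        if free_idx:
            default_free = (1.0 - sum(a for a in fixed if a is not None)) / len(free_idx)
        # the sum-to-1 expression must be added after its operands exist
        for i, c in enumerate(spec.components):
            if c.amplitude is not None:
                p.add(f"f{i}", value=c.amplitude, vary=False)
            elif i != expr_i:
                p.add(f"f{i}", value=float(init.get(f"amp{i}", default_free)),
                      min=0.0, max=1.0)
        if expr_i is not None:
            others = " - ".join(f"f{j}" for j in range(n) if j != expr_i)
            p.add(f"f{expr_i}", expr=f"1 - {others}" if others else "1")

        lag_lo, lag_hi = float(lags[0]), float(lags[-1])
        for i, c in enumerate(spec.components):
            name = f"tau{i}"
            if c.tau_d_s is not None:
                p.add(name, value=c.tau_d_s, vary=False)
            else:
                t0 = init.get(f"tau{i}", c.tau_d_init)
                if t0 is None:
                    # spread free components across the lag decade range
                    t0 = np.exp(
                        np.log(lag_lo) + (i + 1) / (n + 1) * (np.log(lag_hi) - np.log(lag_lo))
                    )
                lo, hi = (c.tau_d_bounds_s if c.tau_d_bounds_s is not None
                          else (lag_lo / 100.0, lag_hi * 100.0))
                p.add(name, value=float(np.clip(t0, lo, hi)), min=lo, max=hi)
            aname = f"alpha{i}"
            if c.alpha is not None:
                p.add(aname, value=c.alpha, vary=False)
            else:
                p.add(aname, value=float(init.get(f"alpha{i}", 0.9)), min=1e-3, max=1.0)

        if spec.kappa_vary:
            p.add("kappa", value=spec.kappa, min=1.0 + 1e-6, max=20.0)
        else:
            p.add("kappa", value=spec.kappa, vary=False)

        if spec.triplet is not None:
            t = spec.triplet
            if t.fraction is not None:
                p.add("ftrip", value=t.fraction, vary=False)
            else:
                p.add("ftrip", value=float(init.get("triplet_fraction", t.fraction_init)),
                      min=0.0, max=1.0 - 1e-6)
            lo, hi = t.tau_bounds_s
            if t.tau_s is not None:
                p.add("tautrip", value=t.tau_s, vary=False)
            else:
                p.add("tautrip", value=float(init.get("triplet_tau", np.sqrt(lo * hi))),
                      min=lo, max=hi)
        return p

    def _eval(self, params: lmfit.Parameters, lags: np.ndarray) -> np.ndarray:
        n = self.spec.n_components
        amps = np.array([params[f"f{i}"].value for i in range(n)])
        taus = np.array([params[f"tau{i}"].value for i in range(n)])
        alphas = np.array([params[f"alpha{i}"].value for i in range(n)])
        g = params["G0"].value * acf_components(lags, amps, taus, alphas, params["kappa"].value)
        if self.spec.triplet is not None:
            g = g * triplet_factor(lags, params["ftrip"].value, params["tautrip"].value)
        return g

    def fit(self, X, y, sample_weight=None):
        """Fit to lag times ``X`` [s] and autocorrelation values ``y``."""
        lags = np.asarray(X, dtype=float).reshape(-1)
        G = np.asarray(y, dtype=float).reshape(-1)
        if lags.shape != G.shape:
            raise ValueError("lags and G must have equal length")
        if lags.size < self.MIN_POINTS:
            raise ValueError(f"need >= {self.MIN_POINTS} lag points; got {lags.size}")
        if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
            raise ValueError("lags must be positive and strictly increasing")
        w = None
        if sample_weight is not None:
            w = np.sqrt(np.asarray(sample_weight, dtype=float).reshape(-1))
            if w.shape != lags.shape or np.any(w < 0):
                raise ValueError("sample_weight must be non-negative, same length")

        params = self._build_params(lags, G)

        def resid(p):
            r = self._eval(p, lags) - G
            return r * w if w is not None else r

        # default-tolerance solve, then a tight polish from the solution;
        # keep the lower-cost result (the polish may hit the budget on
        # noise-free data where the cost floor is machine precision)
        out = lmfit.Minimizer(resid, params, max_nfev=self.max_nfev).minimize(
            method="least_squares")
        converged = bool(out.success)
        try:
            polish = lmfit.Minimizer(
                resid, out.params.copy(), max_nfev=self.max_nfev
            ).minimize(method="least_squares", ftol=1e-12, xtol=1e-12, gtol=1e-12)
        except Exception:
            polish = None
        if polish is not None and polish.chisqr <= out.chisqr:
            converged = converged or bool(polish.success)
            out = polish
        if not converged:
            raise FitConvergenceError(
                f"ACF fit failed: {out.message}",
                diagnostics={"nfev": out.nfev, "spec": self.spec},
            )

        n = self.spec.n_components
        warnings: list[str] = []
        amps = np.array([out.params[f"f{i}"].value for i in range(n)])
        if np.any(amps < -1e-9) or np.any(amps > 1 + 1e-9):
            warnings.append(f"amplitude left [0,1] via sum constraint: {amps}")
        amps = np.clip(amps, 0.0, None)
        s = amps.sum()
        g0 = out.params["G0"].value * s  # N absorbs any clip-induced rescale
        amps = amps / s
        taus = np.array([out.params[f"tau{i}"].value for i in range(n)])
        for i, c in enumerate(self.spec.components):
            if c.tau_d_s is not None and not (lags[0] <= c.tau_d_s <= lags[-1]):
                warnings.append(f"fixed tau_D of component {i} outside the lag range")
        alphas = np.array([out.params[f"alpha{i}"].value for i in range(n)])
        stderr = {
            k: float(v.stderr) for k, v in out.params.items()
            if v.vary and v.stderr is not None
        }
        self.result_ = ACFFitResult(
            N=1.0 / g0,
            amplitudes=amps,
            tau_ds_s=taus,
            alphas=alphas,
            kappa=float(out.params["kappa"].value),
            triplet_fraction=(float(out.params["ftrip"].value)
                              if self.spec.triplet is not None else None),
            triplet_tau_s=(float(out.params["tautrip"].value)
                           if self.spec.triplet is not None else None),
            stderr=stderr,
            redchi=float(out.redchi),
            residuals=np.asarray(out.residual),
            success=converged,
            message=str(out.message),
            warnings=warnings,
            spec=self.spec,
        )
        self.lmfit_result_ = out
        return self

    def predict(self, X):
        """Model curve at lags ``X`` using the fitted parameters."""
        if not hasattr(self, "lmfit_result_"):
            raise AttributeError("model is not fitted; call fit() first")
        return self._eval(self.lmfit_result_.params, np.asarray(X, float).reshape(-1))


def fit_acf(
    curve: AutocorrelationCurve,
    spec: ACFModelSpec,
    init: dict | None = None,
) -> ACFFitResult:
    """Fit ``spec`` to ``curve`` (thin wrapper over MultiComponentACFModel)."""
    est = MultiComponentACFModel(spec=spec, init=init)
    est.fit(curve.lags, curve.G, sample_weight=curve.weights)
    return est.result_


# --------------------------------------------------------------------------
# calibration and conversions


def calibrate_focal_volume(
    ref_curve: AutocorrelationCurve,
    D_ref_um2s: float,
    kappa_init: float = 5.0,
    triplet: bool = False,
    max_rel_residual: float = 0.05,
    max_redchi: float = 5.0,
) -> FocalVolume:
    """Calibrate the focal volume from a reference-dye curve of known D.

    Fits a one-component model with free tau_D and free kappa, then
    converts: w_xy = sqrt(4 D_ref tau_D), V_eff = pi^1.5 w_xy^3 kappa.
    Calibration is rejected (``CalibrationError``) when the single-component
    fit is poor: weighted reduced chi^2 above ``max_redchi`` when weights
    are present, otherwise RMS residual above ``max_rel_residual`` of G(0).
    """
    if D_ref_um2s <= 0:
        raise ValueError("reference diffusion coefficient must be positive")
    spec = ACFModelSpec(
        components=(ACFComponentSpec(amplitude=1.0),),
        kappa=kappa_init,
        kappa_vary=True,
        triplet=TripletSpec() if triplet else None,
    )
    res = fit_acf(ref_curve, spec)
    g0 = 1.0 / res.N
    if ref_curve.weights is not None and np.any(ref_curve.weights > 0):
        if res.redchi > max_redchi:
            raise CalibrationError(
                f"single-component fit rejected: reduced chi^2 {res.redchi:.2f} > {max_redchi}"
            )
    else:
        rel = float(np.sqrt(np.mean(res.residuals**2))) / g0
        if rel > max_rel_residual:
            raise CalibrationError(
                f"single-component fit rejected: RMS residual {rel:.3f} of G(0) "
                f"exceeds {max_rel_residual}"
            )
    tau_d = float(res.tau_ds_s[0])
    w_xy = float(np.sqrt(4.0 * D_ref_um2s * tau_d))  # um, since D um^2/s, tau s
    return FocalVolume(w_xy_um=w_xy, kappa=res.kappa)


def tau_to_diffusion(tau_d_s: float, fv: FocalVolume) -> float:
    """Diffusion coefficient [um^2/s] from a diffusion time: D = w_xy^2/(4 tau_D)."""
    if tau_d_s <= 0:
        raise ValueError("tau_D must be positive")
    return fv.w_xy_um**2 / (4.0 * tau_d_s)


def diffusion_to_tau(D_um2s: float, fv: FocalVolume) -> float:
    """Diffusion time [s] for a species of known D: tau_D = w_xy^2/(4 D)."""
    if D_um2s <= 0:
        raise ValueError("D must be positive")
    return fv.w_xy_um**2 / (4.0 * D_um2s)


def concentration_from_N(N: float, fv: FocalVolume) -> float:
    """Molar concentration [nM] of N molecules in the effective volume."""
    if N < 0:
        raise ValueError("N must be non-negative")
    v_L = fv.V_eff_fL * 1e-15
    return N / (N_A * v_L) * 1e9


def molecular_brightness(mean_intensity_cps: float, N: float) -> float:
    """Counts per molecule [counts/s/molecule]: mean intensity / N.

    The CPM statistic tests the equal-brightness assumption (one
    fluorophore per detected oligomer) that underlies amplitude-based
    concentration bookkeeping.
    """
    if N <= 0:
        raise ValueError("N must be positive")
    return mean_intensity_cps / N
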