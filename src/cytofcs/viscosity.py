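"""Length-scale-dependent effective viscosity of cytoplasm.

The cytoplasm is a structured, crowded fluid: the drag a probe feels grows
with its hydrodynamic radius r_p.  The model implemented here is

    eta_eff(r_p) = eta_0 * A * exp[ (xi^2/R_h^2 + xi^2/r_p^2)^(-a/2) ]

where eta_0 is a reference (buffer/water) viscosity, A is a preexponential
factor of order one, xi and R_h are length scales characteristic of the
cell type, and a < 1 is an exponent.  Small probes (r_p << xi) slip between
macromolecules and feel nearly the buffer viscosity; large probes approach
the macroscopic plateau A*exp[(xi/R_h)^(-a)].

Combined with the Stokes-Sutherland-Einstein relation D = k_B T/(6 pi
eta_eff r_p) the model predicts in-cell diffusion coefficients for any
probe size, which is what turns FCS diffusion times into oligomer sizes.

``LengthScaleViscosityModel`` is a scikit-learn style estimator: ``fit`` on
a tracer panel (radii vs measured D), ``predict`` diffusion coefficients at
new radii.  The module functions are thin wrappers usable without fitting.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import (
    DEFAULT_T_K,
    K_B,
    stokes_einstein_D,
    stokes_einstein_eta,
    water_viscosity,
)
from .errors import FitConvergenceError


@dataclass(frozen=True)
class ViscosityParams:
    """The rheological fingerprint of one cell type / condition.

    Attributes
    ----------
    A : dimensionless preexponential factor (> 0)
    xi_nm : length scale xi [nm] (> 0)
    Rh_nm : length scale R_h [nm] (> 0)
    a : exponent, 0 < a < 1
    eta0_pa_s : reference viscosity eta_0 [Pa*s]
    T_K : absolute temperature [K]
    """

    A: float
    xi_nm: float
    Rh_nm: float
    a: float
    eta0_pa_s: float = water_viscosity(DEFAULT_T_K)
    T_K: float = DEFAULT_T_K

    def __post_init__(self) -> None:
        if not (self.A > 0 and self.xi_nm > 0 and self.Rh_nm > 0):
            raise ValueError("A, xi_nm and Rh_nm must be positive")
        if not (0.0 < self.a < 1.0):
            raise ValueError(f"exponent a must lie in (0, 1); got {self.a}")
        if not (self.eta0_pa_s > 0 and self.T_K > 0):
            raise ValueError("eta0_pa_s and T_K must be positive")

    def replace(self, **kw) -> "ViscosityParams":
        return dataclasses.replace(self, **kw)


#: Fitted parameters for HeLa cytosol at 36 degC (reference buffer = water).
HELA_36C = ViscosityParams(A=1.3, xi_nm=3.16, Rh_nm=12.9, a=0.62)

#: One-sigma uncertainties of the HeLa 36 degC calibration (same field names).
HELA_36C_SIGMA = {"A": 0.3, "xi_nm": 0.14, "Rh_nm": 2.3, "a": 0.07}


@dataclass(frozen=True)
class TracerMeasurement:
    """One calibration tracer: hydrodynamic radius and its in-cell D."""

    r_p_nm: float
    D_um2s: float
    D_sd_um2s: float = 0.0
    n_cells: int = 1
    name: str = ""

    def __post_init__(self) -> None:
        if self.r_p_nm <= 0 or self.D_um2s <= 0:
            raise ValueError("r_p_nm and D_um2s must be positive")
        if self.D_sd_um2s < 0:
            raise ValueError("D_sd_um2s must be non-negative")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")


_FREE_NAMES = ("A", "xi_nm", "Rh_nm", "a")


@dataclass
class ParamErrorBand:
    """Point estimates plus one-sigma uncertainties for ViscosityParams."""

    params: ViscosityParams
    sigma: dict[str, float]
    covariance: np.ndarray | None = None  # over (A, xi_nm, Rh_nm, a)
    residuals: np.ndarray | None = None
    cost: float | None = None

    def __post_init__(self) -> None:
        for k, v in self.sigma.items():
            if v < 0:
                raise ValueError(f"uncertainty for {k} must be >= 0")
        if self.covariance is not None:
            c = np.asarray(self.covariance, float)
            if not np.allclose(c, c.T, atol=1e-8):
                raise ValueError("covariance must be symmetric")
            if np.any(np.linalg.eigvalsh((c + c.T) / 2) < -1e-8 * max(1.0, np.abs(c).max())):
                raise ValueError("covariance must be positive semidefinite")


def eta_eff_relative(r_p_nm, params: ViscosityParams):
    """Relative effective viscosity eta_eff/eta_0 at probe radius r_p [nm].

    Strictly increasing in r_p, bounded below by A (r_p -> 0) and above by
    A*exp[(xi^2/R_h^2)^(-a/2)] (r_p -> inf).
    """
    r = np.asarray(r_p_nm, dtype=float)
    if np.any(r <= 0):
        raise ValueError("probe radius must be positive")
    x = (params.xi_nm / params.Rh_nm) ** 2 + (params.xi_nm / r) ** 2
    out = params.A * np.exp(x ** (-params.a / 2.0))
    return float(out) if out.ndim == 0 else out


def eta_eff(r_p_nm, params: ViscosityParams):
    """Absolute effective viscosity [Pa*s] at probe radius r_p [nm]."""
    rel = eta_eff_relative(r_p_nm, params)
    return params.eta0_pa_s * rel


def predict_diffusion(r_p_nm, params: ViscosityParams):
    """In-cell diffusion coefficient [um^2/s] for a probe of radius r_p [nm].

    D = k_B T / (6 pi eta_eff(r_p) r_p); strictly decreasing in r_p.
    """
    return stokes_einstein_D(eta_eff(r_p_nm, params), r_p_nm, params.T_K)


def predict_diffusion_constant_viscosity(
    r_p_nm, rel_viscosity: float, eta0_pa_s: float | None = None, T_K: float = DEFAULT_T_K
):
    """Diffusion coefficient [um^2/s] assuming a size-independent viscosity.

    The naive alternative to the length-scale model: a single relative
    viscosity (e.g. the one probed by free EGFP) applied at every radius,
    so D scales exactly as 1/r_p.
    """
    if rel_viscosity <= 0:
        raise ValueError("relative viscosity must be positive")
    if eta0_pa_s is None:
        eta0_pa_s = water_viscosity(T_K)
    return stokes_einstein_D(rel_viscosity * eta0_pa_s, r_p_nm, T_K)


def viscosity_from_diffusion(D_um2s, r_p_nm, T_K: float = DEFAULT_T_K):
    """Effective viscosity [Pa*s] experienced by a probe of known radius.

    Exact inverse of :func:`predict_diffusion` at fixed radius: eta_eff =
    k_B T / (6 pi D r_p).  This is the step that turns a measured in-cell
    D into a point on the eta_eff(r_p) curve.
    """
    return stokes_einstein_eta(D_um2s, r_p_nm, T_K)


def total_differential_error(
    fn: Callable[[ViscosityParams], float],
    band: ParamErrorBand,
    rel_step: float = 1e-6,
    abs_floor: float = 1e-12,
) -> float:
    """Total-differential (worst-case linear) error of ``fn`` at the estimate.

    delta_f = sum_i |d fn / d p_i| * sigma_i with partials by central finite
    differences over the four free model parameters.  Parameters missing
    from ``band.sigma`` raise; sigma = 0 contributes nothing.
    """
    p0 = band.params
    missing = [n for n in _FREE_NAMES if n not in band.sigma]
    if missing:
        raise ValueError(f"missing uncertainties for {missing}")
    total = 0.0
    for name in _FREE_NAMES:
        sig = band.sigma[name]
        if sig == 0.0:
            continue
        v = getattr(p0, name)
        h = max(abs(v) * rel_step, abs_floor)
        hi = p0.replace(**{name: v + h})
        lo = p0.replace(**{name: v - h})
        deriv = (fn(hi) - fn(lo)) / (2.0 * h)
        total += abs(deriv) * sig
    return total


class LengthScaleViscosityModel(RegressorMixin, BaseEstimator):
    """Fit the length-scale viscosity model to a tracer panel.

    The estimator regresses measured in-cell diffusion coefficients
    (``y``, [um^2/s]) on probe hydrodynamic radii (``X``, [nm]).  The fit
    is performed on ln(eta_eff/eta_0) — which linearizes the exponential
    and stabilizes the large-radius plateau — using bounded nonlinear
    least squares with a seeded multi-start to escape the xi/R_h/a
    degeneracy.

    Parameters
    ----------
    eta0_pa_s : reference viscosity [Pa*s]; ``None`` -> pure water at T_K.
    T_K : absolute temperature [K].
    init : optional ``ViscosityParams`` initial guess.
    n_starts : number of seeded perturbations of the initial guess (>= 1).
    weighted : propagate per-tracer D_sd into ln-space weights when given.
    random_state : seed for the multi-start perturbations.

    Attributes
    ----------
    params_ : fitted ``ViscosityParams``
    band_ : ``ParamErrorBand`` with one-sigma uncertainties and covariance
    residuals_ : weighted ln-space residuals at the solution
    """

    def __init__(
        self,
        eta0_pa_s: float | None = None,
        T_K: float = DEFAULT_T_K,
        init: ViscosityParams | None = None,
        n_starts: int = 5,
        weighted: bool = True,
        random_state: int = 0,
    ):
        self.eta0_pa_s = eta0_pa_s
        self.T_K = T_K
        self.init = init
        self.n_starts = n_starts
        self.weighted = weighted
        self.random_state = random_state

    # bounds for (A, xi_nm, Rh_nm, a)
    _LB = np.array([1e-3, 1e-3, 1e-3, 1e-6])
    _UB = np.array([1e3, 1e3, 1e4, 1.0 - 1e-6])

    def fit(self, X, y, sample_weight=None):
        """Fit to radii ``X`` [nm] and measured D ``y`` [um^2/s].

        ``sample_weight`` overrides the default inverse-variance weights
        derived from D_sd (see :func:`fit_viscosity_model`).
        """
        r = np.asarray(X, dtype=float).reshape(-1)
        D = np.asarray(y, dtype=float).reshape(-1)
        if r.shape != D.shape:
            raise ValueError("X and y must have matching lengths")
        if np.any(r <= 0) or np.any(D <= 0):
            raise ValueError("radii and diffusion coefficients must be positive")
        if r.size < 5 or np.unique(r).size < 5:
            raise ValueError(
                "need >= 5 tracers at distinct radii to constrain 4 free parameters"
            )
        eta0 = self.eta0_pa_s if self.eta0_pa_s is not None else water_viscosity(self.T_K)
        # observed ln(eta_eff/eta0) from each tracer's D
        y_ln = np.log(stokes_einstein_eta(D, r, self.T_K) / eta0)
        if sample_weight is None:
            w = np.ones_like(y_ln)
        else:
            w = np.sqrt(np.asarray(sample_weight, dtype=float).reshape(-1))
            if w.shape != y_ln.shape or np.any(w < 0):
                raise ValueError("sample_weight must be non-negative, same length as X")

        def resid(theta):
            A, xi, Rh, a = theta
            x = (xi / Rh) ** 2 + (xi / r) ** 2
            model = np.log(A) + x ** (-a / 2.0)
            return w * (model - y_ln)

        init = self.init if self.init is not None else ViscosityParams(
            A=1.0, xi_nm=np.exp(np.mean(np.log(r))), Rh_nm=2.0 * r.max(), a=0.5,
            eta0_pa_s=eta0, T_K=self.T_K,
        )
        theta0 = np.array([init.A, init.xi_nm, init.Rh_nm, init.a])
        theta0 = np.clip(theta0, self._LB * 1.01, self._UB * 0.99)

        rng = np.random.default_rng(self.random_state)
        best = None
        for k in range(max(1, int(self.n_starts))):
            t0 = theta0 if k == 0 else np.clip(
                theta0 * np.exp(rng.normal(0.0, 0.4, size=4)), self._LB * 1.01, self._UB * 0.99
            )
            try:
                sol = least_squares(
                    resid, t0, bounds=(self._LB, self._UB), method="trf",
                    xtol=1e-14, ftol=1e-14, gtol=1e-14,
                )
            except Exception:  # singular jacobian at a pathological start
                continue
            if sol.success and (best is None or sol.cost < best.cost):
                best = sol
        if best is None:
            raise FitConvergenceError(
                "viscosity-model fit did not converge from any start",
                diagnostics={"n_starts": self.n_starts, "radii_nm": r.tolist()},
            )

        A, xi, Rh, a = best.x
        self.params_ = ViscosityParams(
            A=A, xi_nm=xi, Rh_nm=Rh, a=a, eta0_pa_s=eta0, T_K=self.T_K
        )
        dof = max(r.size - 4, 1)
        s2 = 2.0 * best.cost / dof
        JtJ = best.jac.T @ best.jac
        try:
            cov = np.linalg.inv(JtJ) * s2
        except np.linalg.LinAlgError:
            cov = np.linalg.pinv(JtJ) * s2
        sigma = {n: float(np.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(_FREE_NAMES)}
        self.covariance_ = cov
        self.residuals_ = best.fun
        self.band_ = ParamErrorBand(
            params=self.params_, sigma=sigma, covariance=cov,
            residuals=best.fun, cost=float(best.cost),
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X):
        """Predicted in-cell D [um^2/s] at radii ``X`` [nm]."""
        if not hasattr(self, "params_"):
            raise AttributeError("model is not fitted; call fit() first")
        return np.atleast_1d(predict_diffusion(np.asarray(X, float).reshape(-1), self.params_))


def fit_viscosity_model(
    tracers: Sequence[TracerMeasurement],
    eta0_pa_s: float | None = None,
    T_K: float = DEFAULT_T_K,
    init: ViscosityParams | None = None,
    weighted: bool = True,
    random_state: int = 0,
) -> ParamErrorBand:
    """Fit the viscosity model to a panel of tracer measurements.

    Weights (when ``weighted`` and D_sd present for all tracers) are
    inverse variances of ln(eta_eff) ~ (D_sd/D)^2 per point; otherwise the
    fit is unweighted.
    """
    tr = list(tracers)
    est = LengthScaleViscosityModel(
        eta0_pa_s=eta0_pa_s, T_K=T_K, init=init, weighted=weighted, random_state=random_state
    )
    r = np.array([t.r_p_nm for t in tr])
    D = np.array([t.D_um2s for t in tr])
    sw = None
    if weighted and all(t.D_sd_um2s > 0 for t in tr):
        rel = np.array([t.D_sd_um2s / t.D_um2s for t in tr])
        sw = 1.0 / rel**2
        sw = sw / sw.mean()
    est.fit(r, D, sample_weight=sw)
    return est.band_
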