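"""Physical constants and the pure-water viscosity correlation.

All internal units are SI unless a suffix says otherwise (``_nm``,
``_um2s``, ``_fL`` ...). Converters live at the I/O boundary, not here.
"""

from __future__ import annotations

import numpy as np
from scipy import constants as _const

#: Boltzmann constant [J/K]
K_B: float = _const.k

#: Avogadro constant [1/mol]
N_A: float = _const.N_A

#: Default measurement temperature [K] (36 degC climate chamber)
DEFAULT_T_K: float = 309.15


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


def water_viscosity(T_K: float) -> float:
    """Dynamic viscosity of pure water [Pa*s] at temperature ``T_K`` [K].

    Uses the classical CRC-handbook correlations: the Hardy-Cottington
    form below 20 degC and the log-ratio form of Swindells between 20 and
    100 degC.  Accurate to well within 0.5% of tabulated values over the
    liquid range, e.g. 1.002 mPa*s at 20 degC and ~0.705 mPa*s at 36 degC.

    Raises
    ------
    ValueError
        if ``T_K`` is outside the open interval (273.15, 373.15).
    """
    T_K = float(T_K)
    if not (273.15 < T_K < 373.15):
        raise ValueError(
            f"water_viscosity defined for liquid water only (273.15, 373.15) K; got {T_K}"
        )
    t = T_K - 273.15
    if t < 20.0:
        # Hardy & Cottington: log10(eta/cP) = 1301/(998.333 + 8.1855(t-20) + 0.00585(t-20)^2) - 1.30233
        log10_eta = 1301.0 / (998.333 + 8.1855 * (t - 20.0) + 0.00585 * (t - 20.0) ** 2) - 1.30233
        return 10.0 ** log10_eta * 1e-3
    # Swindells: log10(eta/eta20) = (1.3272(20-t) - 0.001053(t-20)^2) / (t + 105)
    eta20 = 1.002e-3
    log10_ratio = (1.3272 * (20.0 - t) - 0.001053 * (t - 20.0) ** 2) / (t + 105.0)
    return eta20 * 10.0 ** log10_ratio


def stokes_einstein_D(eta_pa_s, r_nm, T_K: float):
    """Stokes-Sutherland-Einstein diffusion coefficient [um^2/s].

    D = k_B T / (6 pi eta r) for a sphere of hydrodynamic radius ``r_nm``
    [nm] in a fluid of viscosity ``eta_pa_s`` [Pa*s].
    """
    eta = np.asarray(eta_pa_s, dtype=float)
    r = np.asarray(r_nm, dtype=float)
    if np.any(eta <= 0) or np.any(r <= 0) or T_K <= 0:
        raise ValueError("viscosity, radius and temperature must be positive")
    d_m2s = K_B * T_K / (6.0 * np.pi * eta * r * 1e-9)
    out = d_m2s * 1e12  # m^2/s -> um^2/s
    return float(out) if out.ndim == 0 else out


def stokes_einstein_eta(D_um2s, r_nm, T_K: float):
    """Invert Stokes-Sutherland-Einstein: viscosity [Pa*s] from D [um^2/s]."""
    D = np.asarray(D_um2s, dtype=float)
    r = np.asarray(r_nm, dtype=float)
    if np.any(D <= 0) or np.any(r <= 0) or T_K <= 0:
        raise ValueError("diffusion coefficient, radius and temperature must be positive")
    out = K_B * T_K / (6.0 * np.pi * D * 1e-12 * r * 1e-9)
    return float(out) if out.ndim == 0 else out
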