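"""Shared fixtures: calibrated parameters, synthetic panels, hypothesis profile."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import cytofcs as c

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hela():
    """HeLa cytosol viscosity parameters at 36 degC, reference = water."""
    return c.HELA_36C


@pytest.fixture(scope="session")
def focal_volume():
    """A typical calibrated confocal volume (w_xy = 0.3 um, kappa = 5)."""
    return c.FocalVolume(w_xy_um=0.3, kappa=5.0)


@pytest.fixture(scope="session")
def tracer_radii():
    """Eight tracer radii spanning calcein to nanoparticles (0.65-35 nm)."""
    return np.array([0.65, 1.4, 2.8, 4.7, 8.4, 14.0, 22.0, 35.0])


def make_tracer_panel(params, radii, noise_frac, n_rep, rng):
    """Synthetic tracer panel: per-probe mean of n_rep noisy replicate D values."""
    tracers = []
    for r in radii:
        d_true = c.predict_diffusion(float(r), params)
        if noise_frac > 0:
            reps = d_true * (1.0 + noise_frac * rng.standard_normal(n_rep))
            reps = np.abs(reps)
            tracers.append(c.TracerMeasurement(
                r_p_nm=float(r), D_um2s=float(reps.mean()),
                D_sd_um2s=float(reps.std(ddof=1)), n_cells=n_rep,
            ))
        else:
            tracers.append(c.TracerMeasurement(r_p_nm=float(r), D_um2s=d_true))
    return tracers


@pytest.fixture(scope="session")
def noise_free_panel(hela, tracer_radii):
    return make_tracer_panel(hela, tracer_radii, 0.0, 1, None)
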