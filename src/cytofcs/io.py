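"""Readers and writers: curves, tracer tables, parameter files, manifests.

Conventions: CSV for tabular data, YAML for key-value parameter files;
units are encoded in column and key names (``_nm``, ``_um2s``, ``_uM``)
so that a nanometre can never silently become a micrometre.  Readers
validate loudly and name the offending line; writers round-trip to full
float precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .acf import ACFFitResult, AutocorrelationCurve, FocalVolume
from .errors import ParseError
from .simulate import PhotonTrace
from .viscosity import ParamErrorBand, TracerMeasurement, ViscosityParams

_CURVE_HEADERS = (["lag_s", "G"], ["lag_s", "G", "weight"])


def read_curve(path) -> AutocorrelationCurve:
    """Read an autocorrelation curve from ``lag_s,G[,weight]`` CSV."""
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError("empty file", path)
    header = [h.strip() for h in lines[0].split(",")]
    if header not in [list(h) for h in _CURVE_HEADERS]:
        raise ParseError(f"expected header lag_s,G[,weight]; got {lines[0]!r}", path, 1)
    has_w = len(header) == 3
    lags, g, w = [], [], []
    prev = -np.inf
    for ln, raw in enumerate(lines[1:], start=2):
        if not raw.strip():
            continue
        cells = raw.split(",")
        if len(cells) != len(header):
            raise ParseError(f"expected {len(header)} columns, got {len(cells)}", path, ln)
        try:
            vals = [float(c) for c in cells]
        except ValueError as e:
            raise ParseError(f"non-numeric cell: {e}", path, ln) from None
        if vals[0] <= prev:
            raise ParseError(
                f"lag times must be strictly increasing; {vals[0]} after {prev}", path, ln
            )
        if vals[0] <= 0:
            raise ParseError("lag times must be positive", path, ln)
        prev = vals[0]
        lags.append(vals[0])
        g.append(vals[1])
        if has_w:
            if vals[2] < 0:
                raise ParseError("weights must be non-negative", path, ln)
            w.append(vals[2])
    if not lags:
        raise ParseError("no data rows", path)
    return AutocorrelationCurve(
        lags=np.array(lags), G=np.array(g),
        weights=np.array(w) if has_w else None, meta={"source": str(path)},
    )


def write_curve(curve: AutocorrelationCurve, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        if curve.weights is not None:
            fh.write("lag_s,G,weight\n")
            for t, g, w in zip(curve.lags, curve.G, curve.weights):
                fh.write(f"{float(t)!r},{float(g)!r},{float(w)!r}\n")
        else:
            fh.write("lag_s,G\n")
            for t, g in zip(curve.lags, curve.G):
                fh.write(f"{float(t)!r},{float(g)!r}\n")


def read_tracer_table(path) -> list[TracerMeasurement]:
    """Read a tracer panel from ``probe,r_p_nm,D_um2s,D_sd_um2s,n`` CSV."""
    path = Path(path)
    expected = ["probe", "r_p_nm", "D_um2s", "D_sd_um2s", "n"]
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise ParseError(f"cannot parse CSV: {e}", path) from None
    if list(df.columns) != expected:
        raise ParseError(f"expected header {','.join(expected)}; got {list(df.columns)}", path, 1)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(TracerMeasurement(
                r_p_nm=float(row["r_p_nm"]), D_um2s=float(row["D_um2s"]),
                D_sd_um2s=float(row["D_sd_um2s"]), n_cells=int(row["n"]),
                name=str(row["probe"]),
            ))
        except (TypeError, ValueError) as e:
            raise ParseError(str(e), path, i + 2) from None
    return out


def write_tracer_table(tracers, path) -> None:
    with Path(path).open("w") as fh:
        fh.write("probe,r_p_nm,D_um2s,D_sd_um2s,n\n")
        for t in tracers:
            fh.write(f"{t.name},{float(t.r_p_nm)!r},{float(t.D_um2s)!r},{float(t.D_sd_um2s)!r},{t.n_cells}\n")


def write_viscosity_params(band: ParamErrorBand | ViscosityParams, path) -> None:
    """Serialize fitted viscosity parameters (+ 1-sigma errors) to flat YAML."""
    if isinstance(band, ViscosityParams):
        band = ParamErrorBand(params=band, sigma={})
    p = band.params
    doc = {
        "A": float(p.A), "xi_nm": float(p.xi_nm), "Rh_nm": float(p.Rh_nm),
        "a": float(p.a), "eta0_pa_s": float(p.eta0_pa_s), "T_K": float(p.T_K),
    }
    for k, v in band.sigma.items():
        doc[f"{k}_err"] = float(v)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_viscosity_params(path) -> ParamErrorBand:
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ParseError("expected a flat key-value mapping", path)
    required = {"A", "xi_nm", "Rh_nm", "a", "eta0_pa_s", "T_K"}
    missing = required - doc.keys()
    if missing:
        raise ParseError(f"missing keys: {sorted(missing)}", path)
    try:
        params = ViscosityParams(
            A=float(doc["A"]), xi_nm=float(doc["xi_nm"]), Rh_nm=float(doc["Rh_nm"]),
            a=float(doc["a"]), eta0_pa_s=float(doc["eta0_pa_s"]), T_K=float(doc["T_K"]),
        )
    except ValueError as e:
        raise ParseError(str(e), path) from None
    sigma = {k[:-4]: float(v) for k, v in doc.items() if k.endswith("_err")}
    return ParamErrorBand(params=params, sigma=sigma)


_MANIFEST_COLS = ["cell_id", "file", "label", "p_tagged"]


def read_manifest(path) -> pd.DataFrame:
    """Read the per-cell manifest CSV (``cell_id,file,label,p_tagged``)."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise ParseError(f"cannot parse CSV: {e}", path) from None
    if list(df.columns) != _MANIFEST_COLS:
        raise ParseError(
            f"expected header {','.join(_MANIFEST_COLS)}; got {list(df.columns)}", path, 1
        )
    if df["cell_id"].duplicated().any():
        dup = df.loc[df["cell_id"].duplicated(), "cell_id"].iloc[0]
        raise ParseError(f"duplicated cell_id {dup!r}", path)
    bad = ~df["p_tagged"].between(0, 1, inclusive="right")
    if bad.any():
        raise ParseError(
            f"p_tagged must lie in (0, 1]; offending row {int(np.flatnonzero(bad)[0]) + 2}", path
        )
    return df


def write_fit_report(result: ACFFitResult, path, residuals_path=None) -> None:
    """Fit report as flat YAML (+ optional residuals CSV)."""
    doc: dict = {
        "N": float(result.N),
        "kappa": float(result.kappa),
        "redchi": float(result.redchi),
        "success": bool(result.success),
        "message": str(result.message),
    }
    for i, (a, t, al) in enumerate(zip(result.amplitudes, result.tau_ds_s, result.alphas)):
        doc[f"A_{i}"] = float(a)
        doc[f"tau_D_{i}_s"] = float(t)
        doc[f"alpha_{i}"] = float(al)
    if result.triplet_fraction is not None:
        doc["triplet_fraction"] = float(result.triplet_fraction)
        doc["triplet_tau_s"] = float(result.triplet_tau_s)
    for k, v in result.stderr.items():
        doc[f"{k}_err"] = float(v)
    if result.warnings:
        doc["warnings"] = list(result.warnings)
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))
    if residuals_path is not None:
        with Path(residuals_path).open("w") as fh:
            fh.write("index,residual\n")
            for i, r in enumerate(result.residuals):
                fh.write(f"{i},{float(r)!r}\n")


def write_trace(trace: PhotonTrace, path) -> None:
    """Photon trace as CSV: a ``# bin_time_s=`` comment then ``bin_index,counts``."""
    with Path(path).open("w") as fh:
        fh.write(f"# bin_time_s={trace.bin_time_s!r}\n")
        fh.write("bin_index,counts\n")
        for i, c in enumerate(trace.counts):
            fh.write(f"{i},{int(c)}\n")


def read_trace(path) -> PhotonTrace:
    path = Path(path)
    lines = path.read_text().splitlines()
    if len(lines) < 2 or not lines[0].startswith("# bin_time_s="):
        raise ParseError("expected '# bin_time_s=...' comment on line 1", path, 1)
    try:
        bin_time = float(lines[0].split("=", 1)[1])
    except ValueError:
        raise ParseError("unparsable bin_time_s", path, 1) from None
    if lines[1].strip() != "bin_index,counts":
        raise ParseError("expected header bin_index,counts", path, 2)
    counts = []
    for ln, raw in enumerate(lines[2:], start=3):
        if not raw.strip():
            continue
        cells = raw.split(",")
        if len(cells) != 2:
            raise ParseError("expected 2 columns", path, ln)
        try:
            counts.append(int(cells[1]))
        except ValueError:
            raise ParseError(f"non-integer count {cells[1]!r}", path, ln) from None
    return PhotonTrace(bin_time_s=bin_time, counts=np.array(counts, dtype=np.int64))


def read_oligomer_table(path):
    """Read oligomer specs from ``name,stoichiometry,r_p_nm`` CSV."""
    from .oligomers import OligomerSpec

    path = Path(path)
    expected = ["name", "stoichiometry", "r_p_nm"]
    try:
        df = pd.read_csv(path)
    except Exception as e:
        raise ParseError(f"cannot parse CSV: {e}", path) from None
    if list(df.columns) != expected:
        raise ParseError(f"expected header {','.join(expected)}; got {list(df.columns)}", path, 1)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(OligomerSpec(str(row["name"]), int(row["stoichiometry"]),
                                    float(row["r_p_nm"])))
        except (TypeError, ValueError) as e:
            raise ParseError(str(e), path, i + 2) from None
    return out


# --------------------------------------------------------------------------
# experiment configuration


@dataclass
class ExperimentConfig:
    """Resolved pipeline configuration (all defaults materialized)."""

    temperature_c: float = 36.0
    eta0: str | float = "auto-water"
    d_ref_um2s: float | None = None
    calibration_curve: str | None = None
    w_xy_um: float | None = None
    kappa: float | None = None
    viscosity_params: str | None = None
    tracers: str | None = None
    oligomers: str | None = None
    rel_const_viscosity: float = 2.34
    protocol: str = "three_component_fixed"
    blinking: bool = True
    p_default: float = 0.1
    seed: int = 0
    out_dir: str = "results"

    def __post_init__(self) -> None:
        if not (0 < self.temperature_c < 100):
            raise ValueError("temperature_c must be a liquid-water temperature")
        if isinstance(self.eta0, str) and self.eta0 != "auto-water":
            raise ValueError("eta0 must be 'auto-water' or a value in Pa*s")
        if self.protocol not in ("two_component", "three_component_fixed", "auto"):
            raise ValueError(f"unknown protocol {self.protocol!r}")
        if self.calibration_curve is None and (self.w_xy_um is None or self.kappa is None):
            raise ValueError("provide calibration_curve or explicit w_xy_um + kappa")

    @property
    def T_K(self) -> float:
        return self.temperature_c + 273.15


def load_experiment_config(path) -> ExperimentConfig:
    """Load and strictly validate a YAML experiment configuration."""
    path = Path(path)
    doc = yaml.safe_load(path.read_text())
    if not isinstance(doc, dict):
        raise ParseError("expected a mapping at top level", path)
    known = set(ExperimentConfig.__dataclass_fields__)
    unknown = set(doc) - known
    if unknown:
        raise ParseError(f"unknown keys rejected: {sorted(unknown)}", path)
    try:
        return ExperimentConfig(**doc)
    except (TypeError, ValueError) as e:
        raise ParseError(str(e), path) from None
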