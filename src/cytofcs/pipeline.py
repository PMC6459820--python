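"""End-to-end orchestration: calibrate -> viscosity model -> cells -> population.

Every stage failure is re-raised as a ``PipelineStageError`` tagged with
the stage name; per-cell fit failures flag the cell and exclude it from
the population instead of halting.  Runs are deterministic given the
seeds in the configuration, and the resolved configuration is logged in
full for reproducibility.
"""

from __future__ import annotations

import logging
from pathlib import Path

import yaml

from . import io as cio
from .acf import FocalVolume, calibrate_focal_volume
from .errors import CytoFCSError, PipelineStageError
from .oligomers import (
    DRP1_OLIGOMERS,
    analyze_variant_cell,
    population_summary,
    predict_oligomer_table,
)
from .viscosity import ParamErrorBand, fit_viscosity_model
from .constants import water_viscosity

log = logging.getLogger("cytofcs.pipeline")


def _stage(name):
    class _ctx:
        def __enter__(self):
            log.info("stage %s: start", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, PipelineStageError):
                raise PipelineStageError(name, str(exc)) from exc
            log.info("stage %s: done", name)
            return False

    return _ctx()


def run_pipeline(config: cio.ExperimentConfig, manifest_path, out_dir=None) -> dict:
    """Run the full analysis described by ``config`` over a cell manifest.

    Returns a dict with the focal volume, viscosity band, per-cell table
    and population summary; all artefacts are also written to
    ``out_dir`` (cells.csv, population.yaml, viscosity_params.yaml,
    resolved_config.yaml).
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("resolved config: %s", config)
    (out / "resolved_config.yaml").write_text(
        yaml.safe_dump({k: getattr(config, k) for k in config.__dataclass_fields__})
    )

    with _stage("calibrate"):
        if config.calibration_curve is not None:
            if config.d_ref_um2s is None:
                raise ValueError("calibration_curve given but d_ref_um2s missing")
            ref = cio.read_curve(config.calibration_curve)
            fv = calibrate_focal_volume(ref, config.d_ref_um2s)
        else:
            fv = FocalVolume(w_xy_um=config.w_xy_um, kappa=config.kappa)
        log.info("focal volume: w_xy=%.4f um kappa=%.2f V_eff=%.4f fL",
                 fv.w_xy_um, fv.kappa, fv.V_eff_fL)

    with _stage("viscosity"):
        eta0 = (water_viscosity(config.T_K) if config.eta0 == "auto-water"
                else float(config.eta0))
        if config.viscosity_params is not None:
            band = cio.read_viscosity_params(config.viscosity_params)
        elif config.tracers is not None:
            tracers = cio.read_tracer_table(config.tracers)
            band = fit_viscosity_model(tracers, eta0_pa_s=eta0, T_K=config.T_K,
                                       random_state=config.seed)
        else:
            raise ValueError("provide viscosity_params or tracers")
        cio.write_viscosity_params(band, out / "viscosity_params.yaml")

    with _stage("predict-oligomers"):
        specs = (cio.read_oligomer_table(config.oligomers)
                 if config.oligomers is not None else list(DRP1_OLIGOMERS))
        table = predict_oligomer_table(specs, band.params, config.rel_const_viscosity)
        table.to_csv(out / "oligomer_predictions.csv", index=False)
        pred_d = dict(zip(table["name"], table["D_model_um2s"]))

    with _stage("analyze-cells"):
        manifest = cio.read_manifest(manifest_path)
        base = Path(manifest_path).parent
        cells, rows = [], []
        for _, row in manifest.iterrows():
            cell_id = str(row["cell_id"])
            fpath = Path(row["file"])
            if not fpath.is_absolute():
                fpath = base / fpath
            if not fpath.exists():
                raise ValueError(f"curve file missing for cell {cell_id!r}: {fpath}")
            curve = cio.read_curve(fpath)
            try:
                cell = analyze_variant_cell(
                    curve, config.protocol, fv, p=float(row["p_tagged"]),
                    predicted_D_um2s=pred_d, cell_id=cell_id, blinking=config.blinking,
                )
            except CytoFCSError as e:
                log.warning("cell %s excluded: %s", cell_id, e)
                rows.append({"cell_id": cell_id, "flags": f"fit-failed: {e}"})
                continue
            log.info("cell %s: protocol=%s C=%.1f nM flags=%s",
                     cell_id, cell.protocol, cell.C_FCS_nM, cell.flags)
            cells.append(cell)
            rows.append({
                "cell_id": cell_id,
                "C_FCS_nM": cell.C_FCS_nM,
                "A_dimer": cell.amplitudes.get("dimer", cell.amplitudes.get("fast")),
                "A_tetramer": cell.amplitudes.get("tetramer"),
                "A_slow": cell.amplitudes.get("slow"),
                "KD_uM": cell.K_D_uM,
                "flags": ";".join(cell.flags),
            })
        import pandas as pd

        pd.DataFrame(rows).to_csv(out / "cells.csv", index=False)
        if not cells:
            raise ValueError("no cell could be analyzed")

    summary = None
    if any(c.K_D_uM is not None for c in cells):
        with _stage("population"):
            summary = population_summary(cells)
            (out / "population.yaml").write_text(yaml.safe_dump({
                "n_cells": summary.n_cells,
                "KD_mean_uM": summary.kd_mean_uM,
                "KD_sd_uM": summary.kd_sd_uM,
                "KD_p25_uM": summary.kd_percentiles_uM[0],
                "KD_p50_uM": summary.kd_percentiles_uM[1],
                "KD_p75_uM": summary.kd_percentiles_uM[2],
                "KD_vs_C_spearman_r": summary.kd_concentration_spearman_r,
                "KD_vs_C_spearman_p": summary.kd_concentration_spearman_p,
                "amplitude_means": summary.amplitude_means,
                "amplitude_sds": summary.amplitude_sds,
            }, sort_keys=False))

    return {"focal_volume": fv, "viscosity": band, "cells": cells,
            "population": summary, "out_dir": out}
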