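# cytofcs

Quantitative fluorescence correlation spectroscopy (FCS) inside living
cells: length-scale-dependent cytoplasmic viscosity, multi-component
autocorrelation fitting, and amplitude-based dissociation constants for
protein oligomerization — plus a Brownian-dynamics FCS simulator that
provides ground truth for every step.

## The problem

FCS measures the diffusion coefficient `D` of a fluorescent probe from
intensity fluctuations in a femtoliter confocal volume. In buffer,
`D = k_B T / (6 pi eta r_p)` converts `D` into a hydrodynamic radius
`r_p`. In cytoplasm this fails, because the viscosity a probe feels
depends on the probe's own size: small molecules slip between
macromolecules while larger complexes feel the full crowded medium.
`cytofcs` implements the exponential length-scale drag law

    eta_eff(r_p) = eta_0 * A * exp[ (xi^2/R_h^2 + xi^2/r_p^2)^(-a/2) ]

calibrated per cell type from inert tracers of known radius. With it, an
in-cell `D` becomes a complex size — and FCS becomes an assay for
oligomerization state. For a protein in dimer⇌tetramer equilibrium
(the shipped example: the mitochondrial fission GTPase Drp1, EGFP-tagged,
in HeLa cytosol), the fitted component amplitudes and the detected
concentration give a per-cell dissociation constant

    K_D = (C_FCS / p) * A_dimer^2 / A_tetramer

where `p` is the tagged fraction of total protein. Autocorrelation
curves are modelled by the standard multi-component 3D-Gaussian-volume
form with optional triplet/blinking kinetics; every amplitude, diffusion
time and anomalous exponent can be declared free, fixed or bounded.

Audience: biophysicists doing in-cell FCS who want the full pipeline
(calibration → viscosity model → per-cell fits → K_D population
statistics) as reusable, tested code, and methods developers who need a
validated simulator to benchmark FCS estimators.

## Worked example

```python
import cytofcs as c

# HeLa cytosol at 36 C: A=1.3, xi=3.16 nm, R_h=12.9 nm, a=0.62
table = c.predict_oligomer_table(c.DRP1_OLIGOMERS, c.HELA_36C)
print(table.round(3).to_string(index=False))

kd = c.compute_KD(C_FCS_nM=30.0, p=0.1, A_dimer=0.34, A_tetramer=0.15)
print(f"K_D = {kd:.3f} uM")
```

prints

```
    name  stoichiometry  r_p_nm  D_model_um2s  D_const_um2s  pct_diff_model  pct_diff_const
 monomer              1    4.74        15.134        28.947          40.155          26.053
   dimer              2    6.41         9.057        21.406          37.604          23.962
tetramer              4    8.43         5.651        16.276             NaN             NaN

K_D = 0.231 uM
```

Reading it: `D_model_um2s` is the predicted in-cell diffusion
coefficient of each oligomer under the length-scale drag law (15.1, 9.1
and 5.7 µm²/s to experimental precision); `D_const_um2s` is what a naive
constant-viscosity assumption (2.34× water, the value probed by free
EGFP) would predict. The percent columns give the D contrast between
consecutive oligomers: 26%/24% under constant viscosity — below what
curve fitting can resolve — versus 40%/37% under the length-scale model,
which is why dimers and tetramers are distinguishable at all. The K_D
line converts one cell's fitted amplitudes (dimer 0.34, tetramer 0.15,
detected concentration 30 nM, 10% tagged) into a tetramerization
dissociation constant of 0.23 µM.

The simulator closes the loop end to end:

```python
sim = c.simulate_wildtype_experiment(n_replicates=10, seed=1)
print(sim.amplitude_mean)   # fitted (dimer, tetramer, slow) amplitudes
```

simulates ten 60-second photon traces of the dimer/tetramer/slow mixture
through a 3D-Gaussian confocal volume, correlates them with the built-in
multi-tau estimator, and refits the three-component fixed-time model —
recovering the input amplitude fractions (0.34/0.15/0.51) within
replicate scatter.

A command-line surface wraps the library for shell use:

```
cytofcs fit-viscosity --tracers tracers.csv --temp-c 36 --out params.yaml
cytofcs predict-d     --params params.yaml --radius-nm 4.74
cytofcs calibrate     --curve rhob.csv --d-ref 400
cytofcs fit-acf       --curve cell.csv --model model.yaml --out fit.yaml
cytofcs simulate      --config sim.yaml --out trace.csv
cytofcs correlate     --trace trace.csv --m 16 --out curve.csv
cytofcs simulate-population --kd-um 0.7 --n-cells 30 --seed 1 --out pop.csv
cytofcs run-pipeline  --config experiment.yaml --manifest manifest.csv
```

File formats are plain CSV/YAML with units in the column and key names
(`r_p_nm`, `D_um2s`, `KD_uM`); see `docs/methods.md` for the models,
numerical choices and validation studies.

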