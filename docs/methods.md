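# Methods

`cytofcs` quantifies protein oligomerization directly in the cytoplasm of
living cells from fluorescence correlation spectroscopy (FCS) data. This
note records the models, the numerical choices, what the synthetic-data
generators emulate, and the limits of what the test suite demonstrates.

## 1. Length-scale-dependent viscosity

The effective viscosity felt by a probe of hydrodynamic radius `r_p` in
cytoplasm is modelled as

    eta_eff(r_p) = eta_0 * A * exp[ (xi^2/R_h^2 + xi^2/r_p^2)^(-a/2) ]

with reference viscosity `eta_0`, preexponential factor `A ~ 1`, length
scales `xi` and `R_h` (nm), and exponent `0 < a < 1`. The model
interpolates between the buffer-like drag felt by small molecules and a
macroscopic plateau `A*exp[(xi/R_h)^(-a)]` for large particles; it treats
the cytosol of a given cell type under given culture conditions as one
homogeneous structured fluid (no spatial maps). Diffusion coefficients
follow from the Stokes–Sutherland–Einstein relation
`D = k_B T / (6 pi eta_eff r_p)`.

The shipped calibration `HELA_36C` (A=1.3, xi=3.16 nm, R_h=12.9 nm,
a=0.62, eta_0 = pure water at 36 °C, T=309.15 K) is the HeLa-cytosol
parameter set this pipeline is normally used with. `eta_0` defaults to a
pure-water correlation (CRC-handbook forms, <0.5% error over the liquid
range) because the published HeLa oligomer predictions are reproduced with
water at 36 °C; any explicit `eta0_pa_s` overrides it.

**Fitting.** `LengthScaleViscosityModel` regresses `ln(eta_eff/eta_0)`
(from measured tracer D values) on `r_p`. The ln transform linearizes the
exponential and keeps the large-radius plateau from dominating the loss.
Bounded trust-region least squares (`A, xi, R_h > 0`, `0 < a < 1`) with a
five-start seeded multi-start handles the partial `xi–R_h–a` degeneracy;
the best-cost solution is kept. Weights default to inverse variances of
`ln eta`, i.e. `(D/D_sd)^2`, when per-tracer SDs are available. A panel
must contain at least five distinct radii (four free parameters).
Parameter uncertainties come from the Jacobian at the solution scaled by
the residual variance; Monte-Carlo calibration (200 synthetic panels,
eight radii 0.65–35 nm, 10% replicate noise, N=15) shows the estimates
unbiased with two-ensemble-sigma coverage ≥95% per parameter, while the
reported per-fit standard errors are ~12% optimistic — typical for bounded
nonlinear least squares.

Error bands on derived quantities use the total-differential method,
`delta_f = sum_i |df/dp_i| sigma_i`, with central finite differences
(relative step 1e-6, absolute floor 1e-12); the partials are checked
against symbolic differentiation in the test suite.

## 2. Autocorrelation model and fitting

Curves are modelled by the standard multi-component 3D-Gaussian-volume
form

    G(tau) = (1/N) sum_i A_i [1+(tau/tau_Di)^alpha_i]^-1
                          [1+(tau/tau_Di)^alpha_i/kappa^2]^-1/2

optionally multiplied by a blinking factor
`1 + f_T/(1-f_T) exp(-tau/tau_T)`. The blinking functional form is the
standard multiplicative triplet correction; the characteristic time is
hard-bounded to 0.1–0.3 ms by default, matching the constraint used when
fitting EGFP constructs. `alpha` is fixed at 1 (free diffusion) for fast
cytosolic components and configurable for the slow pool (default also 1).

Internally the fit parameterizes a total diffusive amplitude `G0 = 1/N`
and fractions that sum to exactly 1 (one fraction carries the sum
constraint), so every reported amplitude vector is a partition of unity
and `N` absorbs the scale. Fixed values pass through untouched; bounds
are hard. Fits are unweighted by default; per-lag inverse-variance
weights are accepted (e.g. from correlating trace segments). In our own
simulation studies segment-derived weights did not improve, and fitting
segment-averaged curves is avoided deliberately: short segments carry a
finite-length downward bias at lags approaching the segment duration,
which visibly distorts slow-component estimates.

**Calibration.** A reference-dye curve of known `D_ref` is fitted with
one free component and free `kappa`; then `w_xy = sqrt(4 D_ref tau_D)`
and `V_eff = pi^{3/2} w_xy^3 kappa`. Calibration is rejected when the
single-component fit is poor (RMS residual > 5% of G(0), or reduced
chi-square > 5 with weights). Concentrations follow from
`C = N/(N_A V_eff)`, and molecular brightness (CPM) from mean intensity
over `N`.

## 3. Oligomer analysis and K_D

Predicted oligomer mobilities combine the viscosity model with the input
hydrodynamic radii (for EGFP-tagged Drp1: monomer 4.74 nm, dimer 6.41 nm,
tetramer 8.43 nm, from bead-model hydrodynamics; radii are inputs, never
computed here). The constant-viscosity column uses a single relative
viscosity (default 2.34, the value probed by free EGFP) for contrast:
under it consecutive oligomers differ by only 26%/24% in D, under the
length-scale model by 40%/37% — the separation that makes the
fixed-time multi-component fit feasible at all.

Per-cell protocols: non-oligomerizing variants get a two-component fit
(free fast + free slow, blinking on for EGFP); wild-type-like cells get a
three-component fit with dimer and tetramer times fixed at
`tau = w_xy^2/(4 D_pred)` and amplitudes free. An `auto` rule runs both
and prefers the fixed-time model when the two-component fast time falls
strictly between the two fixed times *and* its reduced chi-square is
worse by a configurable factor (default 1.2) — in practice the
free-slow-time two-component model fits mixtures almost as well, so the
chi-square gate rarely fires at its default and per-cell overrides are
expected.

The tetramerization constant is
`K_D = (C_FCS/p) * A_dimer^2 / A_tetramer` (computed in nM, reported in
µM), with `p` the tagged fraction, a required input. Its validity gates
are enforced as checks, not assumptions: equal brightness across cells
(CPM relative spread below a threshold, default 0.25), `p ≤ 0.5` warning
for the excess-untagged assumption, a flagged "no-tetramer" outcome when
`A_tetramer = 0`, and a low-information flag when the slow pool exceeds
0.8. Population summaries report mean ± SD, quartiles, and a Spearman
rank correlation of K_D against detected concentration — chosen over
Pearson because per-cell K_D distributions are strongly skewed — as the
equilibrium consistency check (no correlation expected).

The monomer is deliberately absent from wild-type fits (dimerization is
assumed fast and monomers undetectable); this is configurable for other
proteins.

## 4. Brownian-dynamics simulator

Ground truth for the whole chain. Point particles diffuse independently
in a periodic cube (edge ≥ 10 κ w_xy; default 15 µm for w_xy=0.3 µm,
κ=5) with exact Gaussian increments of SD `sqrt(2 D dt)` per axis. The
detection profile is the same 3D Gaussian the analytical model assumes —
so simulator and fit model share their geometry exactly, and
`G(0) = 1/(c V_eff)` holds by construction. Expected intensity is
`sum_i B_i exp(-2(x^2+y^2)/w_xy^2 - 2z^2/w_z^2)` plus background; photon
counts are Poisson per bin. Particle number is fixed (closed box);
occupancy fluctuations arise from the subvolume, as in real FCS.

Numerical design, all validated against the closed form in the tests:

- Base step: `dt` must satisfy `sqrt(2 D_max dt) ≤ w_xy/10`. Species
  with smaller D internally use the largest integer multiple of `dt`
  that still satisfies the same bound for their own D (Gaussian
  increments are exact at any step, so this only coarsens the intensity
  sampling of already-slow signals).
- Far-field acceleration: in the scaled radius
  `u^2 = x^2+y^2+z^2/kappa^2` the detection weight is exactly
  `exp(-2u^2/w_xy^2)`; beyond `u = 2.2 w_xy` (weight < 1e-4, truncated
  mass ~2e-4 of the profile integral) a particle takes one Gaussian jump
  of `m` steps, with `m` capped so that five jump-SDs stay short of the
  detection radius — a jump cannot cross into the observed region
  undetected. Entry statistics are preserved because coarse jumps are
  exact Brownian increments.
- RNG: a xoshiro256+ stream with a 128-layer ziggurat normal sampler
  inside the compiled kernel (the displacement loop draws ~1e9 variates
  per minute-long trace). Seeding is explicit everywhere; identical
  seeds give identical traces bit-for-bit.
- Blinking (optional, off by default — the validation experiment
  deliberately leaves fluorophore dark-state kinetics out, and fits then
  omit the triplet factor too): a bright/dark telegraph propagated with
  the exact finite-time two-state transition probability at any step
  size.

**Correlator.** A multi-tau estimator (m=16 lags per octave, progressive
pairwise binning, symmetric normalization) turns counts into curves. At
native lags it equals a direct correlator to 1e-10; at coarser levels it
equals the direct correlator applied to the identically binned trace —
the triangular smoothing inherent to multi-tau binning is part of the
estimator's definition, not an error. Shot noise does not bias any lag
k ≥ 1.

**Wild-type validation experiment.** Three species at amplitude
fractions 0.34/0.15/0.51 and D = 9.1/5.7/0.5 µm²/s (the slow pool is a
diffusing species, not immobile: D = 0.5 µm²/s gives the millisecond-
scale diffusion times seen for nonspecifically bound protein), equal
brightness (one label per oligomer), 45 000 particles — about 10
molecules in the effective volume, the occupancy of the cell
measurements this emulates — 60 s per replicate at 40 µs bins. Each
replicate is correlated and refitted with dimer/tetramer times fixed
from the input D values, amplitudes free, the slow time free within
5 ms–2 s, over lags ≤ 0.5 s, unweighted. Pilot calibration: the
per-replicate dimer amplitude has SD ≈ 0.13 — the dimer/tetramer split
(diffusion-time ratio 1.6) is intrinsically ill-conditioned at 60 s of
statistics, and tetramer estimates occasionally collapse to 0 — while
the replicate mean is stable (≈0.335 ± 0.026 over 24 replicates) and
consistent with the 0.36 ± 0.06 this experiment is designed to
reproduce. Weighted fits, difference fits and fixing the slow time were
all tried on matched seeds and did not improve the dimer estimate.

**Population generator.** Per cell: total subunit concentration drawn
log-normally (default median 2 µM, sigma 0.7 — order-of-magnitude
cell-to-cell expression spread), the dimer⇌tetramer mass action
`[D]^2/[T] = K_D` solved in closed form, a slow/bound pool holding a
fixed fraction (default 0.5) of detected oligomers added, amplitudes set
to number fractions (one fluorophore per oligomer), and
`C_FCS = p ([D]+[T]+[slow])`. Under this labelling bookkeeping the K_D
formula inverts the generator exactly at zero noise, for any slow
fraction. Amplitude noise is truncated-Gaussian (non-negative) with
SDs 0.09/0.05 — the cell-to-cell spread of the measured wild-type
amplitudes.

## 5. What the synthetic data does and does not show

The generators emulate: the length-scale drag law with measurement
noise; multi-component free diffusion with realistic occupancy, photon
statistics and acquisition length; mass-action dimer–tetramer
equilibrium with expression spread; one-label-per-oligomer brightness.
They do not emulate: spatial heterogeneity or compartment boundaries,
anomalous diffusion of the slow pool, EGFP photophysics beyond an
optional two-state telegraph, detector afterpulsing/dead time, membrane
binding kinetics, or reactions occurring during a trace (equilibrium is
imposed at the population level). Passing tests therefore demonstrate
the estimators are correct and calibrated under the stated model — not
that the model captures every property of real cytoplasm.

## 6. Problem sizes and tolerances

Defaults used by the test suite and the acceptance script, chosen for
statistical adequacy: 200 panels for the viscosity-fit calibration; 100
populations × 30 cells for K_D recovery (factor-2 criterion, ≥90%
expected); single-species simulator validation on one 60 s trace at
occupancy 10 compared with the closed form at 16 log-spaced lags within
3 per-lag standard errors (SE from 15 trace segments); wild-type
validation with 24 (tests) or 32 (acceptance script) replicates of 60 s.
Zero-noise identities are exact to 1e-3 relative or better; the
correlator oracle agreement is exact to 1e-10. Degenerate inputs
(non-positive radii or times, amplitude sums > 1, non-monotone lag
grids, undetectable tetramer) raise or return explicit outcomes rather
than propagating silently.
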