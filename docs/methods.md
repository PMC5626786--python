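# Methods

`nusrd` simulates and analyses Carr-Purcell-Meiboom-Gill (CPMG) relaxation
dispersion experiments recorded with non-uniform sampling (NUS). This note
documents the models, the numerical choices, and what the synthetic studies
do and do not demonstrate.

## Two-state exchange model

A nucleus exchanges between a ground state A (population `p_A`) and an
excited state B (`p_B = 1 - p_A`) with rate `kex = k_AB + k_BA` and a
chemical-shift difference `dw` (rad/s; reported as `|dw|` in ppm via the
probed nucleus' Larmor frequency — CPMG data do not determine the sign).
During the constant relaxation delay `T` a train of 180-degree pulses is
applied at repetition rate `nu_cpmg = 1/(2*delta)`, `delta` being the
spacing between pulse centres; the number of pulses is `round(2*nu*T)`
forced even, and the half-echo delay is `T/(2n)`.

Evaluators:

- `bm_r2eff` — reference numerical propagation of the two-site in-phase
  Bloch-McConnell equations through the explicit echo train. The observable
  is the ground-state magnetization; `R2,eff = -ln(M_A(T)/p_A)/T`.
  Cross-checked against brute-force ODE integration to 1e-12.
- `cr_r2eff` — the same physics in closed form via the analytic
  eigendecomposition of the 2x2 evolution operator, vectorized over
  frequencies and parameter arrays, exact to machine precision. The
  classical truncated Carver-Richards expression is kept as `cr72_r2eff`
  for reference; it errs by up to ~10% for slow exchange with large
  excited-state populations, which is why the exact form backs all fitting.
- `luz_meiboom_r2eff` — fast-exchange limit, linear in `(r2_0, phi)` for
  fixed `kex`; used by the significance test.

The in-phase model is taken as valid throughout: experiments of this class
equalize in-phase/anti-phase periods, so no anti-phase relaxation is
modelled. A single static field (18.8 T, labelled 800.13 MHz 1H) is
supported; 15N and 13CO are the probed nuclei.

## Significance testing

Per residue, a flat model `R2 = r2_0` is compared with the fast-exchange
model `R2 = r2_0 + phi * g(nu; kex)` (`kex` scanned over a 24-point log
grid, `(r2_0, phi)` by weighted linear least squares). The comparison
statistic is the F ratio of the chi-square reduction. Because `kex` is
unidentified under the null (Davies' problem), the textbook F(2, n-3) tail
is badly mis-calibrated: the reduction behaves like a maximum of correlated
1-dof chi-squares. The reported p-value therefore comes from a seeded
Monte-Carlo table of the null F distribution, which is pivotal given the
frequency grid and the relative error profile (20000 draws per design,
cached). Beyond the table the classical tail is used, which is conservative
there. Verified type-I error at p < 0.01: 1.0-1.5% over 5000 flat curves.

## Global two-state fit

Residues significant at p < 0.01 enter a global weighted fit sharing
`(kex, p_b)` with per-residue `(|dw|, r2_0)`, using the exact closed form.
Multi-start trust-region least squares: starting points on a log-uniform
`kex` grid (10 by default) are scored, the best few refined; bounds
kex 10-5000 1/s, p_b 0.001-0.2, dw 0-6 ppm, boundary-pinned optima are
flagged. Uncertainties come from the Jacobian covariance scaled by the
reduced chi-square; the strong `kex`/`p_b` anticorrelation is exposed
through the full covariance matrix. On noiseless synthetic curves the fit
recovers parameters to <1e-4 relative; on noisy curves the reported errors
match the Monte-Carlo spread (verified over 20 replicates).

## Synthetic data

A site contributes a separable product of exponentially damped complex
sinusoids, one per spectral dimension; CPMG plane `nu` is scaled by
`exp(-R2,eff(nu) * T)` relative to the reference plane (recorded without
the delay). States quadrature is stored as the two lossless complex
combinations (positive / negative indirect modulation); both carry
independent complex Gaussian noise. Defaults emulate the benchmark
conditions: 18.8 T; 2D grids of 64 (1H, 900 Hz window of the amide region)
by 48 (15N, 2250 Hz / 13CO, 1400 Hz) points; HNCO-type 3D grids with
(15N, 13CO) indirect dimensions; eleven CPMG frequencies 25-1000 Hz (all
dividing evenly into T = 40 ms) plus four duplicates and the reference
plane; per-residue linewidths and amplitudes drawn from small-protein
ranges; exchange regimes kex = 182 1/s / p_b = 2.9% with |dw| 0.2-3 ppm
(15N) and kex = 173 1/s / p_b = 3.6% with |dw| 0.1-1 ppm (13CO). The
time-domain noise scale is calibrated so a typical dispersion point has
sigma_R2 ~ 0.2 1/s, matching the benchmark's error scale.

What the generator does **not** emulate: scalar couplings and the Asp/Asn
side-chain carbonyl coupling artifact, off-resonance and finite-pulse
effects, solvent/baseline artifacts, temperature drift, and lineshape
deviations from Lorentzian. Passing studies therefore demonstrate the
correctness and calibration of the processing chain under the stated
model, not robustness to every artifact of real spectra. The constant
relaxation delay is configurable (default 40 ms, a typical value for this
experiment class).

## Sampling schedules

Plane assignment is "flat": points are stratified as evenly as the total
allows across CPMG planes (remainders randomized). Within a plane,
indirect coordinates are drawn without replacement with density
`prod_d exp(-t_d / t_match)`, `t_match = 100 ms`. Two standard safeguards
are built in: the first time-domain point of every plane is always
measured, and the union of the schedule covers every indirect evolution
time of every dimension (swap-repair after the draw, can be disabled).
Without marginal coverage the shared shape vectors of the decomposition
are unconstrained at the missing times, which distorts lineshapes and,
through the per-plane amplitude fits, the dispersion curves themselves.
A "coupled" mode reuses one indirect coordinate set on every plane.

## co-MDD reconstruction

All CPMG planes are modelled jointly as a sum of components, each the
tensor product of one normalized shape vector per dimension (direct
dimension in the frequency domain, transformed first; indirect dimensions
in the time domain) with a real per-plane amplitude. Shapes are shared
across planes — peak positions and lineshapes do not depend on the CPMG
frequency — so the dispersion lives entirely in the amplitudes.

Fitting is alternating least squares restricted to the sampled
coordinates: direct shapes, then each indirect shape matrix, then the
amplitudes, each sub-problem a Tikhonov-regularized linear solve with the
penalty scaled to the Gram diagonal (`lambda = 1e-4` by default; 2000
iteration cap; stop when the relative residual change drops below 1e-9).
Shapes are renormalized every sweep, with norms absorbed into the
amplitudes and phases rotated so the largest element of each constrained
shape is real positive (the last indirect factor keeps the residual
phase). With many strongly overlapping components, randomly initialized
ALS stalls in the classic degenerate "swamp"; `comdd_fit` therefore
accepts expected peak positions — available in any quantitative RD
workflow — and seeds the leading components with idealized lineshapes,
leaving spare randomly-initialized components for noise. Validation
studies use `n_components = n_peaks + 2`.

## IRLS with virtual echo

Per plane and per direct-frequency column, the sampled indirect points
constrain a real spectrum through the virtual-echo construction (length-2n
conjugate-symmetric extension; here the model grid is 4x the acquired
length for one indirect dimension, 2x per dimension for two, so the model
can represent a signal that keeps decaying past the measured window).
Phase-pure columns are formed from the two States combinations: the
absorptive and dispersive direct-dimension parts each modulate the
indirect dimension with a real coefficient, satisfying the VE assumption
exactly; both are solved and recombined. Weights follow
`w = (x^2 + eps^2)^((p-2)/2)` with `p = 0.5`, `eps` halved each of 30
iterations from the initial minimum-norm solution's maximum down to a
1e-3 relative floor (the floor bounds the condition number of the
weighted solves). Missing time-domain points are synthesized from the
solution, measured points are kept, and the completed data run through
the reference FT path, so fully sampled input reproduces `full_ft`
exactly. Iterations run only on columns whose measured power exceeds
1e-4 of the maximum; empty columns keep the minimum-norm completion.

## Quantification

Peak heights are read at the maximum grid point within a search window on
the reference plane, and at that same grid point on every plane (the
position-invariance assumption again); no sub-grid interpolation.
`R2,eff = ln(I0/I)/T`; non-positive intensities are flagged and excluded,
not dropped silently. Repeated CPMG frequencies are averaged before
fitting; their spread feeds the classical pooled global error (per-pair
SD, i.e. |difference|/sqrt(2), floored at 1e-6). Validation studies
exclude peaks whose nearest neighbour is within 2.5 linewidths in every
dimension simultaneously, the standard practice for crowded spectra.

## Resampling errors

Delete-d jackknife: 20 trials each omit d = 17.5% of the N NUS points
(redrawn if a plane would empty, and, where feasible, if an indirect
evolution time would lose its last sample — deleting the last constraint
of a shape row measures coverage loss, not data uncertainty). Trial
intensities are read at the grid points of the full-set reconstruction.
The per-peak, per-plane error is the trial SD scaled by the inflation
factor `F = sqrt(N/d)`; the raw SD underestimates because trials share
most of their data.

Targeted acquisition: a nested random ordering of the NUS points is
processed at increasing fractions (3.3% to 8.3% in 1% steps by default);
the raw RMS intensity change between successive steps underestimates the
current step's error by the nested-sampling factor
`sqrt((n_k - n_{k-1})/n_{k-1})` (variance ~ 1/n), so the reported TA error
is the raw difference scaled by its inverse. After scaling, the TA and
per-step jackknife tracks agree to ~20% on synthetic data.

Calibration: on 8.3%-NUS HNCO-type data at the benchmark scale (30 x 40
indirect points, ~1200 NUS points) the inflated jackknife sigma_R2 runs
~20-30% above a fixed-schedule, noise-only Monte-Carlo truth. The excess
is not a residual deterministic error (delete-d trials on noiseless data
move the intensities by <2% of sigma): it is the re-weighting of the
fixed noise realization as the reconstruction's effective interpolation
weights shift with the deleted subset. The effect grows sharply on
smaller grids (to ~40-80% when the point count halves or worse) and
shrinks as the NUS level rises and the reconstruction becomes
noise-dominated; jackknife errors should therefore be read as mildly
conservative, increasingly so near the sparsity limit — consistent with
the construction of subsampling estimators, whose trials probe spectrum
quality at a 10-20% lower NUS level.

## Problem sizes

The validation studies use 2D grids of 64 x 48 points with 16 planes
(14-17 residues), a 48 x (30 x 40) 3D grid for jackknife calibration
(8 residues, ~1200 NUS points, two system draws pooled), and a
24 x (32 x 16) 3D grid for targeted acquisition (4 realizations, 5
jackknife trials per step); ALS runs 150-300 sweeps there, which is
within ~2% of the converged peak heights. These sizes were chosen so every study completes in minutes on a
single CPU while staying in each method's operating regime.

## Known limitations

- co-MDD quality degrades sharply once the schedule cannot cover the
  indirect evolution times (e.g. 8.3% NUS on a 2D 48-point grid is
  structurally infeasible; the sparse levels of the benchmarks are 3D).
- The time-domain-regularized decomposition variant (R-MDD) is not
  implemented; at extreme sparsity it would be the appropriate tool.
- The ALS peak-seeded initialization assumes approximately correct
  expected positions (within a few linewidths); grossly wrong peak lists
  degrade to the random-initialization behaviour.
- Jackknife errors inherit the reconstruction's subset sensitivity (see
  above) and should be read as mildly conservative.
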