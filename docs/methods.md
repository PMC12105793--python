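# Methods

## The haemodynamic model

CVSim-6 is a closed-loop, six-compartment lumped-parameter (0D) model of the
adult circulation: left ventricle (l), systemic arteries (a), systemic veins
(v), right ventricle (r), pulmonary arteries (pa) and pulmonary veins (pv).
Each compartment is a two-element Windkessel with capacitance `C`, unstressed
volume `V0`, and a shared inflow/outflow resistance `R` to its neighbours;
the four heart valves (mitral, aortic, tricuspid, pulmonary) are ideal diodes
written as indicator functions on the pressure difference — no regurgitation,
no smoothing.  There are no atrial compartments and no respiratory coupling.

The six state variables are the compartment pressures
`P = [Pl, Pa, Pv, Pr, Ppa, Ppv]`.  Mass balance per compartment gives

    d/dt [ C_i (P_i − P_ref,i) ] = Q_in,i − Q_out,i ,

which for the two ventricles (time-varying `C(t)`) carries the extra
`−(P − Pth)·dC/dt / C` term.  The transthoracic pressure `Pth` (default
−4 mmHg) is the reference pressure of the intrathoracic compartments (both
ventricles and the pulmonary circulation); the systemic arteries and veins
are referenced to atmospheric.  With these references the total *stressed*
volume `Σ C_i (P_i − P_ref,i)` is conserved exactly by the continuous
dynamics — the package treats this as its primary discretization diagnostic
(the reference solver keeps the relative drift below 1e-6 over 12 cycles).

Units: integration is carried out in CGS (Barye, ml, s) with
1 mmHg = 1333.22 Barye; pressures are mmHg at every user-facing interface.
Cardiac output is reported in L/min and vascular resistances in dyn·s/cm⁵
(numerically identical to Barye·s/ml).

### Ventricular activation

The driving ventricular capacitances are C1-smooth raised-cosine
interpolations: over a cycle of length `Ttot = 60/Hr` the capacitance starts
at its diastolic value, falls to the systolic value at end systole
`t = rsys·Ttot` (`rsys` = systolic fraction, default 0.33), and recovers over
diastole, with an analytic derivative and exact periodicity.  Left and right
ventricles are perfectly synchronized.  The exact waveform used by the
original formulation was not available to this implementation; the raised
cosine satisfies every stated property of that waveform (endpoints, minimum
at end systole, periodicity, smoothness), and reproduces the published
spectral landmarks of the linearized system to print precision (see below),
which is the strongest observable check available.

### Initial conditions and burn-in

Initial pressures solve a 6×6 linear system: five rows equalize the
transmural pressure `P_i − P_ref,i` across compartments and the sixth
distributes the stressed volume, `Σ C_i (P_i − P_ref,i) = TBV − Σ V0`, with
capacitances at their diastolic values.  Total blood volume `TBV` defaults
to 5000 ml (standard adult value) and is configuration, never hard-coded.
With `TBV = Σ V0` every pressure equals its reference pressure.

This algebraic start conserves mass but sits away from the periodic orbit;
the slow systemic↔pulmonary volume redistribution (≈10 s time constant)
would still be settling during the last of 12 cycles.  `simulate` therefore
equilibrates by default for 24 cycles with a cheap adaptive integration,
restores exact stressed-volume conservation by a uniform pressure shift
(legitimate because the burn-in ends at a cycle boundary), and only then
integrates the reported cycles.  The published analyses describe their
12-cycle runs as fully converged, so the burn-in reproduces the intended
regime; it changes none of the spectral landmarks and can be disabled
(`burn_in_cycles = 0`).

### Solvers

* `radau` (default): scipy's adaptive fifth-order implicit Runge-Kutta with
  the analytic Jacobian, rtol 1e-8 / atol 1e-6 Barye — the reference scheme
  for this stiff system.
* `lsoda`: adaptive stiff/non-stiff multistep solver, rtol 1e-7 / atol 1e-3
  in the data-generation profile; ~10× faster with ≤1e-4 relative effect on
  the clinical outputs.  Used for bulk dataset generation only.
* `rk4`: fixed-step explicit classic Runge-Kutta at the output step,
  provided to demonstrate the instability of explicit integration (at a
  20 ms step the computed ventricular pressure drops below the arterial
  pressure during ejection, nearly closing the aortic valve).

The right-hand side and Jacobian callbacks are numba-compiled; a pure-numpy
reference implementation is kept and consistency-tested against them.

### Clinical outputs

Sixteen targets are extracted from the final three cycles (`Tp`) of the
dense 1 ms output grid: extrema for the systolic/diastolic arterial,
right-ventricular and pulmonary pressures and left-ventricular volumes;
trapezoidal time averages for wedge pressure (mean `Ppv`), central venous
pressure (mean `Pv`) and cardiac output (mean systemic flow); right
ventricular end-diastolic pressure as `Pr` at the last sample of `Tp`;
ejection fraction `(Vl_dia − Vl_sys)/Vl_dia`; and
`SVR = (mean Pa − Pcvp)/CO`, `PVR = (mean Ppa − Pw)/CO`.  On a converged
periodic orbit the mean flow through each vascular bed equals CO, so SVR and
PVR reduce exactly to `Ra` and `Rpv` — a useful internal consistency check.
If CO ≤ 0 the resistances are flagged invalid (NaN), never ±∞.

Each output carries a literature-based measurement standard deviation
(e.g. 3 bpm for heart rate, 1.5 mmHg for arterial pressures, 0.02 for LVEF)
used by the noise model and the imputation tolerance.

## Stiffness analysis

Freezing the valve indicators at the current state turns the dynamics into
`dP/dt = A(t) P + b(t)`, with `b` carrying the `Pth·dC/C` forcing of the
ventricular rows.  Along the last two cycles of the reference run the 6×6
`A(t)` is eigen-decomposed at every millisecond sample; the spectrum is real
(asserted to a relative imaginary tolerance of 1e-8).  Eigenvalues are
sorted by |Re| descending, ties broken by signed value.  The stiffness ratio

    SR(t) = max|Re(λ)| / min|Re(λ)|

uses the smallest-magnitude eigenvalue above a tolerance (default 1e-14) in
the denominator, because conserved pressure combinations produce exact
zeros.  SR is undefined (NaN, flagged) if the whole spectrum is below
tolerance.  Intrinsic timescales are `τ_i = 1/|Re(λ_i)|`; during ejection
the two fastest agree with the resistor-capacitor constants
`R·C_j C_k/(C_j+C_k)` at the ventricular outflows (systolic ventricular
capacitance at the outflow valves, diastolic at the inflow valves).

At the default parameters the implementation reproduces the published
landmarks: λ1 ≈ −521.1 s⁻¹ and λ2 ≈ −355.9 s⁻¹ at the maximum-SR instant
(t ≈ 9.442 s of 10 s; print value 9.444 s), λ1 ≈ −4.39 s⁻¹ at the
minimum-SR instant (t = 8.618 s), τ1 ≈ 0.0019 s, τ2 ≈ 0.0028 s, RC
constants 1.92 ms and 2.82 ms.  SR rises through systole, peaks just before
the semilunar valves close, and collapses at the onset of isovolumetric
relaxation.

## Training data

Inputs are drawn from uniform box priors centred on the default parameter
vector: the *synthetic* preset varies capacitances ±50% and everything else
±30%; the *ehr* preset widens to heart rate −20/+60%, capacitances and
resistances −80/+60%, remaining parameters ±30%.  Intervals around negative
references (Pth) are ordered automatically.  Outputs come from the exact
simulator; rows whose integration fails are dropped and logged (>50%
failures aborts).  Splits reserve a 4000/54000 validation fraction and
divide the remainder 3:1 into training and online testing — 37500/12500/4000
at the full scale, the same ratios at any reduced scale.  Normalization is
per-feature z-scoring estimated on the training split only and stored with
the model.

Measurement noise is zero-mean, uncorrelated, heteroskedastic Gaussian in
physical output units: `y' = y + δ·s⊙ε` with `s` the per-component standard
deviations above and `δ` a global scale.  Noise is applied before
normalization, redrawn every epoch, and never used for emulator training
(the forward map is deterministic).

## The inVAErt components

`torch` is not available in the execution environment, so the four networks
run on a small in-package reverse-mode autodiff engine (`autograd.py`,
property-tested against finite differences) with an Adam optimizer.

* **Emulator** `NN_e`: MLP (tanh hidden layers, 96×3 at desk scale) from
  normalized parameters (23) to normalized outputs (16); plain MSE on
  noiseless pairs.
* **Flow** `NN_f`: Real-NVP with affine coupling layers (4 at desk scale,
  8 at full scale) and alternating
  even/odd masks on the 16 output coordinates; conditioner MLPs start with
  zeroed output layers so the untrained flow is the identity (its density
  is exactly standard normal — a fixture for tests); log-scales are bounded
  by `c·tanh(·/c)`, c = 2.  Trained by exact maximum likelihood through the
  inverse pass; densities and samples are used for imputation.
* **Encoder** `NN_v`: MLP producing `(μ, log σ²)` of a `dim_w = 7` latent
  variable — the information gap `dim(v) − dim(y) = 23 − 16` that the
  latent space must span; `w = μ + ε⊙σ`.
* **Decoder** `NN_d`: MLP from `[y, w]` (16+7) to the 23 parameters.

Training order follows the objective structure: emulator first (frozen
thereafter), flow independently, then encoder+decoder jointly with

    β_d·|v − v̂|² + (β_v/2)·KL(q(w|v) ‖ N(0,I)) + β_r·|y' − NN_e(v̂)|²

summed per sample and averaged over batches.  The re-evaluation term
backpropagates through the frozen emulator (its weights are excluded from
the optimizer; tests assert bit-equality before/after).  The loss weights
(β_d = 0.1, β_v = 0.5, β_r = 10 at desk scale) were selected by held-out
validation of the decode-then-re-evaluate error: the published
hyperparameters live in an appendix that was not available, and the choice
is therefore the package's own.  Rationale: under structural
non-identifiability the input-reconstruction term cannot (and should not)
be driven to zero, while output consistency through the emulator is the
quantity the method is judged on; the KL weight controls how faithfully
standard-normal latent draws cover the learned posterior at inversion time.
The EHR profile adds ℓ2 weight decay (1e-5), halves β_d and sets δ = 0.5,
the anti-overfitting adjustments appropriate for noisy, misspecified data.

One master seed fans out (via `SeedSequence`) into independent streams for
initialization, batch shuffling, reparameterization draws and noise.

## Inversion, manifolds, imputation

For a complete observation `y`, `invert` decodes `Nw` standard-normal
latent draws against the fixed `y`, tracing the non-identifiable manifold
`M_y = {v : f(v) = y}`.  `verify_solutions` re-evaluates the decoded
parameters through the exact simulator (synthetic studies; failures are
recorded and excluded with a count) or the frozen emulator (EHR pipeline,
~200× faster and crash-free) and reports per-component absolute-error
statistics plus aggregate relative errors.

Two relative-error aggregations are provided and used deliberately:

* `max_relative_error`: max over components and solutions of `|Δ|/|y|` —
  the aggregation used for the published single-number reproduction targets
  (0.139% for the 100-draw inversion of a flow-sampled observation, 0.408%
  for imputed completions), whose observations have no near-zero components.
* ℓ2 relative error `‖Δ‖/‖y‖` per solution — the distribution reported for
  the emulator and the metric used for the desk-scale gates, because
  held-out validation observations routinely contain near-zero components
  (right-ventricular diastolic pressure crosses 0 mmHg inside the prior
  range), on which a componentwise ratio is unbounded regardless of
  absolute accuracy.

`manifold_spectrum` column-centres the decoded sample matrix (no variance
scaling) and reports singular values with cumulative energy
`CE_n = Σ_{i≤n} s_i² / Σ s_i²`.  Identifiability shows up as range ratios:
across a manifold, `Ra` and `Rpv` vary little relative to their prior
widths while `Cv`, `Cr_sys`, `Cpv`, the ventricular inflow/outflow
resistances and most unstressed volumes span most of theirs.

Missing components are completed by density-ranked rejection: draw `M`
candidates from the flow, keep those whose observed components all fall
within `match_tol` (default 3) measurement standard deviations of the
measurements, overwrite observed entries with the measurements exactly,
rank by flow log-density, return the top `K`.  An empty match set falls
back to the nearest candidates with a warning rather than failing.  The
EHR pipeline applies this per patient (only patients with more than 10 of
16 observed attributes are inverted; the rest are listed as skipped),
decodes `Nw` draws per completed observation, re-evaluates through the
emulator, and scores per-attribute errors
`e_k = (1/|P_k|)(1/Nw) Σ_{q∈P_k} Σ_i |y_k^(q) − Ŷ_ik^(q)|` over the
patients `P_k` observing attribute `k` (undefined, not zero, when `P_k` is
empty).

## Synthetic EHR generator

The EHR fixture emulates the structure of the clinical cohort the method
targets: 84 patients, per-attribute Gaussian noise at the Table of
measurement standard deviations scaled by δ (default 0.5), and per-attribute
independent missingness with observation probabilities shaped like the
cohort's counts (routine attributes ≈ always present; right-heart diastolic
pressure ≈ 25%; central venous pressure and diastolic volume ≈ 7%; systolic
ventricular volume never observed).  Ground-truth parameters are retained
for recovery tests.  What it does **not** emulate: model misspecification
(every patient is exactly a CVSim-6 solution plus noise), correlated
missingness patterns, out-of-range measurements, and reporting errors — so
a green pipeline test establishes the mechanics and noise robustness of the
inversion, not clinical validity on real records.

## Scales, budgets and reproducibility

The *desk-scale* profile (2000 simulated pairs, the network sizes above,
minutes on one CPU) is the CI configuration; the *full-scale* profile
mirrors the published 54000-pair studies and costs hours on one CPU (the
original emulator alone trained for ~3.8 h).  Full-scale accuracy targets
(e.g. max emulator validation error ≈1%, 0.139%/0.408% inversion errors)
are not reachable at desk scale; the desk-scale gates are: emulator median
ℓ2 validation error ≤5% (measured ≈0.3%), decode-then-re-evaluate median
ℓ2 error ≤2% on held-out observations, imputation coherence ≤3%, and the
identifiability range ordering.

Every stochastic step takes an explicit seed; datasets and model bundles
serialize to HDF5 with their configuration and provenance, and reloading a
bundle reproduces all four networks' outputs bit-identically.

## Known limitations

* The ventricular activation waveform and initial-condition system are
  reconstructed from their stated properties, not copied from the original
  appendix; all observable landmarks agree, but sub-print-precision
  differences in e.g. mid-diastolic eigenvalue transients are possible.
* The decode-then-re-evaluate accuracy at desk scale is floored by the
  emulator's own error (the re-evaluation loss trains through it).
* The componentwise-max relative error on held-out observations is
  dominated by near-zero right-heart diastolic pressures (~4-5% at desk
  scale even though the absolute errors are ~0.05-0.07 mmHg).
* The numpy autodiff engine is single-threaded; full-scale training is
  possible but slow, and no GPU path exists.
* Real clinical tables are accepted in CSV shape only; no unit conversion
  or plausibility screening of foreign data is attempted.
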