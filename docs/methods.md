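# Methods

`mfdlab` implements the quantitative chain used to characterise minor,
flexible conformational states of a tightly bound protein complex — in
the motivating application, p27 bound to Cdk2/cyclin A — from
single-molecule multiparameter fluorescence detection (MFD), filtered
fluorescence correlation spectroscopy (fFCS) and isothermal titration
calorimetry (ITC).  No raw instrument data ships with the package;
every analysis stage is validated against a synthetic-data generator
with known ground truth.

## The synthetic measurement (simkit)

**Transit model.**  Molecules enter the confocal volume as a Poisson
process with rate `occupancy / t_diff` and dwell for an exponentially
distributed time with mean `t_diff` (default 1.7 ms, the measured
diffusion time of the labelled complex).  Within a transit the detected
photon rate is constant (`brightness`, default 100 kHz/molecule): a
top-hat detection volume.  This preserves exactly the burst-duration
and photon-count statistics that burst selection, time-window tiling
and PDA consume, at a small fraction of the cost of Brownian paths.
The ACF of such a stream decays as `exp(−τ/t_diff)`, so FCS fits of
top-hat streams use the exponential transit term.

For FCS-shape calibration an optional `profile="gaussian3d"` mode runs
Brownian dynamics through a 3D-Gaussian detection profile (waist
0.5 µm, axial aspect 4 by default, periodic box of 12 waists, step
`t_diff/100`);
its ACF follows the standard `(1+τ/t_d)⁻¹(1+τ/(s²t_d))^(−1/2)` law.
The periodic box holds a fixed number of molecules (~25 at occupancy
0.08), which depresses the correlation baseline by ≈1/N; the
relaxation fitter therefore carries a free baseline.  This mode
supports single-state models only — it exists to verify that the
diffusion-time calibration path recovers `t_diff`.

**Conformational exchange.**  States interconvert as a continuous-time
Markov chain with the supplied rate matrix (s⁻¹); the trajectory starts
from the stationary distribution.  Each state visit draws one
quasi-static donor–acceptor distance from a Gaussian
`N(R_DA, sigma_DA)` — the same quasi-static assumption PDA makes for
its half-widths, so generator and fitter share one definition of
"half-width" (the Gaussian σ).

**Photon physics.**  A photon emitted in a visit with efficiency
`E = 1/(1+(R/R0)^6)` (R0 = 53.0 Å) is red with probability E (modified
by the green/red detection ratio if ≠1).  Micro times are IRF
(Gaussian, default σ = 0.25 ns centred at 1 ns) plus an exponential
dwell with the FRET-shortened donor lifetime `tau_D·(1−E)`;
FRET-sensitised red photons add an acceptor dwell (1.7 ns).
Polarisation splits by the steady-state Perrin anisotropy
`r = r0/(1+τ/ρ)` of the emitting dye, via
`P(parallel) = (1+2r)/(2+r)`; sensitised acceptor emission uses a
transfer-depolarised fundamental anisotropy of 0.1.  Background is
Poisson per channel (default 0.3 kHz) with uniform micro times.  The
excitation period is 15.625 ns (64 MHz laser).

**Defaults as study conditions.**  Occupancy defaults to 0.002
(~1 burst/s, the dilution used in the measurements).  Simulations in
the tests and the acceptance script use occupancy 0.02–0.05 — still
dilute single-molecule conditions (transit overlap ~2%) — so that
thousands of bursts accumulate in minutes of simulated time rather
than hours; this compresses measurement time, not physics.

**ITC.**  Injection heats follow the exact 1:1 isotherm with
displacement dilution bookkeeping (each injection of volume v dilutes
cell contents by `1 − v/V0`), the protocol of the experiments (0.5 µl
then 3.1 µl injections of 10 µM titrant into 1 µM complex, 200 µl
cell), Gaussian heat noise, and a linear ΔH(T) with slope ΔCp across
the 5–25 °C series.

## Burst analysis (bursts)

Burst search is an all-photon sliding-window filter: a photon is
in-burst when the running mean of interphoton times over 30 intervals
falls below 0.1 ms; runs are then extended over adjacent photons with
individually small gaps (the centred smoothing otherwise clips half a
window from each edge), and kept if they hold ≥60 photons above the
expected background.  The criterion is deliberately simple; none of
the downstream statistics depend on its details because PDA re-weights
by the observed photon-count distribution.

Per segment (burst or Δt window): the donor/acceptor ratio and
`⟨R_DA⟩_E = R0·(γF_D/F_A)^(1/6)` after background, crosstalk and
direct-excitation correction (zero-acceptor segments are right-censored
at 150 Å and excluded from PDA, mirroring the donor-only region of the
2D histograms); the scatter-corrected anisotropy
`r_D = (gF_∥−F_⊥)/((1−3l₂)gF_∥+(2−3l₁)F_⊥)` with `l₁ = l₂ = 0` by
default (instrument-specific values are not published in the main
text, so the standard MFD correction is used and documented as such);
and `⟨τ_D(A)⟩_f` from a maximum-likelihood mono-exponential fit of the
green micro times, using an exponentially-modified-Gaussian density
(analytic IRF convolution) truncated to the excitation period, with a
uniform micro-time floor carrying the expected background fraction.

## Probability distribution analysis (pda)

For every observed window photon total N, each state's Gaussian
observable distribution (21-node Gauss–Hermite quadrature, truncated
at physical bounds) is mapped to a success probability — green
detection for FRET, parallel detection for anisotropy — and convolved
with the Binomial(N, p) counting law; the discrete outcomes are pushed
through the same estimator used on the data and accumulated into the
histogram bins, weighted by the empirical count distribution.  Only
shot noise is predicted; nothing about the histogram width is fitted.
Optional acceptor-brightness variation enters as a multiplicative
Gaussian factor on the red efficiency (7-node quadrature; default off).
A unit test and the acceptance suite verify the prediction against a
10⁶-draw Monte-Carlo of the generative process (total-variation
distance < 0.01).

Fitting minimises Poisson-weighted histogram residuals with bounded
trust-region least squares, 8 seeded multi-starts, state means and
half-widths always global across the Δt ∈ {1, 2, 3} ms datasets and
fractions global by default (`shared="per_window"` frees them per Δt;
a static species must then show Δt-independent fractions, which is
tested).  The reported reduced χ² is evaluated over bins with
predicted count ≥ 1, where the Poisson-weighted residual has unit
variance; including the many near-empty tail bins would deflate the
statistic.  Windows are compressed to ≤40 weighted representative
photon totals before fitting (quantile binning), which changes
predictions negligibly and bounds the fit cost.  Model comparison
ranks by χ²_r with a parsimony rule: more states win only on a >10%
improvement, ties go to fewer states.

Background in PDA: window observables use raw counts and the PDA model
assumes zero background.  At the study conditions (0.3 kHz/channel
against ~100 photons/ms in-burst) the induced distance bias is ≪1 Å;
strong-background data should be windowed more tightly instead.

## Static FRET lines and the dynamic shift (fretmodel)

Static lines are stored verbatim as coefficient records
`⟨R_DA⟩_E(τ) = (1/(τ₀eff/p(τ)−1))^(1/6)·R0` with quadratic
`p(τ) = a₂τ²+a₁τ+a₀`; the two built-in sets (unphosphorylated and
pY88) are the published ones, and their valid lifetime range is
computed from the positivity of the inner polynomial at load time.
The printed "+ −0.1618" is read as adding a negative constant.  An
ideal-dye line (`a₂=a₀=0, a₁=1`, τ₀eff = donor-only lifetime) is the
correct comparator for generator data, whose dyes have no
linker-broadened decay: against the published lines an ideal static
simulation sits ~1.3 Å off the curve, which would masquerade as a
shift.

The dynamic-shift diagnostic reports, per record, the distance-axis
deviation from the line, **signed positive on the long-lifetime
(rightward) side** (`line(τ) − R_DA`): sub-window exchange averages
efficiencies linearly but weights lifetimes by fluorescence, so mixed
records fall right of the line; a two-sided sign test against median
zero summarises significance.  Slow exchange (windows mono-state)
centres on the line.

## Filtered FCS (ffcs)

Species filters solve the weighted unmixing problem
`F = (D W Dᵀ)⁻¹ D W` over (channel, micro-time-bin) decay patterns,
with `W = diag(1/M)` for the mixture pattern M; `F Dᵀ = I` holds by
construction (unbiasedness: a pure species returns weight 1 for
itself, 0 for others).  Near-collinear patterns abort with the
condition number.  Reference patterns come from simulated pure-species
streams (ground truth available); on real data they would come from
subpopulation-gated bursts.  A background/scatter pattern is included
as its own species whenever the analysed stream contains appreciable
background — without it the unmixing projects background photons
asymmetrically onto the conformational species and can drive one
species' total weight (and hence its correlation normalisation) toward
zero — and the mixture pattern M is taken from the analysed stream
itself.

The correlator counts photon pairs directly on a quasi-logarithmic
multi-tau grid (16 linear lags per cascade, then doubling), using
cumulative filtered weights so all species pairs share one pair
search.  Left photons are restricted so the full lag window fits in
the trace (no edge bias), and curves are normalised so uncorrelated
Poisson photons give G = 1.  Statistical weights are the spread over 8
trace segments; bins seen by a single segment inherit the largest
well-estimated σ.

Relaxation fits use
`G(τ) = offset + a·diff(τ)·(1 + Σ Aᵢ·exp(−τ/tᵢ))`, with the transit
term matching the generator mode, seeded multi-starts, and relaxation
times capped at twice the diffusion time (slower terms are masked by
the transit envelope and degenerate with its amplitude).  For species
curves the diffusion time is pinned to the value fitted on the
unfiltered intensity ACF of the same stream — exchange does not
modulate total intensity, so that ACF isolates diffusion.  Negative
amplitudes flag anticorrelation, the exchange signature in the sCCF.
Exchange times are estimated by a global fit of the four species
curves (two sACFs, two sCCFs) with a shared relaxation time and free
per-curve amplitudes and baselines (`fit_relaxations_global`) —
markedly more precise than averaging independent single-curve fits
when per-curve pair statistics are thin.  At microsecond relaxation
times a single 100 s trace still carries ~15–20% estimator spread
(pair counts at µs lags are small), so µs-scale recoveries average
several measurement repeats.

## Thermodynamics (thermo)

The single-site fit shares its isotherm/dilution model with the
simulator, so noiseless round trips are exact; K_D is fitted in log
space (hence geometric means across replicates).  ΔG = RT·ln K_D
(R = 1.9872×10⁻³ kcal mol⁻¹ K⁻¹), −TΔS = ΔG − ΔH, ΔCp is the OLS slope
of ΔH over T.  The Spolar–Record dissection uses
`ΔS_HE = 1.35·ΔCp·ln(T/386 K)`, `ΔS_rt = −50 cal mol⁻¹ K⁻¹` and
−5.6 cal mol⁻¹ K⁻¹ per folding residue; all constants are overridable
because small variations in them shift ℜ by 5–10%.  Two evaluation
conventions are provided: dissection at the measurement temperature
(default, 298.15 K for the published table) or extrapolation of the
association entropy to T_s; the published values are consistent with
the former.  With the defaults the three table rows give ℜ ≈ 93, 77
and 44 residues against published 100±8, 81±4 and 48±2 — inside each
±2 SD and strictly ordered.

## Accessible volumes and SASA (avsim)

The AV search marks a grid point allowed when (a) Dijkstra geodesic
distance from the attachment atom, computed through linker-clearance
nodes over a 7×7×7 prime-offset stencil (chamfer error ≈1%, versus 8%
for 26 neighbours), stays within the linker length, and (b) the dye
sphere is clash-free; several dye radii give AV3-style fractional
weights.  Defaults (linker 20 Å, width 4.5 Å, dye radius 3.5 Å, grid
0.9 Å) follow common practice for maleimide-linked visible dyes and
are explicit assumptions.  `⟨R_DA⟩_E` averages the Förster efficiency
over weighted position pairs (seeded Monte-Carlo subsampling above
5×10⁶ pairs) and is reported with the mean-position distance R_mp.

SASA is Shrake–Rupley with Fibonacci sphere points (960 default),
1.4 Å probe and Bondi radii; relative SASA normalises a residue's
summed atomic area by extended-tripeptide reference values.  A free
residue therefore reads ≥100%.  An independent implementation
(biotite) agrees within 1 percentage point on test fixtures.

## What the synthetic data does not capture

Dye photophysics beyond mono-exponential decay (triplet blinking,
acceptor dark states, linker-broadened donor decay), detector dead
time and afterpulsing, pulsed interleaved excitation, real IRF shapes,
and the instrument's calibrated crosstalk/γ (both default to ideal
values but are configurable).  Passing recovery tests therefore
demonstrates correctness of the estimators under shot noise, diffusion
statistics and exchange kinetics — not robustness to every instrument
artefact.

## Numerical choices and degenerate inputs

Zero-acceptor windows censor at 150 Å; lifetime fits need ≥20 green
photons (else NaN); anisotropy states truncate to (−0.2, 0.4) and
distances to ≥1 Å; empty AV clouds (buried attachment) warn and return
an empty, flagged cloud; all-zero ITC heats flag K_D unidentifiable;
c-values outside [1, 10⁴] warn.  All stochastic stages take explicit
seeds; identical seeds reproduce results bit-for-bit.

## Problem sizes

Test and acceptance runs use 100–300 s simulated traces (≥5000 PDA
windows, ~6×10⁵ photons per fFCS trace, 10⁶-draw Monte-Carlo oracles),
chosen so each recovery claim is decided by its stated tolerance
rather than by sampling noise.  The diffusion-time calibration
averages two independent 120 s Gaussian-profile traces at axial aspect
3, where the estimator's seed-to-seed spread (~5% per trace, dominated
by slow axial occupancy fluctuations) leaves a comfortable margin
inside the 10% recovery tolerance.
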