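# Methods

This note documents the models behind each analysis stage, the synthetic
data they are validated against, the numerical choices, and the known
limitations. Units: concentrations molar (readers convert µM at the
boundary), energies kJ/mol (ΔS in J/mol/K), reaction coordinates nm,
temperatures kelvin. R = 8.314 J/mol/K; k_B·T = 2.4789 kJ/mol at 298 K.

## Binding model and titration generator

The generator draws from the exact 1:1 mass-action model with ligand
depletion: the bound complex [PL] solves
`Ka·([P]0−[PL])·([Q]0−[PL]) = [PL]` (numerically stable smaller root of
the quadratic), and static quenching reduces the tryptophan emission in
proportion to the bound protein fraction, `F = F0·(1 − [PL]/[P]0)`. This
makes two identities exact, and they anchor the tests:

- `(F0−F)/F = Ka·[Q]_free` at every titration point, so the double-log
  regression with free-ligand correction recovers n = 1 and Ka exactly
  on noise-free data;
- dynamic (collisional) quenching multiplies an independent factor
  `1/(1 + K_D·[Q]_free)`; "mixed" mode multiplies both.

Depletion is modelled exactly rather than by the excess-ligand
approximation because the default protein concentration (4 µM) is
comparable to the ligand range (0–17 µM, 1 µM steps): the apparent
Stern–Volmer constant vs *total* ligand then falls below Ka (by ~10–15%
at these concentrations) and converges to Ka as [P]0 → 0 — a real
feature of such experiments that the tests assert, and a plausible
reading of published tables in which K_SV < Ka for the same system.

Inner-filter attenuation is applied as the exact inverse of the
correction formula `F_corr = F_obs·10^((5·A_ex+A_em)/10)`, with
absorbances built as ε·[Q]_total·path and recorded in the output, so
correction-after-generation is an identity to machine precision. The 5:1
exponent weighting matches the 10 × 2 mm cuvette protocol it comes from;
the more common symmetric form would be `(A_ex+A_em)/2`. The physical
plausibility of the geometry is not adjudicated — the correction and the
generator are exact inverses by construction.

Noise is multiplicative Gaussian with coefficient of variation
`noise_cv`; F0 is taken from the (noisy) zero-ligand point, as an
experimenter would. Default study conditions: [P]0 = 4 µM, ligand 0–17
µM in 1 µM steps, T ∈ {288, 298, 308} K, ε_ex = 16 500 M⁻¹cm⁻¹ at the
ligand's absorption band when attenuation is enabled.

Emission spectra are modelled as two Gaussian bands — protein at 340 nm
(FWHM 28 nm), amplitude following the titration; ligand at 485 nm (FWHM
43 nm), amplitude proportional to total ligand. The bands' half-maximum
intervals are disjoint, so peak extraction at 340 nm recovers the
titration series; the ligand's emission amplitude per molar is a free
cosmetic parameter (its quantum yield is not specified by the protocol
emulated).

## Fitting choices (quenching)

All fits use the linearised coordinates of the classical procedure, not
nonlinear least squares on raw intensities; a nonlinear 1:1 refit is
available as a labelled cross-check (`nonlinear_binding_refit`).

The double-log regression is OLS by default (faithful to the published
plots). Under constant-CV intensity noise the log-coordinate variance is
∝ (F0/(F0−F))², i.e. low-quench points are ~10× noisier than high-quench
points; `weighting="fb2"` applies the corresponding inverse-variance
weights (w = fb²) on the same coordinates and is the recommended
estimator for noisy data (the pipeline and CLI use it). It is identical
to OLS on noise-free data. Logarithms are base 10; n = −slope and
log10 Ka = intercept/n, with SEs propagated to first order from the
regression covariance including the slope–intercept correlation.

Points with F ≥ F0 are excluded from the double-log fit (log of a
non-positive number) with a warning, but kept in the Stern–Volmer fit;
fluorescence enhancement beyond 5% over F0 is flagged. A non-positive
free-ligand estimate (bound fraction × [P]0 exceeding total ligand)
aborts the fit naming the offending point.

Mechanism classification regresses K_SV on T, weighted by the fits' SEs
(known-variance formulas — no residual rescaling, since with three
temperatures a residual-based scale estimate would have one degree of
freedom). "Unchanged" is operationalised as |slope|/SE ≤ 2; a
significant positive slope reads dynamic, or mixed when any per-
temperature Stern–Volmer R² falls below 0.98. An exactly flat panel is
protected by a relative-flatness guard (|slope|·ΔT/mean K_SV < 1e−9 →
static) so that floating-point jitter cannot produce a spurious trend.

Two honest limitations of the K_SV(T) heuristic surfaced in testing and
are worth knowing:

- a *static* binder with ΔH > 0 has Ka(T), and hence apparent K_SV(T),
  rising slightly (~3.5% per 10 K at ΔH = 2.5 kJ/mol). At high data
  precision (≤1% noise) the 2·SE rule resolves that rise and reports
  "dynamic"; the classical flat-K_SV reading of such systems holds at
  typical experimental precision (K_SV errors of a few percent);
- the R² < 0.98 "mixed" trigger cannot distinguish curvature from plain
  statistical scatter, so it is only meaningful when the quench signal
  is well above the noise (roughly Ka·[Q]_max ≳ 0.5 at 1% noise).

## van't Hoff analysis

`ln Ka` on `1/T`, weighted by δ(ln Ka) = Ka_se/Ka when SEs are supplied
(known-variance weighting, same rationale as above); ΔH = −R·slope,
ΔS = R·intercept, ΔG(T) = ΔH − T·ΔS = −R·(slope + T·intercept), with the
variance of ΔG taken from the full slope–intercept covariance. With
exactly two temperatures the SEs are reported as absent rather than
zero. No standard-state or concentration correction is applied to ΔG
from Ka (matching the emulated procedure).

Note the precision asymmetry, visible in the worked example: ΔG at an
observed temperature is essentially −RT·ln Ka and is determined to
~0.1 kJ/mol, while ΔH from a 3-point regression over a 20 K span
carries an uncertainty of a few kJ/mol even at 1–3% Ka error. Reported
force classifications (sign rules: ΔH>0 ∧ ΔS>0 → hydrophobic/
non-specific; ΔH<0 ∧ ΔS<0 → H-bond/van der Waals; ΔH<0 ∧ ΔS>0 →
electrostatic) should therefore be read against the ΔH/ΔS error bars.

A consistency caveat on the emulated study's printed values: Ka ≈
4.3×10⁴ M⁻¹ implies T·ΔS ≈ 29 kJ/mol and ΔG ≈ −26.5 kJ/mol at 298 K
under these equations, not the ~16–17 and −14 kJ/mol printed alongside;
the package reproduces the procedure, not the printed rounding.

## CD helix content

`[θ] = θ_mdeg/(10·[P]·l·n_res)` (deg·cm²·dmol⁻¹; blank subtraction
assumed upstream), and the Chen single-wavelength estimate
`% helix = (|MRE_222| − 2340)/30300·100`. The magnitude convention is
deliberate: applied to the signed (negative) helical ellipticity the
formula as often printed would give negative fractions; the magnitude
form reproduces the accepted 63%/56% values for the IL6 system.

MRE at 222 nm is read as the mean over a ±0.3 nm window of the 0.1 nm
digitised spectrum. On noise-free spectra the window bias is < 0.05
helix points (the n→π* band is locally flat); on noisy spectra it
averages ~7 points of independent instrument noise, which matters
because at 4 µM protein in a 0.01 cm cell the whole 222 nm signal is
only ~−1.6 mdeg, so 0.05 mdeg of single-point noise would alone be
~2 helix points. Replicates (the emulated protocol is triplicate) give
a sample-SD uncertainty. Estimates marginally outside [0, 100] —
measurement noise around fully disordered or fully helical proteins —
clamp to the boundary with a warning; an excess beyond 5 points raises,
since it indicates wrong concentration/path/residue metadata rather
than noise.

The synthetic CD generator builds the helix basis from Gaussians at 222
and 208 nm normalised so the mixed spectrum's MRE at 222 nm is exactly
−(2340 + 303·h), and a coil basis constructed to contribute exactly
zero at 222 nm; band shapes away from 222 nm are cosmetic. Consequently
the round trip is exact by construction at 222 nm — these tests
validate the analysis algebra and the noise/replicate handling, not the
spectroscopy of real proteins (no basis-set deconvolution such as
CONTIN/BeStSel is attempted; 208 nm information is unused).

The helix-change report prints both the absolute difference in
percentage points and the change relative to the starting content
(63% → 56% is −7.0 points but −11.1% relative); published prose
sometimes mixes the two, so both are always given, with quadrature-
propagated SEs.

## Umbrella sampling and WHAM

The synthetic sampler draws window samples directly from the biased
Boltzmann density `exp(−β[U(ξ) + k/2(ξ−ξ_i)²])` by inverse-CDF lookup on
a 4096-point grid — the exact stationary distribution, no dynamics, so
sampler validation reduces to closed forms (uniform on a flat landscape;
variance k_BT/K in a harmonic well; SD √(k_BT/k) ≈ 0.056 nm under the
default k = 800 kJ·mol⁻¹·nm⁻² restraint at 298 K). Optional time
correlation is imposed through a Gaussian copula with an AR(1) latent
series whose lag-1 coefficient (τ−1)/(τ+1) gives an integrated
autocorrelation time of exactly τ for the latent process (and
approximately τ after the marginal transform). Ground-truth PMF forms:
flat, harmonic, and a Gaussian-well "binding funnel" with a flat
dissociated tail; all accept a constant offset, which verifiably leaves
the recovered profile unchanged.

WHAM iterates the standard self-consistency equations on fixed
histograms (default 200 bins over the sampled range; bias Boltzmann
factors may underflow far from a window, which is harmless), converging
on the window free energies f_i (max|Δf| < 1e−6 kJ/mol, f_1 ≡ 0) rather
than on the PMF, and anchors min(PMF) = 0. Empty bins stay masked and
are never extrapolated. Adjacent windows must have overlapping sample
supports; the error message lists the gap. A single unbiased window
degenerates to histogram inversion, which the tests check against
−kT·ln(counts) directly, and a hand-built 3-bin/2-window instance is
checked against an independently coded scalar fixed-point solver to
1e−8 kJ/mol.

Binding ΔG is the PMF at the well minimum minus the mean over the
unbound plateau (default: supported bins in the last 10% of the
coordinate range; ≥3 required). No standard-state volume or Jacobian/
radial-entropy correction is applied — the reference procedure states
none — so ΔG values are comparable only within this convention.

Errors: the integrated autocorrelation time of each window series is
estimated with Geyer's initial-positive-sequence estimator (FFT
autocovariance, paired sums); the block bootstrap resamples each window
in contiguous blocks of length ⌈τ⌉ (moving blocks, truncated to the
series length), never across windows, and re-solves WHAM per replicate
warm-started from the point estimate. The per-bin SE is the replicate
SD; the ΔG SE likewise. Default 1000 replicates; the test suite uses
200 (and less for small checks) to keep runtimes in seconds — with the
default window designs the ΔG SE is ~0.4–0.5 kJ/mol, so 200 replicates
estimate it to ~5%. τ exceeding half the series length aborts (fewer
than two independent blocks). The estimator caps near n/3 on pathological
(drifting) series, so the abort primarily protects against explicitly
long-correlated inputs.

Window design matters more than bin count: with k = 800 kJ·mol⁻¹·nm⁻²
(window SD 0.056 nm), 0.2 nm spacing leaves ~3.6σ between neighbours
and the stitching of window offsets dominates the ΔG error (~0.5
kJ/mol); 0.1 nm spacing (~1.8σ) roughly halves it. The validation
suites use 11 windows on [0, 2] nm for profile-shape recovery (RMSE
< 0.5 kJ/mol against the analytic harmonic well at 5000 samples/window)
and 21 windows for well-depth recovery (depths 3–12 kJ/mol within 2
bootstrap SE).

## Recovery-sweep conventions

Parameter-recovery tests draw 50 affinities log-uniformly in
[10³, 10⁶] M⁻¹ at 1% noise and demand ≤5% median error. The titration
window is matched to each draw — Ka·[Q]_max and [P]0/[Q]_max held at
the reference design's values (0.731 and 4/17) — because a fixed 0–17 µM
window carries essentially no information about affinities far from
1/[Q]_max; with the matched design the dimensionless estimation problem
is identical across draws, and the sweep tests estimator consistency
across scales rather than the information limit of one window.

## Determinism

Every stochastic step takes a seed (NumPy `default_rng`); fixed seeds
give bit-identical generator output, bootstrap SEs and JSON reports
(timestamps aside). Derived seeds stay below 2³¹.
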