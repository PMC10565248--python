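# Methods

`morphograd` re-implements, as a tested pipeline, the quantitative
machinery used to characterize an extracellular morphogen gradient in a
developing tissue: fluorescence correlation spectroscopy (FCS) of the
ligand in the extracellular space, reconstruction of its spatial
gradient from positioned count rates, quantification of target-gene
expression profiles, mapping of expression-domain boundaries onto
relative ligand concentrations, and a hindered-diffusion
reaction–diffusion model of how the gradient forms.  All data the
package analyses are synthetic, generated by its own simulators with
known ground truth; the generators' default parameters encode the
measured study conditions (diffusion coefficients, component fractions,
concentrations, domain sizes) so that tests validate the estimators
under realistic statistics.

## FCS model and fitting (`fcs_core`)

The confocal observation volume is a 3D Gaussian with lateral 1/e²
radius ω₀ and axial radius z₀; the structural parameter is S = z₀/ω₀.
(Note one convention pitfall: S is sometimes written as the inverse
ratio, but with z₀ > ω₀ only S = z₀/ω₀ is consistent with the reported
S ≈ 5; this package uses that convention throughout.)  Free diffusion
of one or two components with a multiplicative triplet-state factor
gives the fitted model

G(τ) = [1 + T/(1−T)·e^(−τ/τ_T)] · (1/N_p) · Σᵢ Fᵢ (1+τ/τ_{D,i})⁻¹ (1+τ/(S²τ_{D,i}))^(−1/2)

with particle number N_p, fractions Fᵢ (Σ=1) and dwell times τ_{D,i}.
Following the measurement protocol, sample fits fix T = 10 %,
τ_T = 30 µs and S at the calibration average; only the calibration fit
lets S float.  Derived quantities: D = ω₀²/(4τ_D), V_eff = π^{3/2}ω₀²z₀,
C = N_p/(V_eff·N_A).

**Correlator.**  Photon-count traces are correlated with a multi-tau
scheme (16 channels per cascade, bin width doubling per cascade) using
the symmetric normalization ⟨F_head F_tail⟩/(⟨F_head⟩⟨F_tail⟩) − 1,
which removes the leading finite-length bias.  The implementation is
tested for exact (≤1e−10 relative) agreement with a brute-force
direct-sum correlation at shared lags.

**Fit protocol.**  Fits are weighted nonlinear least squares (lmfit,
Levenberg–Marquardt).  Two-component fits parameterize the slow dwell
time as τ_D2 = τ_D1 × ratio with ratio ≥ 2, which keeps the components
ordered and prevents collapse onto a single decay, and are restarted
from three seeded initializations.  The default sample-fit window is
40 µs – 100 ms: the first lag channel is excluded because finite-bin
triangular averaging and the fixed triplet factor distort it most, and
lags beyond 100 ms carry no model information at these dwell times
(τ_fast ≈ 0.18 ms, τ_slow ≈ 2.5 ms) while contributing correlated
noise.  When a curve is the average of repetitions, per-lag standard
errors from the repetition scatter serve as weights.

**Model selection.**  The choice between the one- and two-component
models uses a nested-model F-test at α = 0.05 restricted to lags
0.5–50 ms, the band in which the two decays are distinguishable.  On
synthetic pure one-component curves the type-I rate is near nominal;
well-separated two-component curves (dwell ratio ≥ 10, minor fraction
≥ 15 %) are detected in ≥ 95 % of cases.

**Calibration.**  Two routes are provided.  `fcs_core.calibrate`
implements the classical protocol: fit the reference-dye curve 3D-1C
with S free, then ω₀ = √(4·D_ref·τ_D) with the dye's literature
diffusion coefficient, z₀ = S·ω₀.  D_ref defaults to 435 µm²/s (a
common room-temperature value for the usual calibration dye) and is
configurable — an input constant, not a claim.  That route recovers
exactly on noise-free curves, but on desk-scale simulated dye traces
the free S is unstable: it is pinned by the faint correlation tail,
where shot noise and any finite-box artifact dominate.  The pipeline's
`calibration_volume` therefore anchors the effective volume on the
dye's known concentration instead — V_eff = N_p/(C_ref·N_A) from the
fitted amplitude, which is exact in expectation and stable to a few
percent — while taking ω₀ from the fitted dwell time as above.
Simulated calibration traces include two-state blinking at the fixed
triplet defaults so the calibration fit is well specified; this
matters because the dye dwell time (≈23 µs) overlaps the triplet
window.

## Brownian-dynamics simulator (`fcs_sim`)

Molecules take isotropic Gaussian steps of std √(2DΔt) per axis in a
periodic box (≥ 8ω₀ laterally, ≥ 8z₀ axially) and emit photons as an
inhomogeneous Poisson process with per-molecule rate
B·exp(−2(x²+y²)/ω₀² − 2z²/z₀²); counts are binned at the simulation
step (default 20 µs, stability bound Δt ≤ ω₀²/(20·D)).  The detection
profile equals the analytic fit model by construction, so recovery
tests isolate estimator error from model mismatch.  Box size matters
beyond the nominal 8-radius rule: periodic images make a molecule's
occupancy recur on the timescale L²/(4π²D), below which the correlation
tail is suppressed relative to the infinite-medium model.  Mixture
experiments therefore use a 4.8-µm lateral box, which pushes the fast
species' recurrence out of the 1–20 ms band where the minor slow
component is fitted (in a minimal 1.6–2.4 µm box the deficit reaches
~20 % of the slow component's signal and biases it low).  The inner
loop is a numba kernel consuming bulk-generated SFC64 float32 normals;
traces are bit-reproducible per seed.  Defaults encode the
study conditions: a 93 %/7 % mixture of D = 55 and 4 µm²/s at a total
concentration of 8 nM (the measured source-domain concentration, which
also reproduces the reported ~1.1–1.4 kHz near-margin count rate at the
default brightness of 3 kHz/molecule).  Molecule numbers per species
are fixed at round(expected) by default: the box stands for a fixed
realization of an effectively infinite bath, and focal-volume number
fluctuations still arise from diffusion; Poisson-drawn numbers are
available as an option but add bath-concentration scatter between
realizations that the real tissue does not have at this scale.
Per-molecule brightness and triplet blinking are configurable; blinking
is off by default (fits fix the triplet term regardless, mirroring the
protocol).

**Statistical limits.**  At 3 kHz/molecule and 8 nM, a measurement of
twenty 10-s repetitions carries an intrinsic (Cramér–Rao) relative
standard error of roughly 8–11 % on the fast dwell time, ~35–40 % on
the slow one and ~3 percentage points on the fast fraction — the minor
slow component is close to the identifiability limit, exactly as the
large per-measurement scatter reported for such experiments suggests.
Recovered values therefore scatter noticeably between seed families;
averaging repetitions before fitting (rather than averaging per-trace
fits, which diverge at this SNR) is the protocol used throughout.

## Synthetic embryos (`synthetic_embryo`)

The phantom is a 300 × 100 × 20 µm strip with x measuring distance from
the embryonic margin; one cell tier is 14 µm (140 µm ≈ 10 tiers).  The
relative gradient curve is a monotone (PCHIP) interpolation through
anchors encoding the measured shape: depressed levels in the two
marginal-most tiers, peak plateau at 40–55 µm, 0.8 of peak at 70 µm,
0.4 at 140 µm, smooth decay beyond; a single scalar (default 8 nM)
anchors the curve to an absolute concentration, because the measurement
yields one absolute source-domain value rather than a calibrated
absolute curve.  smFISH foci are an inhomogeneous Poisson process along
x (uniform in y, z) with piecewise-linear rate functions: the
margin-confined target (*tbxta*-like) is maximal over 40–70 µm and zero
beyond 140 µm; the broad target (*etv4*-like) is positive everywhere
with its plateau over 70–140 µm.  Absolute rate amplitudes are
arbitrary (~80 expected foci per 10-µm band at the plateau — a
realistic smFISH density for this strip size); profiles are normalized
downstream, so only shape matters.  Nuclei sit on a jittered hard-core
lattice (radius 2.5 µm) with reporter intensity
response(gradient(x)) × lognormal noise; the default saturating
response I = g/(g+0.2) produces the deliberately shallow reporter
profile (≥ 0.6 of peak everywhere within 10 tiers).  Rendering draws
foci as 3D Gaussians and nuclei as soft-edged spheres with Poisson
photon noise plus 2 % Gaussian read noise.  What the phantoms do *not*
emulate: cell movement during gastrulation, transcriptional bursting,
optical aberrations with depth, and segmentation errors on touching
nuclei — passing tests therefore validate the quantification chain, not
robustness to those real-data effects.

## Quantification (`profiles`)

Spectral unmixing is per-pixel non-negative least squares onto
reference endmember spectra, with a residual-norm map for QC (the
vendor tool's exact algorithm is unpublished; NNLS is the standard
non-negative formulation of "linear unmixing").  Strip profiles
sum-project over z, average transversely over a 100-µm strip and bin
along x with per-sample max normalization (hence exposure invariance).
Foci are detected by scale-matched 3D Laplacian-of-Gaussian at the
stated physical radius (1 µm for smFISH foci; 2.5 µm for nuclei) with a
relative response threshold, sub-voxel intensity-weighted centroids and
per-blob mean intensities.  The original manual per-image threshold
adjustment is not reproducible and is replaced by a fixed relative
threshold chosen to maximize F1 on rendered phantoms (F1 ≥ 0.9 at
default SNR).  Binning is left-closed/right-open at 10 µm from the
margin; normalization is per-sample max by default, or
control-average-max when comparing a perturbed group against controls.

## Gradient assembly and threshold mapping (`gradient_mapping`)

FCS gradient order of operations is fixed: subtract the background
count rate, normalize each sample to its own maximum, bin at 40 µm,
aggregate across samples (mean ± s.d.) — making the profile invariant
to per-sample gain.  Threshold overlay defines the peak expression
domain as the contiguous bins within 90 % of the maximal mean bin, and
the expression boundary as the left edge of the first post-peak bin
with zero mean foci count (intensity profiles instead use a 10 %-of-max
floor, since intensities never vanish exactly).  The gradient is
interpolated monotonically (PCHIP) at feature positions; positions are
also reported in cell tiers (x/14).  Group comparisons use the
unpaired two-tailed pooled-variance t-test; spatial association uses
Pearson's r.  The decay length is a least-squares exponential fit to
the post-peak tail.

## Reaction–diffusion model (`rd_model`)

The transport model is stated verbally by the underlying biology
(hindered diffusion: free extracellular diffusion retarded by binding
to immobile HSPG sites); all equations and rate constants here are this
package's own modelling choices.  Free ligand diffuses
(D = 55 µm²/s, the measured fast component), binds reversibly to
immobile sites and degrades; bound ligand is immobile.  Defaults:
k_off = 1 s⁻¹, k_on·B_tot chosen so the near-source bound fraction is
≈ 7 % (the measured slow fraction), degradation acting predominantly on
the bound pool (k_deg_bound = 0.09 s⁻¹ ≫ k_deg_free = 5·10⁻⁴ s⁻¹) with
a production strip of one cell tier.  The bound-pool-degradation choice
is what makes binding-site removal *flatten* the gradient (decay length
grows from ≈ 95 µm to ≈ 200 µm in the HepI scenario) rather than
truncate it, matching the observed perturbation; with degradation on
the free pool the model would predict the opposite.  Scenarios:
`hepI` (B_tot × 0.3), `tethered_clone` (D ≈ 0: ligand confined to ~2
tiers of the source), `morpho_trap` (uniform high-affinity immobile
binder: free-ligand range collapses).  Numerics: explicit finite
differences (dx = 2 µm, dt = 0.02 s, CFL-stable), conservative no-flux
boundaries (exact mass conservation to round-off in sealed runs), a
Dirichlet option at x = 0 for analytic comparisons (k_on = 0 steady
state matches c₀e^(−x/√(D/k)) to < 1 %), and steady-state declaration
at relative change < 1e−8 per characteristic time.

## Problem sizes and determinism

Validation and the reproduction script use twenty 10-s traces per FCS
experiment, twenty synthetic embryos per profile experiment, and the
300-µm RD domain — sizes at which every stage's expected error is
within its stated tolerance while a full run stays at desk scale.  All
generators are deterministic under (config, seed); a single global seed
fans out to per-stage child seeds (SeedSequence over a stage-name
hash), so stages can be re-run in isolation and identical configs
produce byte-identical artifacts.
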