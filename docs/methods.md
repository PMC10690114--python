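# Methods

This note records the models petkin implements, the numerical choices behind
them, what the synthetic-data generator does and does not emulate, and the
known limitations. Symbols follow standard PET nomenclature: Cp(t) the
metabolite-corrected arterial plasma (parent) concentration, C_T(t) the
tissue concentration, V_T the total volume of distribution, V_ND its
nondisplaceable part, BP_ND = V_T/V_ND − 1 the binding potential.

## Units and conventions

All kinetic-side times are minutes post injection; the PK–PD side uses hours
post dose, and conversions go through the explicit bridges
`minutes_to_hours` / `hours_to_minutes`. Activities are kBq/mL and assumed
decay-corrected to injection time (the standard convention for tabulated
TACs); injected dose is MBq, body weight kg, so SUV = activity ·
weight/dose is dimensionless for unit tissue density. Frames are
`[start, end)` intervals; gaps (scan breaks) are legal, overlaps are not.
Model predictions are referenced to frames by averaging over the frame, and
graphical methods use frame midpoints — one convention throughout, so t*
cutoffs are reproducible. TAC tables are CSV with `frame_start, frame_end`
then one column per region; blood tables are `time, conc`.

## Forward model and convolution

The serial 2TC impulse response is a sum of two exponentials with rates
a₁,₂ = ½[(k₂+k₃+k₄) ∓ √((k₂+k₃+k₄)² − 4k₂k₄)]. Tissue curves are this
response convolved with Cp. Cp is linearly interpolated onto a uniform grid
(default 0.1 min) and the convolution with each exponential is evaluated by
the exact one-step recurrence for piecewise-linear inputs (implemented as a
first-order IIR filter), so there is no quadrature error beyond the linear
interpolation of Cp itself, and the recursion is stable for arbitrarily
large rate·t. Frame averages use the closed form
∫(Cp ⊗ e^{−at}) = [∫Cp − (Cp ⊗ e^{−at})]/a, again exact on the grid; frame
edges off the grid are interpolated on the (smooth) integral. A coincident
pair of 2TC eigenrates (discriminant ≈ 0) is regularised by a 1e−12 floor
on the rate gap.

## Compartment fitting

Weighted least squares on frame-averaged predictions, weights equal to
frame duration (uniform variance per unit scan time; "uniform" is
available). Rates are bounded to [1e−4, 10] in their stated units, default
starts K1 = k2 = 0.1, k3 = k4 = 0.01, with a deterministic log-spaced
multistart (5 rescalings of the default start) if the first solve fails.
Standard errors come from the Gauss–Newton covariance (J'J)⁻¹·RSS/dof of
the weighted residuals. AIC uses the weighted RSS without small-sample
correction, n·ln(RSS/n) + 2k; both candidate models are fitted with the
same weights so the comparison is consistent. A fit with k4 pinned at the
lower bound is flagged as irreversible-like rather than rejected. No
fractional blood-volume term and no AIF delay/dispersion correction are
modeled; both are deliberate simplifications of the tissue model.

## Graphical methods

Logan integrals of the tissue curve use midpoint trapezoids with a leading
half-triangle from (0, 0); the plasma integral is trapezoidal on the AIF's
own sampling grid and interpolated at frame midpoints. Only frames with
midpoint ≥ t* (default 30 min) and C_T > 0 enter the OLS regression
(y-errors only; at least 3 points). The choice of midpoint trapezoids vs
continuous interpolation is a convention, tested for self-consistency, not
a claim about any external implementation. Noise biases Logan slopes
downward relative to 2TC V_T; on noiseless synthetic data the two agree on
the identity line (r² ≥ 0.99 across the default 16-region ground truth).

SRTM is solved by basis-function expansion: for each of 100 log-spaced
values of the apparent efflux rate θ = k2/(1+BP_ND) in [1e−3, 1] min⁻¹ the
remaining parameters are a linear least-squares subproblem; the best grid
point is refined by bounded scalar minimisation. This is deterministic and
free of start-value sensitivity. The reference curve is taken linear from
(0,0) through its frame midpoints for the convolution basis. By convention
k2′ for NI-LGA comes from an SRTM fit to the putamen (the highest-signal
region); if absent, the highest-uptake region is used with a logged
warning.

## Reliability

TRT is the signed percent difference normalised to the pair mean; summaries
report the mean and SD of |TRT| per region/method across subjects. The ICC
is the one-way contrast (BMS − WMS)/(BMS + WMS) from paired measurements;
the degenerate zero-variance case raises an error rather than silently
returning 1, since it indicates a simulation or bookkeeping bug. Time
stability refits a quantifier on truncated data (minimum durations: 10 min
1TC, 20 min 2TC, 60 min Logan) and reports signed percent bias against the
full-duration estimate; with the default noiseless kinetics the 90-min bias
of 2TC V_T is under 5%.

## Occupancy

The Lassen regression uses ordinary least squares of (V_T,base − V_T,block)
on V_T,base over all regions present in both scans, unweighted; the slope
SE is from standard OLS theory. Orthogonal regression was considered and
not used (the x-variable is itself an estimate, but the y-error-only
convention is the field's standard and keeps the estimator linear). A slope
below 1e−6 reports occupancy ≈ 0 with V_ND flagged indeterminate instead of
dividing by it. For regional occupancies the V_ND is taken from the
subject's highest-occupancy (first blocking) scan; when that plot is
degenerate, regional values are marked unavailable rather than guessed.
Occupancies outside [0, 100]% are retained and flagged — truncating them
would bias the Emax fit downstream.

## PK–PD

The effect-site ODE dCe/dt = ke0(Cp − Ce) is integrated by the exact
piecewise update for linear Cp segments. The Emax model treats Emax
internally as the fraction 1.0 with outputs in percent, so C = EC50 yields
exactly 50% — the definition of a half-maximal concentration. Plasma-mode
fits fix γ = 1 (noncooperative binding); effect-site-mode fits free γ; the
joint model estimates (ke0, EC50, γ) by unweighted least squares on
occupancy percent, parameters on a log₁₀ scale with a deterministic 7-point
ke0 multistart over [1e−2, 10] h⁻¹ (bounds [1e−3, 1e2]). Reported relative
SEs are the log-scale SEs times ln 10. A design with all observations at a
single post-dose time leaves ke0 unidentifiable and is flagged, not
"fitted".

## Synthetic-data generator

The generator is the package's test bed and defines its study conditions:

- **AIF**: linear rise to a peak at 1.5 min, tri-exponential decay
  (weights 0.75/0.20/0.05, rates 0.6/0.08/0.012 min⁻¹), continuous at the
  peak. The peak amplitude (29.5 kBq/mL at 330 MBq) was calibrated once so
  the default putamen curve peaks near SUV 8 around 30 min, then frozen.
- **Parent fraction**: pf(t) = 0.25 + 0.75·e^{−0.0604t}, i.e. ~27% parent
  at 60 min falling to a 25% plateau — the shape of a rapidly metabolised
  tracer.
- **Regional kinetics**: 16 regions with a common V_ND = K1/k2 =
  1.5 mL/cm³, k4 = 0.024 min⁻¹, and k3 spanning the basal-ganglia-high
  ordering (putamen V_T ≈ 20, cerebellum V_T = 6.4 mL/cm³ with fast
  washout and a ≤5-min peak). These rate constants are this package's own
  choices, selected once to land on published V_T-scale landmarks; they are
  not measured values.
- **Frame schedules**: 6×0.5, 3×1, 2×2, 5×5, 9×10 min, a 30-min break, then
  9×10 min for the kinetic/TRT study; the same head plus 8×10 min (120 min,
  no break) for blocking scans.
- **Noise**: zero-mean Gaussian per frame with sd = level·activity/√duration,
  truncated at zero (a small positive-bias source at very high noise
  levels); every draw is seeded.
- **Occupancy**: drug blocking rescales k3 by (1 − occ) with K1/k2 fixed,
  so blocked V_T = V_ND + (1 − occ)(V_T − V_ND) holds exactly — the
  mechanism consistent with a Lassen plot's common-V_ND assumption. Each
  scan gets its own injected dose (uniform 300–360 MBq) and a
  dose-proportional AIF; the second blocking scan carries no arterial data,
  forcing the surrogate-AIF path.
- **TRT cohorts**: between-subject log-normal multipliers (default CV 15%)
  on K1 (with k2, preserving V_ND) and on k3, shared within a subject's
  pair; within-subject variability comes from frame noise only.
- **Drug PK**: one-compartment oral absorption, Cp(t) =
  dose·ka/[V/F·(ka−ke)]·(e^{−ke·t} − e^{−ka·t}) with defaults ka = 1.5 h⁻¹,
  ke = 0.15 h⁻¹, V/F = 2000 L, and an effect-site link with ke0 =
  0.35 h⁻¹ — magnitudes that put single oral doses of 50–600 mg in the
  ng/mL exposure range where the published EC50 values (3.01 and
  5.52 ng/mL) span the occupancy curve.

What the generator does **not** emulate: image-domain effects
(reconstruction, partial volume, motion), AIF measurement and metabolite-
assay error, dispersion/delay between blood and tissue, whole-blood-to-
plasma ratio corrections, and nonlinear drug pharmacokinetics. Two
consequences matter for interpreting green tests. First, because
within-subject variability is frame noise alone, the synthetic TRT
magnitudes (well under 1% for Logan V_T at the default 3% frame noise) are
far smaller than clinical TRT, which is dominated by input-function and
processing variability; the reliability tests validate the statistics, not
clinical reproducibility magnitudes. Second, noiseless recovery tests
demonstrate correctness of the estimators, not their robustness to the
systematic errors real data carry.

## Problem sizes

Test and acceptance runs use one to six subjects, 3–16 regions, the frame
schedules above, 100-replicate Monte-Carlo loops for the AIC-selection and
EC50/γ-band checks, and 12–30 replicates for spread/mean-recovery checks —
sizes at which every quantity of interest is stable yet the whole suite
runs in well under a minute per module. The Monte-Carlo Emax noise is 5%
proportional on occupancy values.

## Known limitations

- The Lassen and BP_ND machinery presumes a region-common V_ND; the
  generator enforces it, real brains only approximate it.
- AIC model selection uses the weighted-RSS form without small-sample
  correction; with ~30 frames and 2–4 parameters this is mild but present.
- The noise model is Gaussian and truncated at zero rather than Poisson-
  derived; at high noise the truncation biases frame means upward.
- The joint effect-site fit assumes a shared (ke0, EC50, γ) across
  subjects with no random effects; population heterogeneity is out of
  scope.
- Graphical estimates inherit the well-known noise-dependent negative bias;
  the package reports them as-is rather than applying bias corrections.
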