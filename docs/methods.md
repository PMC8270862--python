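# Methods

This note documents the models implemented in `synodce`, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerical choices that affect results.

## Signal model and relaxometry

All simulated and analysed acquisitions are 3D spoiled gradient-echo
(SPGR). The steady-state signal is
S = M₀ sinα (1−E₁)/(1−E₁cosα) with E₁ = exp(−TR/T1). Native T1 is
estimated from variable-flip-angle images (default angles 2/6/14°,
TR 4 ms) by the standard linearisation (S/sinα against S/tanα), which
is exact on noiseless data; an optional nonlinear refinement is
available but changes nothing in the noise regimes tested. Voxels with
a non-physical slope (outside (0,1)) or zero signal are flagged rather
than fitted. No B1 correction is applied; flip angles are taken as
nominal.

Concentration conversion assumes fast water exchange,
R1(t) = 1/T1₀ + r₁C(t) with r₁ = 3.5 L·mmol⁻¹·s⁻¹ (gadoterate at 3 T).
The equilibrium magnetisation is eliminated using the mean of the
pre-bolus baseline frames (default 5) together with the native T1.
Timepoints whose signal implies E₁ outside (0,1) — possible under heavy
noise — are flagged invalid and excluded from fitting, never clipped:
silent clipping would bias K^trans downwards asymmetrically.

Units: seconds throughout relaxometry; minutes in the kinetic module.
The conversion happens once, explicitly, at that boundary. IAUC₆₀ is
reported in mM·s (integral over a minute grid × 60).

## Arterial input function

The plasma input is the population-averaged whole-blood curve — two
Gaussian bolus-passage terms plus an exponentially decaying sigmoid
washout — divided by (1 − haematocrit). The ten population constants
are configuration values with the standard published defaults, so a
site-specific AIF can be substituted without code changes. Haematocrit
defaults to 0.42 (population mean) when no individual value is given.
The curve is zero before a configurable bolus-arrival offset; the
pipeline aligns it with the first post-baseline dynamic frame, since
arterial bolus-arrival detection from image data is out of scope.

Because the first-pass peak (width ≈ 3–8 s) is narrow relative to a
10 s frame interval, the AIF is evaluated on a 10× supersampled time
grid before convolution, and the model is sampled back at frame times.
Both simulation and fitting use the same supersampled representation,
so discretisation of the peak cannot masquerade as kinetic bias.

## Extended Tofts model and fitting

The convolution C_p ⊛ exp(−k_ep·) is evaluated by the exact recursion
for piecewise-linear C_p rather than quadrature: per segment the
integral has a closed form, and the running value propagates with one
multiply per step (implemented as a constant-coefficient IIR filter on
uniform grids, with an explicit loop fallback for non-uniform grids,
and the exact trapezoid limit for k_ep·Δt < 1e-10). Naive trapezoidal
convolution at 10 s sampling biases K^trans by several percent; the
recursion is exact for the assumed input class.

Voxelwise fitting minimises the residual sum of squares over
(K^trans, v_e, v_p) with bounds K^trans ∈ [0,10] min⁻¹, v_e ∈ (10⁻⁶,10],
v_p ∈ [0,1]. v_e is deliberately *not* capped at 1: physiologically
implausible values (v_e > 1) are representable and flagged by a
plausibility mask (v_e ≤ 1, v_p ≤ 0.5, K^trans ≤ 5 min⁻¹), reproducing
the behaviour of unconstrained fits on noisy synovial data instead of
hiding it at a bound.

Two engines are provided:

- `multistart` (default of the voxel-level API): bounded trust-region
  least squares started from the grid {0.01, 0.1, 1} min⁻¹ ×
  {0.1, 0.5} × {v_p = 0.01}. All six starts are scored by initial RSS
  and the best two are polished — on every noiseless grid tested this
  returns the same optimum as polishing all six, at ~3× less cost.
- `varpro` (default of the volume pipeline): for fixed k_ep = K^trans/v_e
  the model is linear in (K^trans, v_p), so the inner problem is solved
  in closed form (with box constraints enforced by candidate
  projection) and only k_ep is searched — a 16-point log grid refined
  by bounded Brent. Both engines are tested to recover noiseless truth
  (varpro to ~10⁻⁶ relative); varpro is ~4× faster, which is what makes
  the end-to-end cohort study tractable on one CPU.

Bolus arrival in the tissue is detected as the first timepoint
exceeding baseline mean + 3·baseline SD for two consecutive frames,
falling back to the first post-baseline frame; the rule is simple,
testable, and conservative under noise. IAUC₆₀ uses each voxel's own
arrival by default (a per-region variant is available), integrating by
trapezoid with interpolated window endpoints; it is invariant to data
after arrival + 60 s.

## Segmentation

The shuffle transform replaces, per post-contrast voxel, the subtrahend
with the pre-contrast value closest to it within a neighbourhood.
"Adjacent 3×3" is read as in-plane (9 candidates): slice thickness
(2–4 mm) far exceeds in-plane voxel size, making through-plane
shuffling anatomically dubious; a 3×3×3 mode exists behind a flag.
Ties are broken by smallest spatial offset, then lexicographic order,
and the neighbourhood is clipped at volume edges. The signed difference
is kept so de-enhancing voxels remain representable.

Otsu's threshold (256-bin histogram, maximising between-class variance;
`scikit-image` implementation, verified against exhaustive search) is
computed over the difference values *inside the ROI union* by default —
a phantom's large empty background would otherwise dominate the
histogram; whole-image sampling is available as an option. Enhancing ∩
ROI is the VEP mask; volumes are voxel counts × voxel volume, reported
per region and whole joint, additive by construction. Median biomarkers
are extracted over VEP voxels (semiautomatic arm) and over the full
manual ROI (manual arm); a region with no eligible voxels is recorded
as missing, never zero.

## Repeatability statistics

Two-visit test-retest data are decomposed by one-way random-effects
ANOVA with two replicates: σ_w² = MS_within,
σ_b² = max(0, (MS_between − MS_within)/2) (negative components
truncated at zero, so an ICC of exactly 0 is possible);
ICC = σ_b²/(σ_b²+σ_w²) with an F-pivot confidence interval floored at
0. The variability scale is chosen by Kendall's τ between subject mean
and |visit difference| at two-sided α = 0.05: relative (wCV, RMS pair
method) when significant, absolute (wSD = √σ_w²) otherwise. The
log-transform wCV alternative was considered and rejected for the
two-replicate design in favour of the simpler RMS method.
SDD = √2·1.96 × wSD (or wCV), reported in the same units/scale.
Observer reproducibility: RMSCV over pairs (sample SD / pair mean) and
Lin's CCC in the population-moment convention. Discrimination: Cohen's
d with (n−1)-weighted pooled SD. Responsiveness: strict count of
|6-month change| > SDD, changes expressed as percent of subject
baseline on the relative scale.

## The synthetic cohort

The phantom is deliberately schematic: seven synovial ellipsoids on a
ring around a central bone ellipsoid with an off-axis fluid pocket, on
a 64×64×16 grid by default (32×32×8 in the demo/validation studies).
Each region carries constant tissue parameters (K^trans spread
0.030–0.055 min⁻¹ around the OA whole-joint mean of 0.039, v_e 0.3,
v_p 0.02, T1₀ 1.2 s); a seeded random 70% of synovial voxels enhance,
the rest (modelling fibrotic pannus) have K^trans = v_p = 0.

Cohort structure mirrors the two-group design: 14 OA / 6 HV by default,
visits baseline / 1 month (test-retest) / 6 months. Subject true
K^trans levels are group mean + N(0, σ_b); each visit adds
N(0, σ_w), with σ_b² = 2.1×10⁻⁴ and σ_w² = 2.4×10⁻⁵ (the published
whole-joint semiautomatic values). The HV mean of 0.025 min⁻¹ places
the true standardised mean difference at ≈ 0.94, the reported K^trans
group separation. Draws are floored at 10⁻³ min⁻¹ to keep the forward
model physical (< 1% of draws at these means; negligible effect on the
calibration invariant, which is tested at n = 500). Haematocrit is
N(0.42, 0.03) clipped to [0.2, 0.6]. Subject images are generated with
region K^trans scaled so the whole-joint median over enhancing voxels
equals the subject-visit true level exactly. For responsiveness
constructions, per-subject deterministic 6-month true changes can be
assigned relative to the realised baseline level (a subject assigned 0
has exactly zero true change); unassigned subjects receive the usual
within-subject draw.

Protocol defaults follow the 3 T knee protocol (TR 4 ms, dynamic flip
14°, 35 phases). The frame interval is not part of that protocol table;
10 s per phase (~5.8 min) is assumed — typical for 3D SPGR knee DCE and
long enough to capture washout — and is a named config key. The bolus
arrives after 5 baseline frames so a pre-contrast reference exists.
Noise is Gaussian by default (σ = 0.5 signal units against baseline
signals of ~20–60, a high-SNR regime chosen so method bias, not noise,
dominates validation); Rician magnitude noise is available, and its
zero-signal floor σ√(π/2) is tested.

What the phantom does **not** emulate: real anatomy, partial volume,
motion (the shuffle transform's motion robustness is tested with
synthetic translations), B1/B0 inhomogeneity, k-space artefacts,
inter-observer segmentation variability (one geometry serves all
subjects, so "manual" volumes are constant across a cohort), and
biological drift between visits beyond the specified variance
components. Passing tests therefore demonstrate correctness of the
computational chain and calibration of the estimators under the assumed
generative model — not clinical performance on patient data.

## Validation scale and runtimes

The end-to-end validation study uses 12 OA / 6 HV on a 32×32×8 grid —
small enough that the full simulate→analyze→stats chain runs in about
two minutes on one CPU while still exercising every stage at realistic
parameter values. Estimator-recovery checks use n = 1000 subjects
(variance components), n = 10⁴ per group (SMD), and 200 replicates
(scale-selection type-I error). Noiseless fit-recovery checks span
K^trans ∈ [0.005, 0.2] min⁻¹ over 500 voxels.

## Known limitations

- One phantom geometry per cohort: manual-segmentation volume metrics
  are degenerate (zero variance) and are skipped with a logged warning.
- The varpro engine assumes a unimodal RSS profile in k_ep after the
  16-point grid scan; pathological multi-modality beyond the grid
  resolution would need the multistart engine.
- ICC confidence intervals use the one-way F-pivot, which is
  approximate for the truncated-at-zero estimator.
- The published repeatability table's printed SDD values were formed
  from unrounded intermediates; recomputation from the printed
  (rounded) wSD/wCV can differ by one unit in the last printed digit,
  and one printed ICC (semiautomatic synovial volume) is not the
  rounding of its own printed variance components. The consistency
  tests encode exactly which rows are reconstructible.
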