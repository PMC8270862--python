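# synodce

Quantitative dynamic contrast-enhanced MRI (DCE-MRI) analysis of knee
synovitis, built for technical validation of imaging biomarkers in
osteoarthritis (OA) research: pharmacokinetic mapping, semiautomatic
segmentation of enhancing synovium, and the repeatability /
discrimination / responsiveness statistics used to decide which
biomarker is fit for experimental-medicine studies. A digital-phantom
cohort simulator makes the entire chain testable without patient data.

## Who this is for

Imaging scientists evaluating DCE-MRI synovitis biomarkers (K^trans,
IAUC₆₀, volume of enhancing pannus), and methodologists who need a
reproducible reference implementation of the analysis chain from raw
SPGR signals to a repeatability report.

## The model

Tissue gadolinium concentration follows the **extended Tofts model**

    C_t(t) = v_p C_p(t) + K^trans ∫₀ᵗ C_p(τ) e^{-(K^trans/v_e)(t-τ)} dτ

with K^trans (min⁻¹) the plasma→interstitium transfer constant, v_e the
extravascular-extracellular volume fraction and v_p the plasma volume
fraction. C_p(t) is a population-averaged arterial input function (two
Gaussians plus a decaying sigmoid) divided by (1 − haematocrit).
Concentration is obtained from the 3D spoiled gradient-echo (SPGR)
dynamic signal via the native T1 (variable flip angle mapping, angles
2/6/14°) and a relaxivity of 3.5 L·mmol⁻¹·s⁻¹; IAUC₆₀ (mM·s) is the
model-free area under C_t for 60 s after bolus arrival in the tissue.

Enhancing synovium is segmented semiautomatically: a **shuffle
transform** subtracts from each post-contrast voxel the closest-valued
pre-contrast voxel within a 3×3 in-plane neighbourhood (robust to
residual motion), Otsu's threshold binarises the difference, and the
intersection with the synovial region-of-interest map is the **volume
of enhancing pannus (VEP)**.

Biomarker quality is quantified by one-way random-effects variance
components: ICC = σ_b²/(σ_b²+σ_w²); smallest detectable difference
SDD = √2·1.96 (≈2.77) × within-subject SD (or CV, chosen by whether
variability scales with magnitude); RMSCV and Lin's concordance
correlation for observer reproducibility; standardised mean difference
(pooled-SD Cohen's d) for OA-vs-healthy discrimination; and the count
of subjects whose 6-month change exceeds the SDD for responsiveness.

## Worked example

```sh
python examples/05_repeatability_stats.py
```

simulates 14 two-visit whole-joint K^trans measurements at the
variance structure σ_b² = 2.1×10⁻⁴, σ_w² = 2.4×10⁻⁵ and prints

```
sigma_b^2 = 2.12e-04   sigma_w^2 = 1.02e-05
ICC = 0.95 (95% CI 0.87, 0.98)
scale = absolute, wSD = 0.0032 min^-1
SDD = 0.0088 min^-1 (24% of group mean)
group discrimination (n=500/500): SMD = 1.06 (means 0.0388 vs 0.0238)
```

ICC near 0.9 means most variance is real between-subject biology; the
SDD says an individual change larger than ~0.009 min⁻¹ is detectable
with 95% confidence under identical conditions. The other examples
cover the AIF (`01`), a single-voxel Tofts fit (`02`), T1 mapping and
concentration conversion (`03`), shuffle segmentation (`04`), and the
full cohort pipeline (`06`).

The pipeline also runs from the shell:

```sh
synodce run-all --config examples/cohort.yaml --out out --seed 0
```

writing per-visit NIfTI maps (T1, K^trans, v_e, v_p, IAUC₆₀, VEP mask),
`biomarkers.csv`, and the `repeatability.csv` / `group_comparison.csv` /
`responsiveness.csv` report tables plus a run manifest.

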