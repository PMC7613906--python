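# Methods

This note records the scientific and numerical choices behind `psymetab`:
what each stage computes, which parameters matter, what the synthetic
cohort generator does and does not emulate, and where the design was
genuinely open.

## Synthetic serum spectra

A spectrum is simulated as a sum of Lorentzian lines on a ppm grid
(default 0.5–9.0 ppm at 0.001 ppm steps):

    I(x) = Σ_m c_m Σ_lines h γ² / ((x − x₀)² + γ²) + baseline(x) + ε(x)

* **Peak library** (`src/psymetab/data/serum_peaks.yaml`, editable): ~24
  serum metabolites with literature chemical shifts and first-order
  multiplets (binomial line patterns, J couplings converted to ppm at a
  configurable spectrometer frequency, default 700 MHz — e.g. the lactate
  doublet's 7 Hz splitting is 0.01 ppm). Lipoprotein fatty-acid envelopes
  (−CH₃ 0.86, (−CH₂−)ₙ 1.26, =CH−CH₂−CH₂− 2.02, =CH− 5.30) are single
  broad Lorentzians (HWHM 0.012–0.015 ppm, at least 5× the sharp-line
  width of 0.0018–0.0022 ppm), which is what a spin-echo-filtered serum
  spectrum's residual macromolecule signal looks like after line-shape
  simplification.
* **Concentrations**: per sample, each metabolite is drawn log-normally
  with mean = (class fold factor) × 1 and coefficient of variation 0.20.
  Default planted effects in the VGKC/GlyR-like class: ×0.7 on the four
  lipoprotein envelopes, ×1.4 on leucine, isoleucine, valine, lysine,
  choline, and glucose. The magnitudes are a calibration choice (the study
  design being emulated reports directions, not fold changes), set so the
  validated classifier operates in the ~95%-accuracy regime.
* **Nuisance structure**: one chemical-shift offset per spectrum
  (SD 0.002 ppm) applied to sharp lines only; a random degree-5 polynomial
  baseline (RMS 0.05 intensity units); white Gaussian noise
  (SD 0.02 per point).
* **Truth record**. Lorentzian tails spread intensity across many bins, so
  "the bins a planted resonance falls in" is defined operationally: a
  retained bin is a planted-effect bin when the noiseless expected
  between-class difference of its integral exceeds one within-class
  standard deviation (between-subject CV plus integrated point noise, both
  computed exactly from the generator's own parameters). With defaults
  this yields ~58 bins. A purely positional (center ± HWHM) definition is
  ill-posed here: envelope tails carry real discriminating intensity
  several bins from the center, and total-intensity closure would blur the
  notion further.
* **Clinical metadata**: 8 PANSS items (P1 Delusions, P2 Conceptual
  disorganisation, P3 Hallucinatory behaviour, N1 Blunted affect, N4
  Social withdrawal, N6 Lack of spontaneity, G5 Mannerisms, G9 Unusual
  thought content), each 1–7; unrated-to-mild symptoms are coded 1. Item
  scores are 1 + a Poisson count (truncated at 6) whose rate multiplies a
  subscale level by a Gamma(4, ¼) patient-severity factor (inducing
  within-patient correlation and realistic IQRs). The subscale levels are
  calibrated so population median totals are 12 (Control and
  NMDAR/LGI1/CASPR2-like classes) and 19 (VGKC/GlyR-like class), with
  positive > negative ≥ general item severities. Demographics (age,
  gender, ethnicity, episode type, disease duration) are drawn from
  distributions shared across classes, i.e. matched by construction.
* Cohort defaults: 70 Control, 20 VGKC/GlyR (13 VGKC + 7 GlyR), 53
  NMDAR/LGI1/CASPR2 (35/9/9). Everything is deterministic given the seed.

What the generator does **not** emulate: acquisition physics (pulse
sequences, relaxation, phase errors, solvent suppression), peak-shape
asymmetry, pH-dependent shift drift of individual metabolites, correlated
metabolite physiology (each metabolite varies independently), and batch or
storage effects. Tests passing on these cohorts therefore demonstrate that
the *analysis machinery* behaves as specified under the assumed statistical
structure, not that the biology of any real cohort is recovered.

## Preprocessing

* **Referencing**: the lactate doublet centroid (mean position of the two
  highest local maxima within ±0.05 ppm of 1.33) is shifted to 1.33 ppm.
  A flat window (fewer than two maxima) raises a referencing error naming
  the sample.
* **Baseline**: a degree-5 polynomial is fitted with iterative asymmetric
  reweighting — points more than 3 robust SDs (1.4826 × median |negative
  residual|) above the fit are dropped and the fit repeated, up to 20
  iterations; convergence is a support change of ≤0.1% of points, and
  non-convergence is flagged in provenance. Peak apex heights are
  preserved to ~2%.
* **Binning**: fixed grid anchored at 0.80 ppm, left-closed/right-open
  0.02-ppm bins, last partial bin dropped, and any bin overlapping the
  open water interval (4.13, 5.22) removed: 383 grid bins − 55 water bins
  = 328 retained. Bin values are trapezoidal integrals with interpolated
  edge nodes, so bins are exactly additive and a constant unit spectrum
  integrates to 0.02 per bin.
* **Normalization**: default is PQN (total-area first, then division by
  the median quotient against the cohort-median spectrum). Plain
  total-area is available but not the default: the lipoprotein envelopes
  hold a large share of total area, so a planted ×0.7 on them inflates
  every unaffected bin by ~9% after row normalization (closure), which
  manufactures spurious apparent effects; PQN's median quotient is robust
  to a minority of truly changed bins and restores per-sample scale.
* **Scaling**: Pareto (divide by √SD) with mean-centering for the
  multivariate models. Inside cross-validation, centering/scaling
  parameters are always estimated on the training split only.
* Samples flagged positive for more than one antibody are excluded from
  model training, driven by a metadata flag and logged in provenance.

## OPLS-DA

With X column-centered/scaled and y coded −1/+1 (centered), each
orthogonal round computes w ∝ Xᵀy (unit norm), t = Xw, p = Xᵀt/tᵀt,
w_o = p − (wᵀp)w normalized, t_o = Xw_o, p_o = Xᵀt_o/t_oᵀt_o, and deflates
X ← X − t_o p_oᵀ. After `n_orth` rounds (default 1; the appropriate count
is genuinely open, so it is configurable and recorded per run) a single
predictive component is fitted on the deflated matrix. Orthogonal scores
are exactly uncorrelated with y by construction. Prediction applies the
training transform, strips orthogonal variation component-wise, scores on
w, and thresholds at the midpoint of the training class-mean scores. With
`n_orth = 0` the model reduces exactly to single-component PLS1.

**VIP** is computed over the predictive component(s) only — orthogonal
variation is class-unrelated by construction, so including it would dilute
the importance ranking. For one component VIP_j = √p·|w_j|/‖w‖, and
Σ VIP² equals the number of bins.

## Validation and significance

* **Ensemble CV**: default scheme draws, per repetition, a fresh
  stratified 90/10 split; the model (including scaling) is fitted on the
  90% and evaluated on the untouched 10%, giving one
  accuracy/sensitivity/specificity triple per repetition (sensitivity =
  recall of the case class). 50 repetitions by default. A pooled
  stratified 10-fold scheme (`scheme="kfold"`, every sample tested exactly
  once per repetition) is also implemented.
* **Permutation null**: class labels are permuted uniformly and the full
  procedure re-run (one repetition per permutation), 100 permutations by
  default.
* **Significance**: two-sample Kolmogorov–Smirnov between observed and
  null metric distributions (exact p when the smaller sample has ≤10
  values), flagged significant only when p ≤ α **and** the observed mean
  exceeds both the null mean and the null's (1−α) quantile. The quantile
  gate operationalizes "greater than the null distribution" and is what
  keeps the flag calibrated: repetitions of the one observed labelling
  locate its chance-level performance far more precisely than independent
  null draws, so the KS p value alone is anticonservative under the null
  (with the pooled k-fold scheme severely so — its repetition spread is
  ~2.5% against a ~5.5% between-labelling null spread, which is why
  `holdout` is the default for significance testing). Under null cohorts
  the flag fires in 0/20 seeds; planted-effect comparisons are flagged at
  p ≈ 0 in every seed.
* **Bin selection**: VIP vectors of all ensemble members are averaged per
  bin; bins are ranked by mean VIP (ties broken by ppm ascending); the
  cut-off is the point of the axis-normalized sorted curve farthest from
  the chord joining its endpoints (a deterministic stand-in for picking
  the inflection by eye), with a VIP > 1 fallback when the curve is affine
  within tolerance. Selection recovers the planted-truth bins with ~0.9
  recall and ~0.9 precision on default cohorts.

## Univariate ladder

`compare_groups(method="auto")` applies: Shapiro-Wilk per group at α=0.05
(groups under 3 observations count as non-normal) → non-normal data go to
Mann-Whitney (2 groups) or Kruskal-Wallis + Dunn (more); normal data are
gated by Levene's test → ANOVA + Tukey under variance homogeneity, else
Brown-Forsythe and Welch ANOVA with Dunnett's T3. Dunn's test uses mean
ranks with tie correction and Bonferroni adjustment within the post-hoc
family; Dunnett's T3 uses pairwise Welch t with Welch–Satterthwaite df and
the Sidák family form (the independent-case studentized-maximum-modulus
tail). Fisher's exact test reports the two-sided hypergeometric p and the
sample odds ratio (Haldane–Anscombe corrected when a cell is zero).
Bonferroni multipliers are explicit arguments, never guessed: reports
record raw and adjusted p values together with m.

## Power analysis

Two-group binned-spectrum data are simulated from a probabilistic-PCA
generative model (q = 2 latent dimensions, unit-variance loadings,
isotropic unit noise); a fraction `prop_significant` of bins receives a
standardized mean shift in the second group; per-bin moderated t
statistics (SAM-style median-SE fudge term) are computed; the top
`prop_significant` fraction of bins is declared significant; and the FDR
among declarations — known exactly from the simulation truth — is averaged
over Monte-Carlo runs. The estimate is the smallest per-group n whose mean
FDR meets the target. Common random numbers (candidate sizes nested inside
one maximal draw per run) keep the averaged FDR curve nearly monotone.

The data-free effect-size default is **1.78 marginal SDs**, calibrated
once (at 800–1500 Monte-Carlo runs) so that the
asymptotic mean-FDR curve crosses the 0.05 target exactly between n = 11
and n = 12 at the reference settings (328 bins, 20% true effects), the
operating point of published PPCA-based metabolomics power calculations in
data-free mode. At 100 Monte-Carlo runs the first-crossing estimator
returns 11–13 across seeds and at 20 runs it ranges 9–14, so ≥100 runs are
recommended; `scripts/acceptance.py` uses 300, at which the estimate is 12
for most seeds (occasionally 11).

## Pipeline report

`run_pipeline` chains simulation → preprocessing → PCA discovery (cluster
sizes, silhouette, covariate overlay) → the three pairwise OPLS-DA
validations → VIP selection, fold changes and per-bin ANOVA/Tukey
confirmation (Bonferroni across selected bins) → PANSS Kruskal-Wallis/Dunn
comparisons → an antibody-blind high-vs-low PANSS model (median split,
ties to "high") reported as a contrast with the antibody-defined model.
Every stochastic stage derives its seed from the master seed by fixed
offsets; the JSON report is byte-identical across runs of the same
configuration, and every reported number traces to a per-stage artifact
file. Reported problem sizes (50 repetitions, 100 permutations, 100
Monte-Carlo power runs) are the package defaults chosen to keep a full
study replica around ten seconds on one core.

## Known limitations

* The generator's independence assumptions (metabolite-wise and
  sample-wise) understate the correlation structure of real serum
  metabolomes; recovery statistics on synthetic cohorts are therefore
  optimistic relative to real data.
* The KS-based significance decision is kept for fidelity to ensemble-CV
  practice in this field, but its calibration rests on the exceedance
  gate; a plain permutation test of the mean metric is the statistically
  cleaner alternative.
* Dunnett's T3 family adjustment ignores the correlation between pairwise
  comparisons (independent-case SMM), making it slightly conservative.
* JCAMP-DX support covers the uncompressed AFFN `(X++(Y..Y))` subset only.
* Multi-class discrimination, kernel OPLS variants, and FDR procedures
  other than Bonferroni are out of scope.
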