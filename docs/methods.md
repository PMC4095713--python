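# Methods

## Study design

Three groups of tooth germs represent three developmental stages: group I
(cap), group II (early bell), group III (late bell). Each group contains
five cases; each case contributes several images whose segmented cells form
the *case database*. From every case database a random sample of 100 cells
(without replacement) enters the analysis, so each group is summarised by a
500-cell vector per parameter. Per-cell parameters are area `A` (µm²),
perimeter `P` (µm) and form factor `FF = 4πA/P²`.

Analysis layers:

1. **Descriptive statistics** per case and group (mean, SD, min, max), plus
   fixed-class histograms (class widths 3.5 µm² for A, 7 µm for P, 0.05 for
   FF) with a Gaussian overlay `n · width · φ((x − mean)/sd)/sd`.
2. **Hypothesis tests**: one-way ANOVA across the three groups and pairwise
   t-tests (Welch by default), with significance tiers at 0.05 / 0.01 / 0.001.
3. **Relative distances** (below).
4. **Regression**: per-group OLS of P on A with the Pearson correlation,
   and the line-proximity ratio at a common evaluation area (30 µm²).

## Mean-value-scaled relative distance

For a set `E` of positive values with mean `M(E)`, the mean-scaling
transformation is `ēᵢ = (eᵢ − M(E))/M(E)`; the scaled values sum to zero
and are invariant to a common rescaling `eᵢ → c·eᵢ`.

* **Intragroup**: `RD_E(eᵢ) = |ēᵢ|` applied to the five case means of one
  group/parameter. Cases with `RD < 0.10` (strict) are conventionally
  "similar"; the report records each RD, the pass flags and the maximum.
* **Intergroup**: `RD(eᵢ, eⱼ) = |eᵢ − eⱼ|/M(E)` applied to the three group
  means, scaled by their global mean. The ratio
  `RD(I,II)/RD(II,III)` quantifies how much closer the middle stage is to
  one neighbour than the other; for form factor it is ≈ 5.

## Synthetic-data model

The original images are not deposited, so the measurement chain is
exercised on synthetic fields with analytic ground truth.

**Per-cell sampling.** For each stage, `(A, FF)` pairs are drawn from
marginal truncated normals matched to the published group mean/SD:

* `A ~ TruncNormal(μ_A, σ_A)` truncated to positive values;
* `FF ~ TruncNormal(μ_FF, σ_FF)` truncated to
  `[μ_FF − 1.65σ, μ_FF + 4.5σ] ∩ (0, 1]`, reproducing the right-skewed
  published FF ranges;
* the two marginals are coupled through a Gaussian copula with rank
  correlation −0.85, because in real populations larger fibroblasts of a
  stage tend to be the more elongated ones. The implied perimeter is
  `P = √(4πA/FF)`, which is what makes per-group A–P correlations > 0.9
  emerge naturally.

**Shape realisation.** Cap cells are star-like outlines
`r(θ) = R(1 + a·cos kθ)` with the lobe amplitude `a` solved numerically so
the polygon hits the target FF; bell cells are fusiform (elongated
ellipse-like) outlines with the aspect ratio solved for the target FF.
Each outline is a dense polygon whose exact area and perimeter (shoelace /
segment sum) are stored as ground truth. Small rendering floors (minimum
area 1 µm², minimum semi-minor axis ≈ 1.5 px, minimum star inner radius
≈ 1.2 px) keep every realised cell rasterisable.

**Placement and rendering.** Cells are placed largest-first at uniformly
random positions, with rejection until the 2 px-dilated footprint is free,
so regions never touch even diagonally. Fields are rendered as 8-bit RGB:
stained-cell foreground (120, 60, 140) on a light background (225, 190,
210), both with Gaussian pixel noise.

## Segmentation

A classical colour-threshold front end: optional per-channel percentile
contrast stretch; inclusive per-channel RGB band threshold (defaults accept
the synthetic foreground with > 6σ headroom at the default noise level);
removal of components below a scrap cut-off (default 5 µm², converted to
pixels by the calibration); deterministic 8-connected labelling ordered by
first pixel in a row-major scan.

## Perimeter estimation

Three registered estimators:

* `chain` — Moore-neighbour boundary tracing; the perimeter is the
  centre-to-centre chain length with isothetic steps counted as 1 px and
  diagonal steps as √2 px. The tracer terminates on state repetition
  (position + backtrack), which is required for thin regions whose boundary
  visits pixels twice. A single pixel is assigned 4 isothetic steps.
* `chain_corrected` (default) — the chain length multiplied by the Kulpa
  factor `(π/4)/(2√2 − 2) ≈ 0.948`, the classical correction for the
  systematic overestimation of digitised straight edges.
* `crofton` — the 4-direction Crofton-formula estimator, as an independent
  cross-check.

On digitised discs of radius ≥ 40 px, the corrected chain estimator is
within ~2% of the true circumference; on study-like star and fusiform
shapes, pixel measurements agree with the polygon oracle within 5% (area),
3% (perimeter at radius ≥ 40 px) and 10% (FF).

## Calibration choice (0.125 µm/px)

Defaults render a 256 µm field of view at 0.125 µm/px (2048×2048). At a
coarser 0.25 µm/px, the thin processes of star-like cells and the tips of
strongly elongated fusiform cells degenerate into 1-px chains or fragments;
perimeter and FF errors then differ *between* shape families
(shape-dependent bias up to ~10%, with occasional FF > 1 artifacts), which
distorts RD ratios even though they are invariant to a *common*
multiplicative bias. At 0.125 µm/px all estimators agree with the polygon
oracle to within ~5% on every stage's shapes, so this resolution is the
study condition. The calibration remains a config option for coarser,
faster runs.

## Default full study

`StudyConfig()` defaults: 5 cases × 5 images per group, 110 cells per
image, sample size 100, seed 0. The run takes roughly 4–5 minutes on one
CPU and reproduces the qualitative findings: FF ordering
cap > early bell > late bell, ANOVA p ≪ 0.001 for all parameters,
per-group A–P correlation r > 0.9, FF RD ratio within 4–7, and regression
lines II and III much closer to each other than to line I.

## Limitations

* The synthetic generator matches the published group means and SDs and a
  plausible A–FF coupling, but the true per-cell joint distribution of the
  histology material is unknown; synthetic results validate the *pipeline*,
  not the biology.
* The published per-case tables are printed summaries; RDs recomputed from
  them can differ in the last digits from the originally reported RDs
  (which were computed from unrounded data), e.g. the form-factor RD ratio
  5.17 recomputed vs 5.33 as reported.
* Pixel-based measurements carry resolution-dependent bias; at the default
  calibration the residual bias is a few percent and common across stages,
  but absolute perimeters (and hence FF) should not be compared across runs
  with different calibrations without re-validation.
* The placement model spreads cells uniformly without the spatial
  organisation (density gradients, alignment) of real pulp tissue; it is
  adequate for measurement validation, not for spatial statistics.
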