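# Methods

`precisionif` implements a tile-based quantification pipeline for dual-marker
immunofluorescence of tissue sections, a cohort-level correlation analysis
against FISH gene copy number, the Langmuir binding-kinetics model that
justifies short antibody incubations, and a seeded synthetic-slide generator
that makes every stage testable without patient material.

## Tile quantification

A scanned slide is a mosaic of tiles, each carrying three registered
grayscale channels normalized to [0, 1]: DAPI (nuclei), pan-cytokeratin
(CK, epithelium) and the target membrane marker (HER2). Per tile:

1. **CK mask.** Otsu's criterion (threshold maximizing between-class
   variance of the 256-bin intensity histogram) selects CK-positive pixels.
   Carcinoma cells are CK-positive, so this restricts interrogation to
   epithelium regardless of how strongly the target is expressed.
2. **Nuclear exclusion.** The DAPI channel is thresholded the same way; the
   nuclear mask is dilated by `dilation_radius` (default 1 px, guarding
   against partial-volume bleed at the nuclear rim since the membrane marker
   abuts nuclei) and subtracted. HER2 and CK are not nuclear markers.
3. **Measurement.** The tile's readout is the arithmetic mean CK and HER2
   intensity over the remaining ROI. A tile with fewer than
   `min_roi_pixels` (default 50) ROI pixels is invalid — means over tiny
   ROIs are unstable.

Otsu always produces *some* threshold, including on stroma-only tiles where
the "classes" are halves of the noise distribution. A tile is therefore
treated as empty when the mean contrast between the foreground and
background classes is below `noise_floor` (default 0.12 intensity units), or
when the foreground covers less than `min_foreground_fraction` (default 1%)
of the tile. The contrast form of this guard matters: an absolute floor on
the threshold *value* misclassifies genuinely epithelial tiles whenever the
background is very dark, while class contrast discriminates signal from
noise in every background regime (pure noise yields a contrast of roughly
2 noise SDs).

## Tile filtering

Per case, in order:

1. invalid tiles are dropped;
2. a **lower CK filter** removes tiles with little or no epithelium. The
   case-specific threshold is Otsu on the per-tile `ck_mean` distribution
   when that distribution is bimodal, else a percentile fallback (default
   10th). Bimodality is judged by Otsu effectiveness (between-class /
   total variance) with cutoff 0.8 — a unimodal Gaussian tops out near
   0.64 and a uniform near 0.75, so anything below 0.8 is treated as
   unimodal. Two robustness guards: the decision is made with the brightest
   5% trimmed off (saturating artifact tiles would otherwise mimic an upper
   mode), and a candidate threshold that would strand the majority of tiles
   below it is rejected (a stroma/epithelium split never discards the
   majority of measurable tiles);
3. an **upper filter** removes exactly `floor(0.05 · n_survivors)` of the
   brightest-CK surviving tiles (ties broken by tile id), guarding against
   saturating artifacts such as small fluorophore agglomerates.

Cases with fewer than `min_tiles` (default 20) usable tiles at any stage are
excluded with an explicit status rather than silently scored.

## Scoring

Each retained tile contributes one HER2/CK ratio. Because a case-level
staining-quality factor multiplies both channels equally, the ratio cancels
it — the rationale for CK normalization. The ratio histogram (frequencies
normalized by tile count; bin width by Freedman–Diaconis with a fallback
count of 50 and a cap of 4096; axis shared across the batch, spanning
[0, max ratio in batch]) is fitted with a Gaussian
a·exp(−(x−μ)²/2σ²) by least squares, initialized at the histogram moments.

Scores are normalized within the staining batch by its IHC-3+ positive
control:

- **M-score** = μ_case / μ_pos — mean expression relative to the control;
- **Σ-score** = σ_case / σ_pos — dispersion relative to the control
  (overexpressing tumors show wider tile-to-tile scatter);
- **MTP-score** = M · Σ.

QC: a case whose fit fails to converge, or whose adjusted R² falls below
`r2_min` (default 0.5 — the smallest round value excluding the reference
study's two discarded fits at 0.4837 and 0.4806) is excluded. A batch whose
positive control fails QC is unscorable as a whole; the negative control is
reported for context but never enters the normalization.

## Cohort analysis

Copy-number classification follows the closed-lower-bound rule: N_FISH < 4
Negative, 4 ≤ N_FISH < 6 Equivocal, N_FISH ≥ 6 Positive. Non-control,
QC-passed cases are correlated with N_FISH (or the HER2/CEP17 ratio) by
Pearson's ρ, and a power-law exponent α of y ~ x^α is estimated by ordinary
least squares in log–log space (non-positive values excluded with a logged
count). Heterogeneity — two tumor subpopulations expressing at different
levels — is flagged when a 2-component Gaussian mixture beats 1 component by
more than `bic_margin` (default 10) BIC units *and* the component means are
separated by more than `separation` (default 2) pooled standard deviations.
The mixture criterion quantifies what is a visual observation in routine
practice; both knobs are configurable.

## Binding kinetics

Single-site Langmuir model with association rate k_on (M⁻¹s⁻¹; printed
sources often write the unit as M⁻¹, but the recognition-rate formula
requires a first-order rate once multiplied by concentration), dissociation
rate k_off (s⁻¹), bulk antibody concentration c_bulk (M):

- K_D = k_off / k_on, θ_eq = c_bulk / (c_bulk + K_D),
- recognition time constant τ = 1/(k_on·c_bulk + k_off),
- desorption time t_d = 1/k_off,
- occupancy θ(t) = θ_eq·(1 − e^(−t/τ)), pseudo-first-order and therefore
  independent of surface antigen density.

With typical IgG constants (k_on ~ 10⁶ M⁻¹s⁻¹, k_off ~ 10⁻³ s⁻¹,
c_bulk ~ 10⁻⁸ M): τ ≈ 91 s and t_d = 1000 s. Since τ < t_d always holds for
c_bulk > 0, a few-minute incubation approaches equilibrium while desorption
stays negligible — the basis for short-incubation staining. Because θ(t)
does not depend on antigen density, the bound-antibody signal is
proportional to the antigen signal at *any* time in the ideal model. The
loss of proportionality observed at hour-long incubations is reproduced
phenomenologically: ab = x/(1 + x/k_sat) with x = θ(t)·ag, a hyperbolic
saturation that recovers proportionality as k_sat → ∞ and degrades
linearity more the larger θ(t) grows. This term is a descriptive device,
not a mechanistic claim.

## Synthetic data generator

The generator emulates the statistical structure the analysis relies on,
not tissue appearance (no PSF, no stitching artifacts, no texture):

- a tile is epithelial with probability `epithelial_fraction` (default
  0.7); epithelium is a randomly placed disc (~42% of the tile dimension),
  stromal tiles carry only background and sparse nuclei;
- nuclei are DAPI-bright discs (radius 4 px, ~25 per 128×128 epithelial
  tile, area-scaled) with CK/HER2 suppressed to 20% inside;
- the tile's HER2 level is drawn Normal(E, cv·E) around the case's
  expression level E, with cv = 0.05 + 0.25·E by default so dispersion
  grows with expression, reproducing the wider scatter of amplified tumors;
- intensities: background 0.05 per channel, epithelial CK 0.5, nuclear DAPI
  0.8, additive per-pixel Gaussian noise SD 0.01, clipped to [0, 1];
- a case-level staining-quality factor (Normal(1, 0.1), clipped to
  [0.7, 1.3]) multiplies all channels, exercising the CK-normalization
  rationale;
- with probability `artifact_rate` (default 0.03) a tile receives a
  saturating CK disc of intensity 1.0 — the agglomerate artifact the upper
  filter exists for;
- a heterogeneous case assigns each tile wholly to one of two subclones
  (tiles are small relative to clonal regions);
- all randomness flows from explicit integer seeds; per-tile streams are
  keyed by (case seed, tile index) so generation is order-independent and
  bit-reproducible.

Cohorts place one positive (expression of a strongly amplified case,
N_FISH-like value 12) and one negative (N_FISH-like 1.5, expression ≈ 0)
control in every batch. Ground-truth copy-number values span a configured
range (default 1.9–15) and map to expression through a monotone map. The
default map is saturating, E(n) = 0.9·(n−1.5)/(8+(n−1.5)) — a config choice
standing in for an unknown biology (copy-number gain does not always mean
overexpression), not an inferred law. A power-law map is provided for
exponent-recovery experiments.

What passing tests therefore show: the pipeline recovers a monotone
expression signal, cancels staining-quality variation, rejects stromal and
artifact tiles, and detects planted heterogeneity — under a generator whose
assumptions (disc geometry, Gaussian noise, single CK level) are far
simpler than tissue. They do not validate performance on real slides,
scanner artifacts, autofluorescence, or focal staining failures.

## Numerical choices and degenerate inputs

- Otsu thresholds come from a 256-bin histogram; a constant channel returns
  the constant and the tile is treated as empty. Ties on the between-class
  variance plateau (empty bins between modes) are broken by the first
  maximizing bin.
- The Gaussian fit uses bounded least squares (amplitude ≥ 0, σ > 0) with
  moment initialization; non-convergence is a reported state, not an
  exception. Adjusted R² uses 3 fitted parameters over all bins of the
  shared axis.
- The upper filter's floor rule means fewer than 20 survivors lose no tile.
- Histograms with fewer than 3 occupied bins (e.g. a noise-free negative
  control whose ratios are all identical) are unscorable by construction
  and excluded with a status.
- Mixture fits use 3 EM restarts with a fixed seed, so heterogeneity
  flagging is deterministic.

## Problem sizes

The test suite exercises two full 25-case, 5-batch cohorts (100 tiles per
case, 128×128-pixel tiles): one at default noise for score–copy-number
correlation, one noise-free (zero background, zero pixel noise, no
artifacts, power-law expression map) for exponent recovery — the noise-free
limit is the only regime in which the log–log slope is exactly the
generator exponent, because a nonzero background adds an additive offset to
every ratio. These sizes keep a full run in tens of seconds while leaving
per-case sampling error (≈ σ/√70 tiles) an order of magnitude below the
effects being measured.

## Known limitations

- The generator's epithelium is a single disc per tile; real epithelial
  geometry (glands, nests, infiltrative strands) produces more boundary
  pixels and harder masks.
- HER2 is painted uniformly on the epithelial ROI rather than as a membrane
  pattern; ROI means are unaffected but texture-sensitive extensions would
  need a membrane model.
- The saturation term in the kinetics module is phenomenological; fitted
  k_sat values have no physical interpretation.
- The lower CK filter's bimodality heuristic assumes at most two modes;
  three-population slides would need the mixture machinery instead.
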