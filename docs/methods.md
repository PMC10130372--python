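# Methods

This note records the models, conventions and numerical choices behind
`glycoclust`, in the spirit of a statistical software vignette: what each
stage assumes, which knobs matter, and what the synthetic validation does
and does not establish.

## Automatic thresholding

A fluorescence channel is modelled as a bright signal minority over a
unimodal background. The threshold is `m + k·s` from a robust background
model: `m` the median and `s = 1.4826 · MAD` of the background pixels,
re-estimated iteratively after excluding pixels above the current cut
(at most 20 passes, relative tolerance 1e-6). `k` (default 6) is the only
tuning constant; it positions the cut far out in the background tail, so
per-image operator tuning is unnecessary and the false-positive rate per
image is roughly constant.

Two refinements matter in practice:

- **Initialisation.** The first `m, s` are taken from the lower half of
  the support intensities. Initialising from the full support can lock
  the iteration onto a signal-dominated fixed point whenever signal
  occupies more than about half the support (dense nuclear staining is
  the common case); the lower-half seed recovers the background mode in
  that regime and coincides with the plain iteration otherwise. This was
  verified on lognormal mixtures: with 60% foreground, full-support
  initialisation returns a threshold above the foreground (cellularity
  collapses to ~0), lower-half initialisation recovers it to within a
  percentage point.
- **Plateaus.** If the background subset has zero MAD it sits on an exact
  plateau (a constant image, or bare glass at zero around a tissue
  section). A dominant plateau (≥ 90% of the subset) is treated as the
  background itself and the threshold is set infinitesimally above it —
  so a constant image yields an empty signal map, and the glass/tissue
  step yields "tissue = everything above glass". Otherwise the spread
  falls back to IQR/1.349, then to the standard deviation.

Tissue support is the thresholded nuclear channel after morphological
closing (radius 25 µm), removal of objects under 0.01 mm² and hole
filling; both sizes scale with `pixel_size`. A uniformly positive frame
is all tissue; an all-zero frame raises `EmptyTissueError`.

## Intensity metrics

`mean_above_threshold` averages intensities over called signal pixels and
is defined as 0 for an empty signal map, so cohort tables never contain
missing cells. The bright-pixel metric uses the nearest-rank percentile
convention: the default `mean_top_decile` averages the brightest ⌈n/10⌉
tissue pixels (the pixels at/above the 90th-percentile intensity), e.g.
mean(91..100) = 95.5 on intensities 1..100. The reading of "90th
percentile intensity" as the percentile *value* itself is available via
`top_decile="percentile_value"`; the two differ and the choice is
recorded with the output.

## Spatial concentration and clusters

The concentration map is the centred `w × w` box count of signal pixels
divided by `w²`, zero-padded at the frame border (signal is quantified to
the section edge). It is computed with an integer summed-area table and
is therefore *exactly* the brute-force definition; a band-tiled variant
with a `w/2` halo reproduces the whole-image map bit-for-bit and is the
strategy for slide-scale images (a full slide at ~3000 px/mm is ~10⁹–10¹⁰
pixels; at desk scale the package keeps mm semantics and coarsens
`pixel_size` instead). The window is stated in mm (default 1 mm) and
converted to the nearest odd pixel width.

Clusters are tissue pixels with concentration ≥ τ. Both region counts
(8-connected by default, 4-connected as an option) and clustered-area
fractions are reported over a τ ladder; the headline "cluster amount" is
the clustered-area fraction at the primary τ (default 0.10), preferred
over region counts because area is stable when one cluster fragments
into touching regions.

## Cluster types and heterogeneity

Typing is pixelwise on the two cluster masks called at the same τ:
`dual = A ∧ B`, `A_only = A ∧ ¬B`, `B_only = B ∧ ¬A`. Pixel algebra
makes the partition identity `area(A_only) + area(dual) = area(A)` exact
on every input, which the tests assert verbatim. Type fractions are
dichotomized at the cohort level with ROC cutoffs (midpoints between
sorted unique values, Youden's J maximised, ties toward the lower cutoff
to favour sensitivity) against the recurrence labels — the cutoffs are
cohort-derived by design, so a specimen's `n_types` (0–3) and the
heterogeneity flag `n_types ≥ 2` are only meaningful within a cohort
analysis.

## Outcome statistics

- **χ².** Pearson statistic with expected counts from the margins, 1 df,
  no continuity correction; the published 2×2 table [[11,2],[2,6]]
  yields 7.46 (p = 0.0063) uncorrected, whereas the Yates-corrected value
  (~5.3) does not match the printed 7.5 — hence uncorrected is the
  default. Specimens with unknown outcome are excluded before the table
  is built.
- **Kaplan–Meier / log-rank.** Standard product-limit estimator and
  two-group log-rank with simultaneous risk-set accounting for ties and
  the hypergeometric variance; median splits send values equal to the
  median to the "low" group (so ⌈n/2⌉ specimens land low when values are
  distinct).
- **Cox.** Single-covariate Breslow partial likelihood maximised by
  Newton–Raphson with the analytic score and information (≤ 50
  iterations, score tolerance 1e-8, steps clipped to ±2). A constant
  covariate raises; a monotone likelihood is flagged as separation with
  β̂ clipped at ±30 (or |β̂| ≥ 15 post hoc, where the likelihood is
  numerically flat). The fit is validated against an independent
  coarse-to-fine grid search of the same likelihood (agreement ≤ 1e-4)
  and against lifelines' Breslow implementation.
- **Explained randomness.** `ρ²_XOQ = 1 − exp(−LR/k)` with `LR` the
  likelihood-ratio statistic and `k` the number of observed events — the
  events-based normalisation recommended under censoring; dividing by the
  total sample size instead is available as `variant="n"`. ρ² is 0
  exactly when the covariate is uninformative and is bounded below 1.
- **Reproducibility.** Between-run agreement is Spearman correlation per
  shared quantification (reported only when ≥ 3 specimens match) plus the
  fraction of specimens with identical heterogeneity flags.

## Synthetic cohorts

The generator emulates the structures the analysis assumes, not the
microscopy itself. Marker signal is a Neyman–Scott process: Poisson
parent points on the tissue (`parent_rate` per mm²), each dispersing
`offspring_per_parent` signal pixels with isotropic Gaussian sd
`offspring_sd` (µm), clipped to tissue, plus uniform stray signal at
`uniform_noise_rate` per mm². Small vs large `offspring_sd` reproduces
the punctate-vs-broad cluster contrast; sharing a fraction
`dual_overlap` of parent locations between the channels creates dual
clusters as a property of cluster *locations*, not pixel correlation.
Intensities are lognormal — background (µ=4.0, σ=0.3) and foreground
(µ=6.5, σ=0.4), ~12× brighter at the median; the lognormal background is
a modelling choice, not a measured scanner property. The nuclear channel
occupies tissue pixels independently at `nuclear_density`. The cancer
annotation is one compact connected lesion covering
`cancer_region_fraction` of the tissue; cluster parents can be confined
to it for pathology-overlap experiments.

Default conditions: 256×256 px frames at 20 µm/px (a 5.1 mm field — a
desk-scale stand-in for whole slides that keeps every mm-scale knob
meaningful), tissue fraction 0.5, parent rate 0.8/mm², 600 offspring at
sd 150 µm (cluster cores then clear the 1-mm box concentration of 0.10),
noise 50 px/mm². Each specimen draws one construction profile from
{none, A, B, A+B, A+B+dual} (probabilities 0.15/0.15/0.15/0.20/0.35),
fixing its ground-truth number of cluster types; recurrence times follow
an exponential proportional-hazards model, hazard
`0.2 · exp(β · 1{n_types ≥ 2})` per year with β = ln 4 by default,
censored at 3 years. All randomness flows from one integer seed through
counter-based per-specimen streams, so a specimen's draws are independent
of cohort size and of whether images are rendered; `simulate_outcome_table`
reuses the same streams to serve the replicate-heavy statistical
simulations without rendering images.

The tissue mask is a smoothed Gaussian field with a broad radial bump
(one dominant section per slide), thresholded and reduced to its largest
filled component; the threshold is found by bisection with a dense-scan
and re-smoothing fallback, then trimmed morphologically to the target
fraction ±2 percentage points (failure beyond ±5 points raises with a
diagnostic rather than returning an empty mask).

**What passing tests show — and don't.** The synthetic channels have
stationary background, no illumination gradients, no staining-round
misregistration, no autofluorescence and pixel-iid nuclei; recovery
results (tissue Jaccard ≥ 0.8, signal F1 ≥ 0.9, exact truth-concordant
heterogeneity calls) therefore validate the algorithmic chain, not
robustness to those real-slide artifacts. The outcome model is exactly
proportional hazards with a binary covariate, which is the regime where
χ²/ρ² recovery is well-posed.

## Known limitations and open choices

- Exactly two markers; no ≥3-marker generalisation.
- The published ρ² values and pathologist ROI counts from the original
  cohort depend on the study's slides and survival times and are not
  reproducible here; they are covered by directional/property simulations
  only.
- The sampling sd of the Breslow MLE for a binary covariate at n = 200
  with all events is ~0.17, so "±0.25 recovery" holds in ~84% of
  replicates, not more — the parameter-recovery tests assert
  unbiasedness of the mean plus a coverage bound consistent with that
  computation.
- Log-rank at ~45 events runs marginally anticonservative (~0.054 at
  nominal 0.05, measured over 4000 pure-exponential replicates); the
  calibration check's [0.03, 0.07] band accounts for this plus Monte
  Carlo noise at 500 replicates.
- ROC-derived cutoffs use the outcome labels (as in the source workflow),
  so heterogeneity calls on small cohorts inherit outcome noise; the
  truth-concordance reported by the acceptance run varies accordingly.
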