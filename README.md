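# glycoclust

Spatial cluster-heterogeneity analysis of glycan biomarkers in multiplexed
immunofluorescence whole-slide images.

Pancreatic ductal adenocarcinoma (PDAC) tumors are internally heterogeneous:
the glycans CA19-9 and STRA mark distinct, partially overlapping
subpopulations of cancer cells, and neither marker's *amount* predicts
recurrence after resection. What does carry signal is the **co-occurrence of
distinct spatial cluster types** — regions clustered in only one marker or
in both — within the same tumor. `glycoclust` implements that analysis end
to end, for anyone quantifying multi-marker fluorescence slides without
per-image operator tuning:

1. **Automatic signal detection.** Each channel is thresholded at
   `m + k·s`, where `m` and `s` are the median and scaled median absolute
   deviation (1.4826·MAD) of the background, iteratively re-estimated after
   excluding pixels above the cut (default `k = 6`). The *signal fraction*
   is the share of tissue pixels above threshold; the tissue support itself
   comes from the nuclear channel, which also yields a cellularity proxy.
2. **Moving-box spatial concentration.** For window width `w` (1 mm by
   default), the concentration at pixel `p` is
   `C(p) = (# signal pixels in the centred w×w box) / w²`, computed exactly
   via a summed-area table with zero padding at the section edge. Tissue
   where `C ≥ τ` (default `τ = 0.10`) forms *spatial clusters*; the
   clustered-area fraction is the per-marker *cluster amount*.
3. **Cluster typing and heterogeneity.** Pixelwise algebra on the two
   cluster masks partitions clustered tissue into `A_only`, `B_only` and
   `dual = A ∧ B`. After ROC (Youden-J) dichotomization of the three type
   fractions against outcome, a specimen's heterogeneity flag is
   `n_types ≥ 2`.
4. **Outcome statistics.** Pearson χ² (1 df, no continuity correction) on
   the 2×2 heterogeneity × recurrence table; Kaplan–Meier with median-split
   log-rank per quantification; single-covariate Cox fits (Breslow partial
   likelihood, Newton–Raphson) summarised by the Xu–O'Quigley explained
   randomness `ρ² = 1 − exp(−LR/k)` with `k` the number of events.
5. **Pathology overlap.** The tissue is tiled into ~3 mm ROIs (three times
   the concentration window), each classified by the cluster types it
   contains, and overlap with a cancer annotation mask is summarised per
   heterogeneity group.
6. **Synthetic cohorts.** A Neyman–Scott generator (Poisson cluster
   parents, Gaussian offspring, shared parents creating dual clusters,
   lognormal intensities) plus an exponential proportional-hazards outcome
   model provide ground truth for every stage.

## Worked example

`examples/study_tables.py` runs the association statistics on the
published per-specimen cluster-type calls from the 22-tumor PDAC resection
cohort the method was developed on:

```
known-outcome specimens: 21 (13 recurrence, 8 no recurrence)
recurrence within 1 year: 7 (33.3%)

heterogeneity (>= 2 cluster types) x recurrence: [[11,2],[2,6]]
chi2 = 7.46 (p = 0.0063)
```

11 of 13 recurrent tumors carried two or more cluster types against 2 of 8
non-recurrent ones: heterogeneity in cluster types, not marker amount,
separates the outcomes. `examples/quantify_specimen.py` shows the
per-specimen half of the pipeline on a synthetic specimen seeded with all
three cluster types:

```
specimen S000 (profile AB_dual, 3 cluster types seeded)
  tissue area: 31651 px (48.3% of frame)
  signal fraction   CA19-9 0.161   STRA 0.121
  cluster amount    CA19-9 0.530   STRA 0.370
  cluster regions   CA19-9 3       STRA 4
  type fractions    A-only 0.185  B-only 0.025  dual 0.345
  cellularity 0.302
```

The other examples cover cohort-level association on a simulated cohort
(`cohort_association.py`), ROI-level pathology overlap
(`pathology_overlap.py`) and between-section reproducibility
(`section_reproducibility.py`).

A thin CLI wraps the same pipeline for shell use:

```
glycoclust simulate --out work/simulated --n 12 --seed 1
glycoclust all --out work --n 12 --seed 1
glycoclust quantify --config config.yaml --specimen S003
```

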