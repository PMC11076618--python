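# fibremorph

Automated histomorphometry of fluorescently stained skeletal-muscle
cross-sections, built for studies of fibre-type remodelling — for example
the posterior cricoarytenoid (PCA) muscle under long-term functional
electrical stimulation — where the readouts are the fibre type ratio,
fibre size, hybrid-fibre proportion and intramuscular collagen content,
measured on multiple images per animal and compared across experimental
conditions.

The package is aimed at muscle physiologists and image-analysis
scientists who need the whole chain in one tested place: pre-processing,
fibre segmentation, slow/fast/hybrid typing, minimum-Feret morphometry,
collagen and nerve quantification, and the mixed-model statistical layer.
Because study microscopy images are rarely shareable, a synthetic
tissue-image simulator with pixel-exact ground truth is a first-class
component: every stage is validated by parameter recovery.

## What it computes

Images carry three channels: red = slow myosin, green = fast myosin,
orange = collagen. Per image:

1. **Pre-processing** — 8-bit conversion, collagen enhancement by
   percentile histogram stretching, and composition of the segmentation
   input `clip(slow + fast − collagen_enhanced, 0, 255)`; channels are
   binarised (Otsu by default, fixed thresholds supported).
2. **Segmentation** — one labelled region per fibre via a
   distance-transform watershed (default), or any external label image
   through the `external-labelmap` backend; border-touching regions are
   excluded.
3. **Classification** — each interior region of area ≥ A_min is typed
   from its coverage in the binarised myosin masks with threshold *T*:
   both ≥ *T* → hybrid, exactly one ≥ *T* → that type, neither → noise.
4. **Morphometry** — per-fibre minimum Feret diameter (MFD, exact
   rotating-calipers on the convex hull); per image the fibre type ratio
   FTR = n_slow / n_fast, hybrid percentage, and collagen area fraction.
   Nerve sections yield axon diameter (AD), overall diameter (OD) and
   myelin thickness MT = (OD − AD)/2 per myelinated axon.
5. **Statistics** — per-image metrics across conditions are fitted with
   the linear mixed model `metric ~ condition + (1 | animal)` (REML);
   contrasts are tested with Satterthwaite degrees of freedom, p-values
   are Benjamini–Hochberg adjusted with significance at q < 0.1, and
   pairwise effect sizes are unsigned Cohen's d binned at 0.2 / 0.5 /
   0.8. Nerve metrics use a two-sided t-test at p < 0.05.

## Worked example

Simulate a small cohort — four control animals (base FTR 0.5) against
four stimulated animals whose muscle has shifted fast-to-slow (base FTR
1.0), with a per-animal random intercept of sd 0.3 on log-FTR and three
images per condition — then run the full pipeline:

```python
from fibremorph.synthetic import CohortDesign
from fibremorph.pipeline import RunConfig, run

design = CohortDesign(
    groups={"CT": 4, "DC07": 4},
    sides=("nPCA",), regions=("PCA+",),
    base_ftr={"CT": 0.5, "DC07": 1.0},
    images_per_condition=3, animal_sd=0.3,
    width_px=512, height_px=512, pixel_size=1.0,
    mean_fibre_diameter=55.0, seed=42,
)
bundle = run(RunConfig(design=design, seed=42))
print(bundle.image_metrics.groupby("group")[["ftr", "hybrid_pct", "collagen_pct"]].mean().round(3))
print(bundle.stats["ftr"][["contrast", "estimate", "df", "p", "q", "d", "stars"]].round(4).to_string(index=False))
```

which prints

```
         ftr  hybrid_pct  collagen_pct
group
CT     0.542       4.573        13.333
DC07   1.032       4.813        13.339

                      contrast  estimate  df     p     q     d stars
CT nPCA PCA- vs DC07 nPCA PCA+   -0.6463 6.0 0.012 0.012 2.256     *
```

The measured per-group FTR means (0.54 vs 1.03) recover the designed
two-fold shift; the mixed model reports the contrast on the log scale
(exp(−0.646) ≈ 0.52, i.e. the control FTR is about half the stimulated
one), with Satterthwaite df = 6 from eight animals, a BH-adjusted
q = 0.012 (significant at q < 0.1) and a large effect (d = 2.26). Hybrid
and collagen fractions are unchanged by design, and come out so.

The same chain is available from a shell:

```bash
fibremorph simulate --out cohort/ --seed 4
fibremorph run --input cohort/ --out results/ --seed 4
fibremorph stats --metrics results/image_metrics.csv --metric ftr --out ftr_stats.csv
```

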