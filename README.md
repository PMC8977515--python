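# graftquant

Quantification of inflammatory infiltrates in renal-allograft biopsy images
and their association with plasma donor-derived cell-free DNA (ddcfDNA).

## The problem

After kidney transplantation, the fraction of circulating cell-free DNA that
originates from the donor organ rises when graft cells are injured, making
plasma ddcfDNA a non-invasive rejection biomarker — but its levels vary
widely between recipients with similar diagnoses. One way to understand that
variability is to quantify the inflammatory burden in matched biopsies:
count the T cells (CD3+), cytotoxic T cells (CD8+), B cells (CD20+) and
macrophages (CD68+) visible in immunohistochemistry (IHC) slides, normalize
the counts by tissue area, and relate the resulting densities — together
with the standardized Banff lesion scores (g, t, v, i, ci, ct, ptc, ...,
and mvi = g + ptc) — to each recipient's plasma ddcfDNA fraction.

`graftquant` implements that pipeline end to end, for cohorts of recipients
grouped as NR (no rejection), Borderline, TCMR (T cell-mediated rejection)
and ABMR (antibody-mediated rejection):

* **Biopsy area** — slide → luma grayscale → binarize at gray 200 (tissue is
  darker than the near-white background) → connected components → drop
  components under 10 % of the largest → pixel counts → physical area at
  2.3 px/µm.
* **Glomerulus masks** — expert LabelMe polygon annotations rasterized to
  instance masks; a tile (1024²) / stride (768) / max-stitch / 0.5-threshold
  harness around a pluggable segmenter (a scaled-down trainable per-pixel
  classifier is included; any tile → probability-map callable plugs in).
* **Positive-cell detection** — difference of Gaussians (σ₁ = 0.5, σ₂ = 3,
  broad minus narrow so dark stained cells give positive peaks) → binarize
  at response > 10 → 8-connected components → drop area < 10 px → keep a
  component iff it contains a pixel with max(R,G,B) < 100. Detections are
  assigned to the glomerular / non-glomerular compartment by centroid
  containment, and densities are counts per compartment mm².
* **Association statistics** — Kruskal–Wallis with pairwise Wilcoxon
  rank-sum post-tests (exact for small samples) across diagnosis groups;
  per-lesion score associations with the named contrasts (i3 vs i ≤ 1,
  mvi ≥ 2 vs < 2); ddcfDNA tertile split (106 → 35/36/35); average-linkage
  hierarchical clustering of z-scored densities; pairwise-complete Pearson
  correlation matrices; chi-square contingency tests; one-way ANOVA.
* **Synthetic data** — a cohort simulator (group sizes 13/13/60/20,
  log-normal ddcfDNA with per-group medians, Banff score frequencies from
  the observed contingency tables, density matrices with configurable
  correlation to log ddcfDNA) and a slide renderer whose ground truth is
  exact by construction, so every stage is tested against planted truth.

## Worked example

```python
from graftquant.synthetic import SlideSpec, render_ihc_slide
from graftquant.geometry import compute_biopsy_mask, mask_area_mm2
from graftquant.glomseg import oracle_probability_map, prob_to_glomerulus_mask
from graftquant.detect import (detect_cells, assign_compartments,
                               compartment_areas_mm2)

img, gt = render_ihc_slide(SlideSpec(seed=42))       # 1000x1000 px, 50 + 50 cells
biopsy = compute_biopsy_mask(img)
glom = prob_to_glomerulus_mask(oracle_probability_map(gt.glomerulus_mask()),
                               biopsy_mask=biopsy)
det = assign_compartments(detect_cells(img, marker="CD68"), glom, biopsy)
areas = compartment_areas_mm2(glom, biopsy)
print(len(det), det.count("glomerular"), round(mask_area_mm2(biopsy), 4))
```

prints `50 4 0.0388`: all 50 planted stained cells are recovered (none of
the 50 light decoys), 4 of them fall inside glomeruli, and the biopsy
fragment covers 0.0388 mm² — giving densities of 1005.5 cells/mm² in the
glomerular and 1322.4 cells/mm² in the non-glomerular compartment.

At the cohort level:

```python
from graftquant.synthetic import SimCohortParams, simulate_cohort
from graftquant.stats import group_compare_ddcfdna

records, truth = simulate_cohort(SimCohortParams(seed=1))   # 106 recipients
omnibus, pairwise = group_compare_ddcfdna(records)
print(f"KW H={omnibus.statistic:.2f} p={omnibus.p_value:.2e}")
```

prints `KW H=43.93 p=1.56e-09`: the four diagnosis groups differ strongly
in ddcfDNA, with pairwise Wilcoxon p-values of 0.38 (NR vs Borderline,
no separation) down to 2·10⁻⁶ (NR vs ABMR).

The same stages are scriptable from the shell:

```bash
graftquant demo --out data --seed 0      # synthetic bundle: cohort + slides
graftquant run  --data data --out results --seed 0
```

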