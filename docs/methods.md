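# Methods

## Scope and data model

`graftquant` quantifies inflammatory infiltrates on brightfield IHC slides
of renal-allograft biopsies and relates the resulting cell densities, and
the Banff lesion scores of the same biopsies, to plasma ddcfDNA fractions.
A cohort is a list of recipient records (ddcfDNA fraction in percent,
diagnosis group, Banff scores, demographics, screening exclusion flag); a
slide is an 8-bit RGB raster with a known resolution in pixels per micron
(default 2.3) and a marker label (CD3, CD8, CD20, CD68). Microvascular
inflammation (mvi) is always recomputed as g + ptc and never stored, so it
can never drift from its constituents.

## Screening filter

Records carrying one of seven exclusion categories (recurrent/de-novo GN,
BKVN, possible BKVN, TCMR with BK viruria, multi-organ transplant, repeat
transplant, CNI toxicity) are removed first, logged per category; an age
floor (default 18 y) then applies to the remainder, logged separately under
`under_age`. When a record matches several categories the first in the
listed order is logged — a deterministic precedence that keeps the
partition exact (retained + excluded = input, always asserted).

## Biopsy area

Grayscale is ITU-R 601 luma (0.299 R + 0.587 G + 0.114 B); the conversion
is configurable because different implementations of "grayscale" differ at
the ±1 level. A pixel is tissue iff luma < 200 strictly — tissue is darker
than the near-white slide background, and putting threshold-valued pixels
in the background makes the tie rule deterministic. Components (8-connected
by default, configurable) below 10 % of the largest component's pixel area
are discarded as debris/edge artifacts. Physical area is pixel count
divided by (px/µm)²; the division is done in decimal arithmetic on the
stated resolution so that the closed form 52,900 px / 2.3² = 10,000 µm² is
exact rather than off by 2 ulp.

## Glomerulus masks

Expert annotations are LabelMe-style JSON polygons; rasterization assigns
each polygon a 1-based instance label with even-odd fill and boundary
pixels inside (an axis-aligned square with corners (0,0)–(9,9) fills
exactly 100 px). Self-intersecting polygons are rejected by shape index;
out-of-bounds polygons are clipped with a warning.

Whole-slide inference around a pluggable segmenter uses 1024 × 1024 tiles
at 768-px strides (edge tiles padded by reflection and cropped after
stitching), per-pixel **maximum** over overlapping tile predictions, a
strict > 0.5 threshold (exact 0.5 → background, again a deterministic tie
rule), and connected-component labeling into glomerulus instances. The
instance mask is clipped to the biopsy mask when one is supplied, so the
glomerular and non-glomerular compartments partition the tissue — the
denominator property the densities need. The training tile size (768)
is kept as a separate configuration field from the inference tile (1024).

The segmenter contract is any callable tile → probability map. The oracle
path used throughout the tests tiles the ground-truth probability map
through the same `tile_image` call and stitches those tiles, validating
the harness (tiling, stitching, thresholding, instance labeling)
independently of any model. The included trainable model is deliberately
scaled down: a per-pixel 3-class softmax (inside / contour / outside) over
raw and Gaussian-blurred RGB features, standardized on the training set,
fitted with a hand-rolled Adam + cross-entropy loop under the two-phase
learning-rate schedule (10⁻³ through epoch 100, 10⁻⁴ to 150). Minibatches
are stratified per class because glomeruli are a small fraction of tissue
pixels. It is a linear classifier, not a deep network: sufficient for the
colour-separable synthetic slides (held-out IoU ≈ 0.8 after 20 epochs) and
for exercising the training contract, but it would not segment real
histology; real use is expected to plug in a trained CNN through the same
contract.

## Cell detection

The band-pass response is Gaussian(σ₂ = 3) ∗ I − Gaussian(σ₁ = 0.5) ∗ I on
the luma image, clipped to [0, 255] (kernels truncated at 4σ). This
orientation makes dark stained cells positive peaks, which is required for
a positive response threshold (default 10) to select them; bright spots on
dark ground produce negative responses and vanish. Components of the
binarized response (strictly above threshold, 8-connected) are dropped
below 10 px. The darkness filter keeps a component iff **any** of its
pixels has max(R, G, B) < 100: the all-pixels variant (available via
`darkness_rule="all"`) would discard genuine cells whose boundary pixels
blend into the counterstain. Centroids are component pixel means.

Compartment assignment is centroid containment: glomerular if the centroid
pixel is labeled in the glomerulus mask, else non-glomerular if inside the
biopsy mask, else dropped (and counted) as a background artifact. Density
is count / compartment area in mm²; a zero-area compartment with a nonzero
count raises, since it can only arise from inconsistent masks. Missing
slides stay missing in the density matrix — never imputed as zero. The
pipeline assumes one slide per marker per recipient.

The fluorescence (MET) counter is an extension with invented parameters:
each of the two registered channels runs the same blob detector with
inverted polarity and no darkness filter, and detections colocalize when
centroids lie within 5 px (greedy nearest-first one-to-one matching).
Double-positive MPO/Histone-H3 counts quantify what the source analysis
assessed qualitatively.

## Statistics

* Chi-square: Pearson, no continuity correction; zero-margin rows/columns
  dropped with a warning; df = (r−1)(c−1). Contingency tables of lesion
  scores are built over all four score levels in ascending order.
* Kruskal–Wallis / Wilcoxon rank-sum: midrank ties; the Wilcoxon test is
  exact (full null distribution) for combined n ≤ 12 without ties and a
  tie-corrected normal approximation otherwise. Pairwise post-test
  p-values are reported raw, matching how such panels are usually printed;
  Holm adjustment is available behind a flag.
* Group comparison: KW omnibus over diagnosis groups plus all pairwise
  Wilcoxon post-tests (two-sided). Lesion associations: per-level
  summaries, KW across populated levels, all pairwise level contrasts, and
  the named contrasts i3 vs i ≤ 1, mvi ≥ 2 vs < 2, and presence/absence
  for ah and c4d (too sparse for level-wise testing).
* Tertile split: ascending sort with a stable tie-break on recipient id;
  lowest ⌊n/3⌋ → low, highest ⌊n/3⌋ → high, remainder → medium, so
  n = 106 always yields 35/36/35 regardless of ties.
* Clustering: columns z-scored (constant columns excluded with a warning;
  missing values imputed with column medians with a warning), Euclidean
  distance, average linkage (UPGMA), row order from dendrogram traversal.
  Distance and standardization are common heatmap-tool defaults, stated
  here because they are genuinely free choices.
* Correlations: pairwise-complete Pearson with two-sided t-based p-values;
  pairs with < 3 complete observations or zero variance are reported
  missing rather than guessed.
* ANOVA convention: all groups constant with equal means → F = 0, p = 1,
  with a warning. Demographic dispersion is reported as standard error of
  the mean.

## Synthetic data: what it emulates, and what it does not

The cohort simulator draws group sizes 13/13/60/20 by default; ddcfDNA is
log-normal per group with medians 0.48 % (NR), 0.60 % (Borderline), 1.20 %
(TCMR) and 2.145 % (ABMR) and log-sd 0.6. Log-normal is the simplest
positive, right-skewed family consistent with the reported medians and
ranges; the TCMR median is not reported anywhere, so 1.20 % is a
calibration default chosen between the Borderline and ABMR medians, and is
never treated as a reproduction target. Banff scores for the seven scored
lesions are drawn from the observed per-group contingency frequencies; the
remaining sparse lesions (cg, cv, mm, ah, aah, c4d) have invented mostly-
zero profiles with C4d enriched in ABMR. Demographics are drawn from the
observed group means/SEs and category counts (the "Simulet" induction
label is read as basiliximab/Simulect). Density columns are linear in
standardized log ddcfDNA plus Gaussian noise (mean 200, sd 60 cells/mm²,
clipped at 0), with default target correlations mirroring the reported
association pattern (CD68 correlated in both compartments, CD8/CD20
non-glomerular, CD3 weak); the achieved correlation converges to the
target as n grows (tested at n = 2,000 within 0.05).

The slide renderer guarantees, by construction, the class separation that
the detection thresholds assume: background gray ≥ 200, tissue/glomerulus
colours with luma < 200, positive cells as radially shaded disks with ≥
10 px of core darker than max(R,G,B) = 100, negative decoys darker than
tissue in luma (so the band-pass detector sees them) but with every pixel's
max channel ≥ 100 (so the darkness filter rejects them), and a minimum
cell separation (default 20 px > 6σ₂) that keeps blob responses disjoint.
Fragments are ellipses confined to grid cells so they never merge;
glomeruli are ellipse polygons rasterized through the same code path that
consumes annotations, making the annotation round-trip exact.

Consequently, passing the planting oracle (precision = recall = 1,
centroid error ≤ 3 px) demonstrates that the implementation applies the
stated rules correctly — not that those rules achieve any particular
accuracy on real histology, which has textured nuclei, stain variation,
overlapping cells and scanner artifacts that the renderer deliberately
omits. The same caveat applies to the trainable segmenter benchmark.

## Determinism and problem sizes

Every stochastic component takes a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical cohorts,
images and pipeline outputs (asserted at the file level). The demo bundle
uses 512-px slides with 25 + 25 cells and 2 glomeruli per slide — 8 slides
across 2 imaged recipients plus the full 106-recipient cohort table — so a
complete end-to-end run takes seconds; the statistical calibration suites
use 500 simulation seeds, and the detection/stitching oracles 20 and 5
full-size (1000–1400 px) slides respectively. These sizes were chosen so
the whole verification cycle runs comfortably on a single CPU while
keeping every estimate's Monte-Carlo error well inside the asserted
tolerances.

## Known limitations

* The renderer's cells are smooth disks; no stain deconvolution or texture
  modelling, so detector parameters validated here still need re-tuning on
  real slides.
* The included trainable segmenter is a linear per-pixel model, not the
  deep encoder-decoder a production deployment would use.
* Real per-recipient ddcfDNA values and slide images are not available, so
  group-level statistics on real data are out of scope; the printed
  contingency tables are the only real-data quantities reproduced.
* Wilcoxon exactness is guaranteed only for combined n ≤ 12 without ties;
  larger or tied samples use the tie-corrected normal approximation.
* OCR of slide labels is not implemented; label regions are assumed not to
  intersect tissue.
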