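"""Synthetic cohorts and slides with exact ground truth.

Every downstream stage (area measurement, glomerulus-mask harness, cell
detection, association statistics) is testable against data whose truth is
known by construction:

* ``simulate_cohort`` draws a recipient cohort with the study's group
  structure (NR / Borderline / TCMR / ABMR), log-normal per-group ddcfDNA
  fractions, Banff score frequencies matching the observed contingency
  tables, demographics matching the observed group summaries, and a density
  matrix whose Pearson correlation with log ddcfDNA is set by the caller.
* ``render_ihc_slide`` paints a brightfield-like slide: near-white
  background (gray >= 200), darker elliptical tissue fragments, elliptical
  glomeruli, dark radially-shaded positive cells whose core pixels satisfy
  max(R, G, B) < 100, and light negative cells whose every pixel satisfies
  max(R, G, B) >= 100 — so the detection thresholds separate the two classes
  by construction.
* ``render_if_slide`` paints a registered two-channel fluorescence image
  with a controlled fraction of double-positive (colocalized) cells.

Cells are rendered as radially shaded disks rather than textured nuclei so
the band-pass (difference-of-Gaussians) response is analytically
predictable; see the methods note for what this does and does not emulate.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import BanffScores, CohortRecord, DIAGNOSIS_GROUPS
from .geometry import RegionMask
from .glomseg import rasterize_polygons

__all__ = [
    "SimCohortParams", "SlideSpec", "GroundTruth", "MARKERS",
    "simulate_cohort", "render_ihc_slide", "render_if_slide",
    "write_labelme_annotations",
]

MARKERS = ("CD3", "CD8", "CD20", "CD68")
COMPARTMENTS = ("glomerular", "non_glomerular")

# Observed per-group Banff score counts (levels 0..3) used as default
# sampling frequencies; groups ordered NR, Borderline, TCMR, ABMR.
BANFF_GROUP_COUNTS = {
    "g":   {"NR": [7, 4, 2, 0], "Borderline": [8, 3, 1, 1], "TCMR": [40, 8, 6, 6], "ABMR": [5, 1, 4, 10]},
    "ct":  {"NR": [6, 7, 0, 0], "Borderline": [1, 10, 1, 1], "TCMR": [7, 37, 11, 5], "ABMR": [1, 13, 5, 1]},
    "t":   {"NR": [8, 5, 0, 0], "Borderline": [0, 11, 2, 0], "TCMR": [4, 5, 29, 22], "ABMR": [5, 7, 6, 2]},
    "v":   {"NR": [13, 0, 0, 0], "Borderline": [13, 0, 0, 0], "TCMR": [37, 22, 1, 0], "ABMR": [10, 4, 6, 0]},
    "i":   {"NR": [8, 5, 0, 0], "Borderline": [0, 11, 1, 1], "TCMR": [3, 8, 25, 24], "ABMR": [3, 4, 6, 7]},
    "ci":  {"NR": [11, 2, 0, 0], "Borderline": [6, 5, 1, 1], "TCMR": [13, 19, 14, 14], "ABMR": [4, 8, 5, 3]},
    "ptc": {"NR": [10, 1, 2, 0], "Borderline": [12, 0, 1, 0], "TCMR": [39, 7, 3, 11], "ABMR": [7, 1, 8, 4]},
}

# Sparse lesions without a printed breakdown: plausible per-group level
# probabilities (chronic lesions rare overall, C4d enriched in ABMR).
_SPARSE_BANFF = {
    "cg":  {"NR": [1, 0, 0, 0], "Borderline": [1, 0, 0, 0], "TCMR": [0.9, 0.07, 0.03, 0], "ABMR": [0.6, 0.2, 0.1, 0.1]},
    "cv":  {"NR": [0.7, 0.2, 0.1, 0], "Borderline": [0.7, 0.2, 0.1, 0], "TCMR": [0.6, 0.25, 0.1, 0.05], "ABMR": [0.6, 0.25, 0.1, 0.05]},
    "mm":  {"NR": [0.9, 0.1, 0, 0], "Borderline": [0.9, 0.1, 0, 0], "TCMR": [0.85, 0.1, 0.05, 0], "ABMR": [0.8, 0.15, 0.05, 0]},
    "ah":  {"NR": [0.7, 0.2, 0.1, 0], "Borderline": [0.7, 0.2, 0.1, 0], "TCMR": [0.65, 0.2, 0.1, 0.05], "ABMR": [0.65, 0.2, 0.1, 0.05]},
    "aah": {"NR": [0.8, 0.15, 0.05, 0], "Borderline": [0.8, 0.15, 0.05, 0], "TCMR": [0.75, 0.15, 0.1, 0], "ABMR": [0.75, 0.15, 0.1, 0]},
    "c4d": {"NR": [0.95, 0.05, 0, 0], "Borderline": [0.95, 0.05, 0, 0], "TCMR": [0.85, 0.1, 0.05, 0], "ABMR": [0.25, 0.2, 0.3, 0.25]},
}

# Observed group demographics: mean and standard error (with group n) for
# continuous variables; category counts for categoricals.
_DEMOGRAPHICS = {
    "age":    {"NR": (41.42, 3.71), "Borderline": (35.00, 2.34), "TCMR": (39.49, 1.52), "ABMR": (31.58, 2.50)},
    "height": {"NR": (167.33, 1.69), "Borderline": (167.15, 2.69), "TCMR": (166.33, 1.14), "ABMR": (168.63, 1.56)},
    "weight": {"NR": (57.35, 2.41), "Borderline": (57.92, 2.98), "TCMR": (61.77, 1.76), "ABMR": (66.44, 3.83)},
    "hla":    {"NR": 3.50, "Borderline": 2.77, "TCMR": 3.13, "ABMR": 2.84},
    "sex_mf": {"NR": (11, 2), "Borderline": (8, 5), "TCMR": (41, 19), "ABMR": (16, 4)},
    "donor":  {"NR": (8, 5), "Borderline": (6, 7), "TCMR": (41, 19), "ABMR": (8, 12)},  # DCD/LD
    "dialysis": {"NR": (2, 7, 4), "Borderline": (0, 8, 5), "TCMR": (5, 43, 12), "ABMR": (0, 15, 5)},
    "induction": {"NR": (0, 4, 9), "Borderline": (1, 6, 6), "TCMR": (10, 30, 20), "ABMR": (4, 12, 4)},
}


def _default_density_corr() -> dict:
    """Target Pearson r between each density column and log ddcfDNA.

    Calibration defaults mirroring the reported association pattern:
    macrophage (CD68) density correlated in both compartments, CD8 and CD20
    in the non-glomerular compartment, CD3 weakly throughout.
    """
    return {
        ("CD3", "glomerular"): 0.10, ("CD3", "non_glomerular"): 0.15,
        ("CD8", "glomerular"): 0.10, ("CD8", "non_glomerular"): 0.25,
        ("CD20", "glomerular"): 0.10, ("CD20", "non_glomerular"): 0.25,
        ("CD68", "glomerular"): 0.30, ("CD68", "non_glomerular"): 0.25,
    }


@dataclass
class SimCohortParams:
    n_per_group: dict = field(default_factory=lambda: {"NR": 13, "Borderline": 13, "TCMR": 60, "ABMR": 20})
    ddcfdna_log_median: dict = field(default_factory=lambda: {"NR": 0.48, "Borderline": 0.60, "TCMR": 1.20, "ABMR": 2.145})
    ddcfdna_log_sd: dict = field(default_factory=lambda: {g: 0.6 for g in DIAGNOSIS_GROUPS})
    banff_profile: dict = field(default_factory=dict)  # lesion -> group -> level probs
    density_corr: dict = field(default_factory=_default_density_corr)
    density_mean: float = 200.0   # cells/mm^2
    density_noise_sd: float = 60.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.banff_profile:
            profile = {}
            for lesion, counts in BANFF_GROUP_COUNTS.items():
                profile[lesion] = {g: np.asarray(c, dtype=float) / sum(c)
                                   for g, c in counts.items()}
            for lesion, probs in _SPARSE_BANFF.items():
                profile[lesion] = {g: np.asarray(p, dtype=float) / sum(p)
                                   for g, p in probs.items()}
            self.banff_profile = profile
        for lesion, per_group in self.banff_profile.items():
            for g, probs in per_group.items():
                if abs(float(np.sum(probs)) - 1.0) > 1e-9:
                    raise ValueError(f"banff_profile[{lesion}][{g}] does not sum to 1")
        for key, r in self.density_corr.items():
            if not abs(r) < 1:
                raise ValueError(f"density_corr[{key}]={r} must satisfy |r| < 1")
        if any(n < 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be >= 0")


def simulate_cohort(params: SimCohortParams | None = None):
    """Draw a cohort; returns ``(records, truth)``.

    ``truth`` carries the latent density matrix (recipients x
    marker/compartment densities in cells/mm^2), the standardized log
    ddcfDNA used to induce the correlations, and the achieved sample
    correlations. ddcfDNA is log-normal per group with the configured
    median (the median of exp(N(mu, sd)) is exp(mu)); densities are linear
    in standardized log ddcfDNA plus Gaussian noise.
    """
    params = params or SimCohortParams()
    rng = np.random.default_rng(params.seed)
    records: list[CohortRecord] = []
    counter = 0
    for group in DIAGNOSIS_GROUPS:
        n = params.n_per_group.get(group, 0)
        mu = np.log(params.ddcfdna_log_median[group])
        sd = params.ddcfdna_log_sd[group]
        dd = np.exp(rng.normal(mu, sd, size=n))
        dd = np.minimum(dd, 100.0)
        age_m, age_se = _DEMOGRAPHICS["age"][group]
        h_m, h_se = _DEMOGRAPHICS["height"][group]
        w_m, w_se = _DEMOGRAPHICS["weight"][group]
        n_obs = {"NR": 13, "Borderline": 13, "TCMR": 60, "ABMR": 20}[group]
        for i in range(n):
            counter += 1
            banff_kwargs = {}
            for lesion, per_group in params.banff_profile.items():
                probs = per_group[group]
                banff_kwargs[lesion] = int(rng.choice(len(probs), p=probs))
            age = max(18.0, rng.normal(age_m, age_se * np.sqrt(n_obs)))
            height = rng.normal(h_m, h_se * np.sqrt(n_obs))
            weight = max(35.0, rng.normal(w_m, w_se * np.sqrt(n_obs)))
            sex_counts = _DEMOGRAPHICS["sex_mf"][group]
            sex = rng.choice(["M", "F"], p=np.asarray(sex_counts) / sum(sex_counts))
            donor_counts = _DEMOGRAPHICS["donor"][group]
            donor = rng.choice(["DCD", "LD"], p=np.asarray(donor_counts) / sum(donor_counts))
            dia_counts = np.asarray(_DEMOGRAPHICS["dialysis"][group], dtype=float)
            dialysis = rng.choice(["None", "HD", "PD"], p=dia_counts / dia_counts.sum())
            ind_counts = np.asarray(_DEMOGRAPHICS["induction"][group], dtype=float)
            induction = rng.choice(["None", "Simulect", "ATG"], p=ind_counts / ind_counts.sum())
            hla = int(rng.binomial(6, _DEMOGRAPHICS["hla"][group] / 6.0))
            records.append(CohortRecord(
                recipient_id=f"R{counter:03d}",
                ddcfdna_fraction=float(dd[i]),
                diagnosis=group,
                banff=BanffScores(**banff_kwargs),
                age_years=float(round(age, 1)),
                sex=str(sex),
                height_cm=float(round(height, 1)),
                weight_kg=float(round(weight, 1)),
                hla_mismatch=hla,
                dialysis=str(dialysis),
                induction=str(induction),
                donor_type=str(donor),
            ))
    # density matrix correlated with log ddcfDNA
    dd_all = np.array([r.ddcfdna_fraction for r in records])
    ids = [r.recipient_id for r in records]
    log_dd = np.log(dd_all)
    if len(records) >= 2 and log_dd.std(ddof=0) > 0:
        z = (log_dd - log_dd.mean()) / log_dd.std(ddof=0)
    else:
        z = np.zeros(len(records))
    columns, achieved = {}, {}
    for marker in MARKERS:
        for comp in COMPARTMENTS:
            r = params.density_corr.get((marker, comp), 0.0)
            eps = rng.standard_normal(len(records))
            dens = params.density_mean + params.density_noise_sd * (
                r * z + np.sqrt(1 - r**2) * eps)
            dens = np.maximum(dens, 0.0)
            col = f"{marker}_{comp}"
            columns[col] = dens
            if len(records) >= 3 and dens.std(ddof=0) > 0 and z.std(ddof=0) > 0:
                achieved[col] = float(np.corrcoef(z, dens)[0, 1])
    density = pd.DataFrame(columns, index=pd.Index(ids, name="recipient_id"))
    truth = {
        "density_matrix": density,
        "log_ddcfdna_z": pd.Series(z, index=ids),
        "achieved_corr": achieved,
        "params": params,
    }
    return records, truth


# ---------------------------------------------------------------------------
# Slide rendering

TISSUE_RGB = np.array([190, 150, 160], dtype=float)       # luma ~163, < 200
GLOM_RGB = np.array([165, 135, 185], dtype=float)         # luma ~150, distinct hue
NEG_BLUE = 190                                            # bright channel keeping max >= 100


@dataclass
class SlideSpec:
    width_px: int = 1000
    height_px: int = 1000
    px_per_micron: float = 2.3
    n_tissue_fragments: int = 2
    n_glomeruli: int = 3
    n_positive_cells: int = 50
    n_negative_cells: int = 50
    positive_core_max_rgb: int = 80
    negative_min_rgb: int = 100
    background_gray: int = 230
    cell_radius_px: tuple[float, float] = (3.0, 4.0)
    min_cell_separation_px: float = 20.0
    fragment_rects: Optional[list] = None  # list of (y0, x0, h, w) exact rectangles
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_gray < 200:
            raise ValueError("background_gray must be >= 200")
        if not self.positive_core_max_rgb < 100 <= self.negative_min_rgb:
            raise ValueError("need positive_core_max_rgb < 100 <= negative_min_rgb")
        if self.min_cell_separation_px <= 2 * max(self.cell_radius_px):
            raise ValueError("min_cell_separation_px must exceed twice the max cell radius")


@dataclass
class GroundTruth:
    tissue_mask: RegionMask
    glomerulus_polygons: list          # each an (n, 2) array of (x, y) points
    positive_cells: list               # (x, y, compartment)
    negative_cells: list               # (x, y)
    image_shape: tuple[int, int]
    double_positive_cells: list = field(default_factory=list)  # IF slides only

    def glomerulus_mask(self) -> RegionMask:
        return rasterize_polygons(self.glomerulus_polygons, self.image_shape,
                                  self.tissue_mask.px_per_micron)


def _ellipse_mask(shape, cy, cx, ry, rx, angle=0.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    y, x = yy - cy, xx - cx
    if angle:
        c, s = np.cos(angle), np.sin(angle)
        x, y = c * x + s * y, -s * x + c * y
    return (x / rx) ** 2 + (y / ry) ** 2 <= 1.0


def _ellipse_polygon(cy, cx, ry, rx, angle=0.0, n_points=48):
    t = np.linspace(0, 2 * np.pi, n_points, endpoint=False)
    x = rx * np.cos(t)
    y = ry * np.sin(t)
    if angle:
        c, s = np.cos(angle), np.sin(angle)
        x, y = c * x - s * y, s * x + c * y
    return np.stack([np.round(cx + x), np.round(cy + y)], axis=1)  # (x, y)


def _paint_radial_cell(img, cy, cx, radius, core_rgb, flat_radius=2.0):
    """Dark/light radial disk: flat core then quadratic blend to the canvas."""
    h, w = img.shape[:2]
    y0, y1 = max(0, int(cy - radius - 1)), min(h, int(cy + radius + 2))
    x0, x1 = max(0, int(cx - radius - 1)), min(w, int(cx + radius + 2))
    yy, xx = np.mgrid[y0:y1, x0:x1]
    r = np.hypot(yy - cy, xx - cx)
    inside = r <= radius
    t = np.clip((r - flat_radius) / max(radius - flat_radius, 1e-9), 0.0, 1.0) ** 2
    patch = img[y0:y1, x0:x1].astype(float)
    core = np.asarray(core_rgb, dtype=float)
    blended = core[None, None, :] + (patch - core[None, None, :]) * t[..., None]
    patch[inside] = blended[inside]
    img[y0:y1, x0:x1] = np.round(patch).astype(np.uint8)


def _place_points(rng, allowed_mask, n, min_sep, margin, budget_factor=400):
    """Rejection-sample n points inside allowed_mask, pairwise >= min_sep apart."""
    from scipy import ndimage as ndi

    eroded = ndi.binary_erosion(allowed_mask, iterations=int(margin)) if margin >= 1 else allowed_mask
    ys, xs = np.nonzero(eroded)
    if len(ys) == 0:
        raise RuntimeError("no room to place cells; use a larger canvas or fewer cells")
    placed: list[tuple[float, float]] = []
    budget = budget_factor * max(n, 1)
    while len(placed) < n and budget > 0:
        budget -= 1
        k = rng.integers(0, len(ys))
        y, x = float(ys[k]), float(xs[k])
        if all((y - py) ** 2 + (x - px) ** 2 >= min_sep**2 for py, px in placed):
            placed.append((y, x))
    if len(placed) < n:
        raise RuntimeError(
            f"placed only {len(placed)}/{n} cells within retry budget; "
            "use a larger canvas or fewer cells")
    return placed


def render_ihc_slide(spec: SlideSpec | None = None):
    """Render a brightfield IHC-like slide; returns ``(image, GroundTruth)``.

    The image is uint8 RGB. All background pixels have gray value
    ``background_gray`` (>= 200); tissue, glomerulus and cell pixels all have
    luma < 200; positive-cell cores satisfy max(R, G, B) < 100 over >= 10 px
    and negative cells satisfy max(R, G, B) >= 100 at every pixel.
    """
    spec = spec or SlideSpec()
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    img = np.full((h, w, 3), spec.background_gray, dtype=np.uint8)
    tissue_labels = np.zeros((h, w), dtype=np.int32)

    if spec.fragment_rects is not None:
        for k, (y0, x0, fh, fw) in enumerate(spec.fragment_rects, start=1):
            tissue_labels[y0:y0 + fh, x0:x0 + fw] = k
    else:
        # one fragment per grid cell so fragments never touch
        n = spec.n_tissue_fragments
        ncols = int(np.ceil(np.sqrt(n)))
        nrows = int(np.ceil(n / ncols))
        cell_h, cell_w = h / nrows, w / ncols
        for k in range(1, n + 1):
            gy, gx = divmod(k - 1, ncols)
            cy = (gy + 0.5) * cell_h + rng.uniform(-0.05, 0.05) * cell_h
            cx = (gx + 0.5) * cell_w + rng.uniform(-0.05, 0.05) * cell_w
            # cap by the smaller cell dimension so the rotated ellipse stays
            # inside its grid cell (fragments never merge or hit the border)
            rcap = min(cell_h, cell_w)
            ry = rng.uniform(0.30, 0.40) * rcap
            rx = rng.uniform(0.30, 0.40) * rcap
            frag = _ellipse_mask((h, w), cy, cx, ry, rx, rng.uniform(0, np.pi))
            tissue_labels[frag] = k
    img[tissue_labels > 0] = TISSUE_RGB.astype(np.uint8)

    # glomeruli: ellipses inside fragments, pairwise disjoint
    polys = []
    frag_ids = [k for k in np.unique(tissue_labels) if k > 0]
    attempts = 0
    glom_centers: list[tuple[float, float, float]] = []
    while len(polys) < spec.n_glomeruli and attempts < 200 * max(spec.n_glomeruli, 1):
        attempts += 1
        frag = frag_ids[len(polys) % len(frag_ids)]
        ys, xs = np.nonzero(tissue_labels == frag)
        k = rng.integers(0, len(ys))
        cy, cx = float(ys[k]), float(xs[k])
        ry = rng.uniform(0.035, 0.055) * min(h, w)
        rx = rng.uniform(0.035, 0.055) * min(h, w)
        rmax = max(ry, rx)
        ellipse = _ellipse_mask((h, w), cy, cx, ry + 1, rx + 1)
        if not (tissue_labels[ellipse] == frag).all():
            continue  # must lie fully inside one fragment
        if any(np.hypot(cy - gy, cx - gx) < rmax + gr + 4 for gy, gx, gr in glom_centers):
            continue
        polys.append(_ellipse_polygon(cy, cx, ry, rx))
        glom_centers.append((cy, cx, rmax))
    if len(polys) < spec.n_glomeruli:
        raise RuntimeError("could not place requested glomeruli; use a larger canvas")
    tissue_mask = RegionMask(labels=tissue_labels, px_per_micron=spec.px_per_micron)
    gt = GroundTruth(tissue_mask=tissue_mask, glomerulus_polygons=polys,
                     positive_cells=[], negative_cells=[], image_shape=(h, w))
    glom_labels = gt.glomerulus_mask().labels
    img[glom_labels > 0] = GLOM_RGB.astype(np.uint8)

    # cells
    margin = max(spec.cell_radius_px) + 2
    n_total = spec.n_positive_cells + spec.n_negative_cells
    if n_total > 0:
        pts = _place_points(rng, tissue_labels > 0, n_total,
                            spec.min_cell_separation_px, margin)
    else:
        pts = []
    pcm = spec.positive_core_max_rgb
    pos_core = (pcm, int(0.62 * pcm), int(0.50 * pcm))
    neg_core = (spec.negative_min_rgb, spec.negative_min_rgb + 10, NEG_BLUE)
    for i, (cy, cx) in enumerate(pts):
        radius = rng.uniform(*spec.cell_radius_px)
        if i < spec.n_positive_cells:
            _paint_radial_cell(img, cy, cx, radius, pos_core)
            comp = "glomerular" if glom_labels[int(round(cy)), int(round(cx))] > 0 \
                else "non_glomerular"
            gt.positive_cells.append((cx, cy, comp))
        else:
            _paint_radial_cell(img, cy, cx, radius, neg_core)
            gt.negative_cells.append((cx, cy))
    return img, gt


def render_if_slide(spec: SlideSpec | None = None, coloc_fraction: float = 0.5):
    """Render a registered two-channel fluorescence slide.

    Bright radial blobs on a dark background; ``round(coloc_fraction * n)``
    of the ``n = n_positive_cells`` planted cells appear at the same
    position in both channels (double-positive), the rest alternate between
    the channels. Returns ``(image HxWx2 uint8, GroundTruth)``.
    """
    spec = spec or SlideSpec()
    if not 0 <= coloc_fraction <= 1:
        raise ValueError("coloc_fraction must be in [0, 1]")
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px
    background = 10
    img = np.full((h, w, 2), background, dtype=np.uint8)
    n = spec.n_positive_cells
    n_double = int(round(coloc_fraction * n))
    allowed = np.ones((h, w), dtype=bool)
    pts = _place_points(rng, allowed, n, spec.min_cell_separation_px,
                        max(spec.cell_radius_px) + 2) if n else []
    tissue = RegionMask(labels=np.ones((h, w), dtype=np.int32),
                        px_per_micron=spec.px_per_micron)
    gt = GroundTruth(tissue_mask=tissue, glomerulus_polygons=[],
                     positive_cells=[], negative_cells=[], image_shape=(h, w))

    def paint(channel, cy, cx, radius):
        y0, y1 = max(0, int(cy - radius - 1)), min(h, int(cy + radius + 2))
        x0, x1 = max(0, int(cx - radius - 1)), min(w, int(cx + radius + 2))
        yy, xx = np.mgrid[y0:y1, x0:x1]
        r = np.hypot(yy - cy, xx - cx)
        inside = r <= radius
        t = np.clip((r - 2.0) / max(radius - 2.0, 1e-9), 0, 1) ** 2
        vals = 220 + (background - 220) * t
        patch = img[y0:y1, x0:x1, channel].astype(float)
        patch[inside] = np.maximum(patch[inside], vals[inside])
        img[y0:y1, x0:x1, channel] = np.round(patch).astype(np.uint8)

    for i, (cy, cx) in enumerate(pts):
        radius = rng.uniform(*spec.cell_radius_px)
        if i < n_double:
            paint(0, cy, cx, radius)
            paint(1, cy, cx, radius)
            gt.double_positive_cells.append((cx, cy))
        else:
            paint((i - n_double) % 2, cy, cx, radius)
            gt.positive_cells.append((cx, cy, "non_glomerular"))
    return img, gt


def write_labelme_annotations(gt: GroundTruth, path: str | Path,
                              label: str = "glomerulus") -> None:
    """Write glomerulus polygons as a LabelMe-style JSON annotation file."""
    shapes = []
    for poly in gt.glomerulus_polygons:
        pts = np.asarray(poly, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 3:
            raise ValueError("degenerate polygon")
        shapes.append({
            "label": label,
            "points": [[float(x), float(y)] for x, y in pts],
            "shape_type": "polygon",
        })
    h, w = gt.image_shape
    data = {"version": "4.2.9", "shapes": shapes,
            "imageHeight": int(h), "imageWidth": int(w)}
    Path(path).write_text(json.dumps(data, indent=1))
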