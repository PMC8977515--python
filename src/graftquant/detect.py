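"""Positive-cell detection and density computation.

Detection pipeline for chromogenic (brightfield) slides: luma grayscale ->
difference of Gaussians (broad blur minus narrow blur, so dark stained
cells become positive peaks) -> binarize strictly above a fixed response
threshold -> 8-connected components -> drop components below a minimum
pixel area -> darkness filter on the original image (a component is kept
iff at least one of its pixels has max(R, G, B) below the darkness cutoff;
stained nuclei are nearly black while counterstain and debris are not).

Detected cells are assigned to the glomerular or non-glomerular compartment
by looking up their centroid pixel in the glomerulus mask, and densities are
counts divided by compartment area in mm^2.

The fluorescence (MET) extension runs the same blob detector per channel
with inverted polarity (bright blobs on dark ground) and no darkness filter,
then pairs detections across the two channels by centroid proximity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .geometry import RegionMask, _structure, to_grayscale

__all__ = [
    "DoGConfig", "MetConfig", "Cell", "CellDetectionSet",
    "dog_response", "detect_cells", "assign_compartments",
    "compute_densities", "detect_met_events",
]


@dataclass
class DoGConfig:
    sigma1: float = 0.5
    sigma2: float = 3.0
    response_threshold: float = 10.0   # on the 8-bit response scale
    min_component_area_px: int = 10
    darkness_max_rgb: int = 100
    darkness_rule: str = "any"         # "any": keep if any pixel dark; "all": every pixel dark
    truncate: float = 4.0              # Gaussian kernel truncation, in sigmas

    def __post_init__(self) -> None:
        if not 0 < self.sigma1 < self.sigma2:
            raise ValueError("need 0 < sigma1 < sigma2")
        if self.response_threshold <= 0 or self.min_component_area_px <= 0:
            raise ValueError("thresholds must be positive")
        if self.darkness_rule not in ("any", "all"):
            raise ValueError("darkness_rule must be 'any' or 'all'")


@dataclass
class Cell:
    x: float
    y: float
    area_px: int
    compartment: Optional[str] = None  # glomerular | non_glomerular


@dataclass
class CellDetectionSet:
    slide_id: str
    marker: str
    cells: list = field(default_factory=list)
    n_dropped_outside_tissue: int = 0

    def __len__(self) -> int:
        return len(self.cells)

    def centroids(self) -> np.ndarray:
        return np.array([[c.x, c.y] for c in self.cells]).reshape(-1, 2)

    def count(self, compartment: Optional[str] = None) -> int:
        if compartment is None:
            return len(self.cells)
        return sum(1 for c in self.cells if c.compartment == compartment)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"slide_id": self.slide_id, "marker": self.marker,
              "x": c.x, "y": c.y, "area_px": c.area_px,
              "compartment": c.compartment or ""} for c in self.cells],
            columns=["slide_id", "marker", "x", "y", "area_px", "compartment"])


def dog_response(image: np.ndarray, cfg: DoGConfig | None = None,
                 invert: bool = False) -> np.ndarray:
    """Difference-of-Gaussians band-pass response, clipped to [0, 255].

    Default polarity (broad minus narrow blur) turns dark blobs on a lighter
    ground into positive peaks; ``invert=True`` flips the sign for bright
    blobs on a dark ground (fluorescence).
    """
    cfg = cfg or DoGConfig()
    gray = to_grayscale(image)
    broad = ndimage.gaussian_filter(gray, cfg.sigma2, truncate=cfg.truncate)
    narrow = ndimage.gaussian_filter(gray, cfg.sigma1, truncate=cfg.truncate)
    response = (narrow - broad) if invert else (broad - narrow)
    return np.clip(response, 0.0, 255.0)


def _component_centroids(labels: np.ndarray, index: np.ndarray):
    return ndimage.center_of_mass(np.ones_like(labels), labels, index)


def detect_cells(
    image: np.ndarray,
    cfg: DoGConfig | None = None,
    slide_id: str = "",
    marker: str = "",
    invert: bool = False,
    darkness_filter: bool = True,
) -> CellDetectionSet:
    """Detect positively stained cells on a brightfield RGB slide.

    Components of the thresholded band-pass response survive iff their pixel
    area is at least ``min_component_area_px`` and (brightfield only) the
    darkness filter passes. Centroids are component pixel means in (x, y).
    """
    cfg = cfg or DoGConfig()
    image = np.asarray(image)
    response = dog_response(image, cfg, invert=invert)
    binary = response > cfg.response_threshold
    labels, n = ndimage.label(binary, structure=_structure(8))
    det = CellDetectionSet(slide_id=slide_id, marker=marker)
    if n == 0:
        return det
    areas = np.bincount(labels.ravel())[1:]
    keep = areas >= cfg.min_component_area_px
    if darkness_filter and image.ndim == 3:
        max_rgb = image.max(axis=2)
        dark = max_rgb < cfg.darkness_max_rgb
        if cfg.darkness_rule == "any":
            has_dark = ndimage.labeled_comprehension(
                dark, labels, np.arange(1, n + 1), np.any, bool, False)
        else:
            has_dark = ndimage.labeled_comprehension(
                dark, labels, np.arange(1, n + 1), np.all, bool, False)
        keep &= has_dark
    idx = np.nonzero(keep)[0] + 1
    if len(idx) == 0:
        return det
    centroids = _component_centroids(labels, idx)
    for (cy, cx), label in zip(np.atleast_2d(centroids), idx):
        det.cells.append(Cell(x=float(cx), y=float(cy), area_px=int(areas[label - 1])))
    return det


def assign_compartments(
    detections: CellDetectionSet,
    glom_mask: RegionMask,
    biopsy_mask: RegionMask,
) -> CellDetectionSet:
    """Label each cell glomerular / non-glomerular by centroid containment.

    A cell whose centroid pixel lies in the glomerulus mask is glomerular;
    otherwise non-glomerular if inside the biopsy mask; cells outside the
    biopsy tissue entirely (background artifacts) are dropped and counted in
    ``n_dropped_outside_tissue``.
    """
    if glom_mask.labels.shape != biopsy_mask.labels.shape:
        raise ValueError("glomerulus and biopsy masks must share shape")
    out = CellDetectionSet(slide_id=detections.slide_id, marker=detections.marker)
    h, w = biopsy_mask.labels.shape
    for cell in detections.cells:
        py, px = int(round(cell.y)), int(round(cell.x))
        if not (0 <= py < h and 0 <= px < w):
            out.n_dropped_outside_tissue += 1
            continue
        if glom_mask.labels[py, px] > 0:
            comp = "glomerular"
        elif biopsy_mask.labels[py, px] > 0:
            comp = "non_glomerular"
        else:
            out.n_dropped_outside_tissue += 1
            continue
        out.cells.append(replace(cell, compartment=comp))
    return out


def compartment_areas_mm2(glom_mask: RegionMask, biopsy_mask: RegionMask) -> dict:
    """Glomerular area and non-glomerular remainder of the biopsy, in mm^2.

    The glomerulus mask is expected to be clipped to the biopsy mask so the
    two compartments partition the tissue.
    """
    from .geometry import mask_area_mm2

    glom = mask_area_mm2(glom_mask)
    total = mask_area_mm2(biopsy_mask)
    if glom > total:
        raise ValueError("glomerular area exceeds biopsy area; masks inconsistent")
    return {"glomerular": glom, "non_glomerular": total - glom}


def compute_densities(
    detections: Sequence[CellDetectionSet],
    areas: Mapping[str, Mapping[str, float]],
    slide_to_recipient: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Cell densities (cells/mm^2) per recipient x (marker, compartment).

    ``areas`` maps slide_id -> {compartment: mm^2}. Zero area with a nonzero
    count raises (mask inconsistency); missing slides stay missing (NaN),
    never zero. Returns a wide frame with columns ``{marker}_{compartment}``
    indexed by recipient_id (slide_id when no mapping given).
    """
    rows: dict[str, dict[str, float]] = {}
    for det in detections:
        rid = slide_to_recipient[det.slide_id] if slide_to_recipient else det.slide_id
        slide_areas = areas[det.slide_id]
        for comp in ("glomerular", "non_glomerular"):
            count = det.count(comp)
            area = float(slide_areas[comp])
            if area <= 0:
                if count > 0:
                    raise ValueError(
                        f"slide {det.slide_id}: {count} cells in zero-area "
                        f"{comp} compartment; masks inconsistent")
                continue
            rows.setdefault(rid, {})[f"{det.marker}_{comp}"] = count / area
    cols = sorted({c for row in rows.values() for c in row})
    df = pd.DataFrame.from_dict(rows, orient="index", columns=cols)
    df.index.name = "recipient_id"
    return df.sort_index()


# ---------------------------------------------------------------------------
# Fluorescence colocalization extension

@dataclass
class MetConfig:
    """Parameters for the MPO/Histone-H3 double-positive (MET) counter.

    Detections from the two registered channels colocalize when their
    centroids lie within ``radius_px``; pairing is greedy nearest-first and
    one-to-one.
    """

    dog: DoGConfig = field(default_factory=DoGConfig)
    response_threshold_ch0: Optional[float] = None  # default: dog.response_threshold
    response_threshold_ch1: Optional[float] = None
    radius_px: float = 5.0

    def __post_init__(self) -> None:
        if self.radius_px <= 0:
            raise ValueError("radius_px must be positive")


def _pair_within(a: np.ndarray, b: np.ndarray, radius: float) -> list[tuple[int, int]]:
    """Greedy one-to-one matching of point sets within a distance cutoff."""
    if len(a) == 0 or len(b) == 0:
        return []
    tree = cKDTree(b)
    candidates = []
    for i, pt in enumerate(a):
        for j in tree.query_ball_point(pt, radius):
            candidates.append((float(np.hypot(*(pt - b[j]))), i, j))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, i, j in candidates:
        if i not in used_a and j not in used_b:
            pairs.append((i, j))
            used_a.add(i)
            used_b.add(j)
    return pairs


def detect_met_events(if_image: np.ndarray, cfg: MetConfig | None = None):
    """Count double-positive (colocalized) cells on a two-channel image.

    Each channel is run through the blob detector in fluorescence mode
    (bright-on-dark polarity, darkness filter disabled), then detections are
    paired across channels within ``radius_px``. Returns
    ``(n_pairs, det_ch0, det_ch1)``.
    """
    cfg = cfg or MetConfig()
    if_image = np.asarray(if_image)
    if if_image.ndim != 3 or if_image.shape[2] != 2:
        raise ValueError("expected a two-channel HxWx2 image")
    dets = []
    for ch, thresh in ((0, cfg.response_threshold_ch0), (1, cfg.response_threshold_ch1)):
        dog = cfg.dog if thresh is None else replace(cfg.dog, response_threshold=thresh)
        dets.append(detect_cells(if_image[:, :, ch], dog, marker=f"ch{ch}",
                                 invert=True, darkness_filter=False))
    pairs = _pair_within(dets[0].centroids(), dets[1].centroids(), cfg.radius_px)
    return len(pairs), dets[0], dets[1]
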