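"""End-to-end orchestration: simulate -> area -> segment -> detect ->
densities -> statistics, with config, seeds, and deterministic outputs.

`make_demo_dataset` writes a self-contained fixture bundle (cohort CSV,
synthetic slides with annotations and ground truth, and the cohort-level
density matrix) sized to run the full pipeline in minutes on one CPU.
`run_pipeline` executes the stages in dependency order and writes CSV/JSON
results plus a run report carrying the seed, the config hash and a checksum
per output file, so identical configurations yield byte-identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import shutil
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from . import stats as assoc
from .cohort import apply_eligibility, load_cohort, write_cohort
from .detect import (DoGConfig, assign_compartments, compartment_areas_mm2,
                     compute_densities, detect_cells)
from .geometry import AreaConfig, compute_biopsy_mask, mask_area_mm2, mask_area_um2
from .glomseg import (TileSpec, oracle_probability_map, prob_to_glomerulus_mask,
                      rasterize_polygons, read_labelme_annotations,
                      stitch_probability, tile_image)
from .synthetic import (MARKERS, SimCohortParams, SlideSpec, render_ihc_slide,
                        simulate_cohort, write_labelme_annotations)

__all__ = ["PipelineConfig", "RunReport", "make_demo_dataset", "run_pipeline"]


@dataclass
class PipelineConfig:
    data_dir: Path
    out_dir: Path
    seed: int = 0
    area: AreaConfig = field(default_factory=AreaConfig)
    tiles: TileSpec = field(default_factory=TileSpec)
    dog: DoGConfig = field(default_factory=DoGConfig)
    segmenter: str = "oracle"  # oracle (annotations) | trained pixel classifier path

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key in ("data_dir", "out_dir"):
            if key in raw:
                kwargs[key] = Path(raw[key])
        for key in ("seed", "segmenter"):
            if key in raw:
                kwargs[key] = raw[key]
        if "area" in raw:
            kwargs["area"] = AreaConfig(**raw["area"])
        if "tiles" in raw:
            t = raw["tiles"]
            kwargs["tiles"] = TileSpec(**{k: tuple(v) if isinstance(v, list) else v
                                          for k, v in t.items()})
        if "dog" in raw:
            kwargs["dog"] = DoGConfig(**raw["dog"])
        return cls(**kwargs)

    def validate(self) -> None:
        if not Path(self.data_dir).exists():
            raise FileNotFoundError(f"data_dir {self.data_dir} does not exist")
        manifest = Path(self.data_dir) / "slides.csv"
        if manifest.exists():
            for _, row in pd.read_csv(manifest).iterrows():
                for col in ("image", "annotation"):
                    p = Path(self.data_dir) / str(row[col])
                    if not p.exists():
                        raise FileNotFoundError(f"referenced path missing: {p}")
        if not (Path(self.data_dir) / "cohort.csv").exists():
            raise FileNotFoundError(f"cohort.csv missing under {self.data_dir}")

    def config_hash(self) -> str:
        payload = {
            "seed": self.seed, "segmenter": self.segmenter,
            "area": dataclasses.asdict(self.area),
            "tiles": dataclasses.asdict(self.tiles),
            "dog": dataclasses.asdict(self.dog),
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    seed: int
    config_hash: str
    outputs: dict  # relative path -> sha256
    stages: list

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------

def make_demo_dataset(outdir: str | Path, seed: int = 0,
                      n_imaged_recipients: int = 2,
                      slide_px: int = 512) -> Path:
    """Write the demo fixture bundle: cohort CSV, density matrix, and one
    synthetic slide per marker for the first ``n_imaged_recipients``
    recipients (with LabelMe annotations and ground-truth cell lists)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    records, truth = simulate_cohort(SimCohortParams(seed=seed))
    write_cohort(records, outdir / "cohort.csv")
    truth["density_matrix"].round(6).to_csv(outdir / "density_matrix.csv")
    manifest = []
    for ri in range(n_imaged_recipients):
        rid = records[ri].recipient_id
        for mi, marker in enumerate(MARKERS):
            slide_id = f"{rid}_{marker}"
            spec = SlideSpec(width_px=slide_px, height_px=slide_px,
                             n_tissue_fragments=1, n_glomeruli=2,
                             n_positive_cells=25, n_negative_cells=25,
                             seed=seed * 1000 + ri * 10 + mi)
            img, gt = render_ihc_slide(spec)
            Image.fromarray(img).save(outdir / f"{slide_id}.png")
            write_labelme_annotations(gt, outdir / f"{slide_id}.json")
            gt_cells = [{"x": x, "y": y, "compartment": c} for x, y, c in gt.positive_cells]
            (outdir / f"{slide_id}.truth.json").write_text(json.dumps(
                {"positive_cells": gt_cells,
                 "n_negative_cells": len(gt.negative_cells)}, indent=1))
            manifest.append({"slide_id": slide_id, "recipient_id": rid,
                             "marker": marker, "image": f"{slide_id}.png",
                             "annotation": f"{slide_id}.json"})
    pd.DataFrame(manifest).to_csv(outdir / "slides.csv", index=False)
    return outdir


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; abort (retaining partial output under ``failed/``)
    if any stage raises."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages: list[str] = []
    try:
        return _run_stages(config, out, stages)
    except Exception as exc:
        failed = out.parent / "failed"
        if out.exists():
            shutil.rmtree(failed, ignore_errors=True)
            out.rename(failed)
        raise RuntimeError(
            f"pipeline failed at stage {stages[-1] if stages else 'setup'}: {exc}") from exc


def _run_stages(config: PipelineConfig, out: Path, stages: list) -> RunReport:
    data = Path(config.data_dir)

    stages.append("cohort")
    records = load_cohort(data / "cohort.csv")
    retained, exclusion_log = apply_eligibility(records)
    exclusion_log.to_json(out / "exclusions.json")

    stages.append("slides")
    manifest = pd.read_csv(data / "slides.csv") if (data / "slides.csv").exists() \
        else pd.DataFrame(columns=["slide_id", "recipient_id", "marker", "image", "annotation"])
    manifest = manifest.sort_values("slide_id").reset_index(drop=True)

    area_rows, detection_frames, areas, slide_to_recipient, det_sets = [], [], {}, {}, []
    trained_model = None
    if config.segmenter not in ("oracle",):
        raise ValueError(f"unknown segmenter {config.segmenter!r}")
    for _, row in manifest.iterrows():
        slide_id = str(row["slide_id"])
        img = np.asarray(Image.open(data / str(row["image"])))

        stages.append(f"area:{slide_id}")
        biopsy = compute_biopsy_mask(img, config.area)
        area_rows.append({"slide_id": slide_id,
                          "component_count": biopsy.n_components,
                          "area_um2": mask_area_um2(biopsy),
                          "area_mm2": mask_area_mm2(biopsy)})

        stages.append(f"segment:{slide_id}")
        polys = read_labelme_annotations(data / str(row["annotation"]))
        gt_mask = rasterize_polygons(polys, img.shape[:2], config.area.px_per_micron)
        # oracle path: tile the ground-truth probability map through the
        # same harness used for model predictions, then stitch and threshold
        prob_tiles = tile_image(oracle_probability_map(gt_mask), config.tiles)
        prob = stitch_probability(prob_tiles, img.shape[:2])
        glom = prob_to_glomerulus_mask(prob, config.tiles, biopsy_mask=biopsy,
                                       px_per_micron=config.area.px_per_micron)

        stages.append(f"detect:{slide_id}")
        det = detect_cells(img, config.dog, slide_id=slide_id, marker=str(row["marker"]))
        det = assign_compartments(det, glom, biopsy)
        detection_frames.append(det.to_frame())
        det_sets.append(det)
        areas[slide_id] = compartment_areas_mm2(glom, biopsy)
        slide_to_recipient[slide_id] = str(row["recipient_id"])

    pd.DataFrame(area_rows, columns=["slide_id", "component_count", "area_um2", "area_mm2"]) \
        .to_csv(out / "areas.csv", index=False)
    (pd.concat(detection_frames, ignore_index=True) if detection_frames
     else pd.DataFrame(columns=["slide_id", "marker", "x", "y", "area_px", "compartment"])) \
        .to_csv(out / "detections.csv", index=False)

    stages.append("densities")
    if det_sets:
        slide_densities = compute_densities(det_sets, areas, slide_to_recipient)
        slide_densities.round(6).to_csv(out / "slide_densities.csv")

    stages.append("stats")
    dd_by_id = {r.recipient_id: r.ddcfdna_fraction for r in retained}
    density_path = data / "density_matrix.csv"
    stat_rows = []
    omnibus, pairwise = assoc.group_compare_ddcfdna(retained)
    stat_rows.append({"analysis": "ddcfdna_group_omnibus", "term": "kruskal-wallis",
                      "group_a": "", "group_b": "", "statistic": omnibus.statistic,
                      "df": omnibus.df, "p_value": omnibus.p_value})
    for _, pr in pairwise.iterrows():
        stat_rows.append({"analysis": "ddcfdna_group_pairwise", "term": "wilcoxon",
                          "group_a": pr["group_a"], "group_b": pr["group_b"],
                          "statistic": pr["statistic"], "df": np.nan,
                          "p_value": pr["p_value"]})
    for lesion in ("g", "t", "v", "i", "ci", "ct", "ptc", "mvi", "ah", "c4d"):
        res = assoc.lesion_score_association(retained, lesion)
        if res["omnibus"] is not None:
            stat_rows.append({"analysis": "lesion_association", "term": lesion,
                              "group_a": "", "group_b": "",
                              "statistic": res["omnibus"].statistic,
                              "df": res["omnibus"].df,
                              "p_value": res["omnibus"].p_value})
        if res["special"] is not None:
            name, tr = res["special"]
            stat_rows.append({"analysis": "lesion_contrast", "term": name,
                              "group_a": "", "group_b": "",
                              "statistic": tr.statistic, "df": np.nan,
                              "p_value": tr.p_value})
    tertiles = assoc.tertile_split(retained)
    tertiles.to_frame().to_csv(out / "tertiles.csv")
    if density_path.exists():
        density = pd.read_csv(density_path, index_col="recipient_id")
        joined = density.copy()
        joined["log_ddcfdna"] = np.log([dd_by_id[i] for i in joined.index])
        clust = assoc.cluster_heatmap(density)
        pd.Series(density.index[clust.row_order], name="recipient_id") \
            .to_csv(out / "cluster_row_order.csv", index=False)
        r, p, n = assoc.correlation_matrix(joined)
        r.round(6).to_csv(out / "correlation_r.csv")
        p.apply(lambda s: s.map(lambda v: f"{v:.6g}")).to_csv(out / "correlation_p.csv")
        for col in density.columns:
            stat_rows.append({"analysis": "ddcfdna_density_correlation", "term": col,
                              "group_a": "", "group_b": "",
                              "statistic": r.loc["log_ddcfdna", col],
                              "df": np.nan, "p_value": p.loc["log_ddcfdna", col]})
    stats_df = pd.DataFrame(stat_rows,
                            columns=["analysis", "term", "group_a", "group_b",
                                     "statistic", "df", "p_value"])
    stats_df["statistic"] = stats_df["statistic"].map(lambda v: f"{v:.8g}")
    stats_df["p_value"] = stats_df["p_value"].map(lambda v: f"{v:.8g}")
    stats_df.to_csv(out / "stats.csv", index=False)

    stages.append("report")
    outputs = {p.name: _sha256(p) for p in sorted(out.glob("*")) if p.is_file()}
    report = RunReport(seed=config.seed, config_hash=config.config_hash(),
                       outputs=outputs, stages=stages)
    report.to_json(out / "run_report.json")
    return report
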