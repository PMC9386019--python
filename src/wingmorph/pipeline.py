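"""End-to-end wing analysis: image in, tables/models/overlays out.

This is the glue the CLI calls; each stage is the corresponding module's
public function, so everything here is also reachable piecewise from
Python.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import export as export_mod
from . import imaging, segmentation, skeleton
from .corrugation import CorrugationParams, extract_sections, loft_surface
from .morphometrics import ScaleSpec, measure_cells, summarize
from .simplify import rdp_simplify

log = logging.getLogger("wingmorph")


@dataclass
class AnalysisResult:
    segmentation: segmentation.SegmentationResult
    boundaries: dict                  # region id -> SimplifiedBoundary
    cells: list                       # CellMorphometry
    junctions: object                 # JunctionSet
    skeleton: np.ndarray
    model: export_mod.WingModel
    quality: imaging.QualityReport
    summaries: dict = field(default_factory=dict)


def analyze(image, secondary=None, epsilon: float = 1.0,
            scale: ScaleSpec | None = None, n_bins: int = 10,
            sections: str = "two_section", model_kind: str = "planar",
            hole_seeds=(), invert: bool = False,
            corrugation: CorrugationParams | None = None,
            threshold: float | None = None) -> AnalysisResult:
    """Run the full pipeline on an image (path or array).

    Returns every intermediate product; see :func:`write_outputs` for the
    file layout the CLI writes.
    """
    if isinstance(image, (str, Path)):
        image = imaging.load_image(image)
    image = np.asarray(image)
    if image.dtype == bool:
        binary = image.copy()
        quality = imaging.QualityReport()
    else:
        quality = imaging.assess_quality(image)
        for flag in sorted(quality.flags):
            log.warning("input image quality: %s (%s)", flag, quality.metrics)
        binary = imaging.binarize(image, threshold)
    if invert:
        binary = ~binary

    seg = segmentation.segment(binary, hole_seeds=hole_seeds)
    log.info("segmented: %d cells, %d holes",
             len(seg.subdomains), len(seg.discontinuities))

    boundaries = {}
    for region in seg.regions:
        boundaries[region.id] = rdp_simplify(
            region.boundary_chain, epsilon, closed=True, source_id=region.id)

    height = seg.shape[0]
    cell_polys = {r.id: boundaries[r.id].vertices for r in seg.subdomains}
    cells = measure_cells(cell_polys, height, scale=scale)
    summaries = {m: summarize(cells, m, n_bins=n_bins)
                 for m in ("area", "length", "width")}

    main_mask = seg.main.interior_mask(seg.shape)
    skel, junctions = skeleton.find_junctions(binary, main_mask)

    surface = None
    if model_kind == "shell":
        if secondary is None:
            raise ValueError("a shell model needs a secondary corrugation image")
        if isinstance(secondary, (str, Path)):
            secondary = imaging.load_image(secondary)
        params = corrugation or CorrugationParams()
        fld = extract_sections(np.asarray(secondary), params,
                               expected_shape=seg.shape)
        surface = loft_surface(
            fld, boundaries[seg.main.id].vertices,
            [boundaries[r.id].vertices for r in seg.discontinuities],
            image_height=height)

    model = export_mod.build_model(seg, boundaries, sections,
                                   surface=surface, scale=scale)
    return AnalysisResult(segmentation=seg, boundaries=boundaries, cells=cells,
                          junctions=junctions, skeleton=skel, model=model,
                          quality=quality, summaries=summaries)


def write_outputs(result: AnalysisResult, out_dir, materials=None,
                  overlays: bool = True) -> dict:
    """Write the standard output bundle; returns {name: path}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    unit = result.cells[0].unit if result.cells else "px"
    df = pd.DataFrame(
        [{"cell_id": c.cell_id, "area": c.area, "length": c.length,
          "width": c.width, "centroid_x": c.centroid[0],
          "centroid_y": c.centroid[1], "unit": c.unit}
         for c in result.cells])
    paths["morphometry"] = out / "morphometry.csv"
    df.to_csv(paths["morphometry"], index=False)

    hist_rows = []
    for metric, summ in result.summaries.items():
        for i, count in enumerate(summ.counts):
            hist_rows.append({"metric": metric, "bin_left": summ.bin_edges[i],
                              "bin_right": summ.bin_edges[i + 1],
                              "count": int(count), "unit": summ.unit})
    paths["histograms"] = out / "histograms.csv"
    pd.DataFrame(hist_rows).to_csv(paths["histograms"], index=False)

    scale = result.model.scale
    jrows = []
    for i, (r, c) in enumerate(result.junctions.junctions):
        row = {"id": i, "row": int(r), "col": int(c)}
        if scale:
            row[f"x_{scale.unit}"] = c * scale.length_per_pixel
            row[f"y_{scale.unit}"] = ((result.model.image_height - 1 - r)
                                      * scale.length_per_pixel)
        jrows.append(row)
    paths["junctions"] = out / "junctions.csv"
    pd.DataFrame(jrows).to_csv(paths["junctions"], index=False)

    paths["segmentation"] = out / "segmentation.json"
    simplified = {
        str(b.source_id): {"epsilon": b.epsilon,
                           "arc_accuracy": b.arc_accuracy,
                           "vertices": b.vertices.tolist()}
        for b in result.boundaries.values()}
    segmentation.write_result_json(result.segmentation, paths["segmentation"],
                                   extra={"simplified": simplified})
    paths["labels"] = out / "labels.png"
    segmentation.write_label_map(result.segmentation, paths["labels"])

    paths["script"] = out / "model_script.py"
    export_mod.write_solver_script(result.model, materials, paths["script"])
    for fmt in ("obj", "stl", "json"):
        paths[f"model_{fmt}"] = out / f"model.{fmt}"
        export_mod.write_neutral_geometry(result.model, paths[f"model_{fmt}"])

    paths["skeleton"] = out / "skeleton.png"
    imaging.save_image(result.skeleton, paths["skeleton"])

    if overlays:
        paths["overlay"] = out / "overlay.png"
        _draw_overlay(result, paths["overlay"])
    return paths


def _draw_overlay(result: AnalysisResult, path) -> None:
    """Boundary points (red) and junctions (blue) over the label map."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    seg = result.segmentation
    h, w = seg.shape
    canvas = np.zeros((h, w), dtype=float)
    for r in seg.subdomains:
        canvas[r.interior[:, 0], r.interior[:, 1]] = 0.7
    canvas[seg.main.boundary_pixels[:, 0], seg.main.boundary_pixels[:, 1]] = 0.3
    fig, ax = plt.subplots(figsize=(8, 8 * h / max(w, 1)))
    ax.imshow(canvas, cmap="gray", interpolation="nearest")
    for b in result.boundaries.values():
        ax.plot(b.vertices[:, 1], b.vertices[:, 0], ".", color="red",
                markersize=2)
    j = result.junctions.junctions
    if len(j):
        ax.plot(j[:, 1], j[:, 0], "o", color="dodgerblue", markersize=4,
                markerfacecolor="none")
    ax.set_axis_off()
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
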