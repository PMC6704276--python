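"""End-to-end orchestration: MSI → segmentation → ROI → LMD XML.

``run_pipeline`` executes the whole chain from a configuration mapping
(typically loaded from YAML): load the MSI data, build the transform chain,
mask to the annotated tumor area, TIC-normalize, segment by NNMF with
silhouette model selection, post-process each segment morphologically,
upscale to the histology frame, trace boundaries, re-express them relative
to the origin teaching point, and write the LMD XML plus the intermediate
tables.  Every transform and count is logged.

By default the tumor mask is applied before normalization
(``normalize_first: true`` flips the order).
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np

from . import geometry, lmd, msi, roi, segmentation

logger = logging.getLogger(__name__)


def load_transform(cfg: dict, source: str, target: str) -> geometry.AffineTransform2D:
    """A transform from config: either ``{"json": path}`` (serialized) or
    ``{"points": path}`` (control points to fit)."""
    if "json" in cfg:
        t = geometry.AffineTransform2D.read_json(cfg["json"])
    elif "points" in cfg:
        cps = geometry.ControlPointSet.read_csv(cfg["points"], source, target)
        t = geometry.fit_affine(cps)
    else:
        raise ValueError(f"transform {source}->{target}: need 'json' or 'points'")
    logger.info("transform %s->%s: params=%s", source, target, t.params)
    return t


def run_pipeline(config: dict) -> dict:
    """Run the full chain; returns a dict of the in-memory results.

    Output files (labels TSV, silhouette TSV, boundary JSON, LMD XML) are
    written under ``config["out_dir"]``.
    """
    out_dir = Path(config["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)

    msi_cfg = config["msi"]
    ds = msi.load_msi(msi_cfg["path"], format=msi_cfg.get("format"),
                      pitch=msi_cfg.get("pitch", 70.0))
    logger.info("loaded %d pixels x %d channels", ds.n_pixels, ds.n_channels)

    tcfg = config["transforms"]
    t_mo = load_transform(tcfg["msi_to_optical"], "msi", "optical")
    t_oh = load_transform(tcfg["optical_to_he"], "optical", "he")
    t_mh = geometry.compose(t_oh, t_mo)

    normalize_first = bool(config.get("normalize_first", False))
    if normalize_first:
        ds = msi.tic_normalize(ds)
    if config.get("annotations"):
        ann = msi.AnnotationSet.read_json(config["annotations"])
        if ann.frame != "he":
            raise ValueError(f"annotations must be in the 'he' frame, got {ann.frame!r}")
        mask = msi.rasterize_annotations(ann, t_mh.inverse(), ds)
        ds = msi.mask_dataset(ds, mask)
        logger.info("tumor mask retains %d pixels", ds.n_pixels)
    if not normalize_first:
        ds = msi.tic_normalize(ds)

    seg_cfg = config.get("segmentation", {})
    result = segmentation.select_k(
        ds.spectra,
        k_range=range(seg_cfg.get("k_min", 2), seg_cfg.get("k_max", 5) + 1),
        seed=seg_cfg.get("seed", 0),
        restarts=seg_cfg.get("restarts", 3),
    )
    logger.info("chosen k=%d, silhouettes=%s", result.chosen_k, result.silhouette_by_k)

    labels = roi.LabelImage.from_dataset_labels(ds.coords, result.labels)
    labels.write_tsv(out_dir / "labels.tsv")
    with open(out_dir / "silhouette.tsv", "w") as fh:
        fh.write("k\tscore\n")
        for k, v in sorted(result.silhouette_by_k.items()):
            fh.write(f"{k}\t{v}\n")

    roi_cfg = config.get("roi", {})
    target_shape = tuple(roi_cfg.get("target_shape", (1600, 1600)))
    boundary_sets = roi.process_segment_masks(
        labels, result.chosen_k, t_mh, target_shape,
        max_removed_area=roi_cfg.get("max_removed_area", roi.DEFAULT_MAX_REMOVED_AREA),
    )
    for bset in boundary_sets:
        logger.info("segment %d: %d region(s)", bset.segment_id, len(bset.polygons))
        bset.write_json(out_dir / f"boundaries_segment_{bset.segment_id}.json")

    # boundaries were traced in the H&E frame; bring them to the optical frame
    t_ho = t_oh.inverse()
    optical_sets = [
        roi.RoiBoundarySet(
            frame="optical",
            segment_id=b.segment_id,
            polygons=[[tuple(p) for p in t_ho.apply(poly)] for poly in b.polygons],
        )
        for b in boundary_sets
        if b.polygons
    ]

    tp = lmd.TeachingPoints.read_csv(config["teaching_points"])
    doc = lmd.to_lmd_coordinates(optical_sets, tp, flip_y=bool(config.get("flip_y", False)))
    xml_path = out_dir / "rois.xml"
    lmd.write_lmd_xml(doc, xml_path)
    logger.info("wrote %d shape(s) to %s", len(doc.shapes), xml_path)

    return {
        "dataset": ds,
        "segmentation": result,
        "labels": labels,
        "boundaries": boundary_sets,
        "document": doc,
        "xml_path": xml_path,
    }
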