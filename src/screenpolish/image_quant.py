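"""Nuclear segmentation, ROI construction, and well scoring.

The per-cell readout is the mean reporter intensity inside an eroded
nuclear mask divided by the mean inside a perinuclear ring; the well score
aggregates per-cell ratios (median by default).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage as ndi
from skimage import filters, measure, segmentation

from .synthetic_screen import well_name

__all__ = [
    "RoiPair",
    "CellMeasurement",
    "WellScore",
    "segment_nuclei",
    "build_rois",
    "measure_cell",
    "aggregate_well",
    "quantify_field",
    "quantify_images",
]

logger = logging.getLogger(__name__)


@dataclass
class RoiPair:
    """Nuclear ROI (eroded stain mask) and cytoplasmic ring for one cell."""

    label: int
    nuclear_mask: np.ndarray  # bool, full image shape
    ring_mask: np.ndarray     # bool, full image shape
    erosion_px: int = 2
    ring_width_px: int = 3
    gap_px: int = 0


@dataclass
class CellMeasurement:
    cell_id: int
    nuclear_mean_intensity: float
    ring_mean_intensity: float
    ratio: float
    n_pixels_nuc: int
    n_pixels_ring: int
    flagged: bool = False


@dataclass
class WellScore:
    score: float
    n_cells: int
    missing: bool


def _distance_to_mask(mask: np.ndarray, metric: str) -> np.ndarray:
    """Distance from each pixel to the nearest True pixel of ``mask``."""
    if metric == "euclidean":
        return ndi.distance_transform_edt(~mask)
    if metric == "chessboard":
        return ndi.distance_transform_cdt(~mask, metric="chessboard").astype(float)
    raise ValueError(f"unknown metric {metric!r}; expected 'euclidean' or 'chessboard'")


def _distance_to_background(mask: np.ndarray, metric: str) -> np.ndarray:
    if metric == "euclidean":
        return ndi.distance_transform_edt(mask)
    if metric == "chessboard":
        return ndi.distance_transform_cdt(mask, metric="chessboard").astype(float)
    raise ValueError(f"unknown metric {metric!r}")


def segment_nuclei(
    image: np.ndarray,
    threshold_method: str | float = "otsu",
    min_area_px: int = 30,
) -> np.ndarray:
    """Label nuclei in the nuclear-stain channel.

    Thresholds (Otsu by default, or a fixed value), discards components
    touching the image border and components smaller than ``min_area_px``.
    A blank (constant) image yields zero labels rather than an error.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    if np.any(image < 0):
        raise ValueError("expected nonnegative intensities")
    if image.max() == image.min():
        return np.zeros(image.shape, dtype=np.int32)
    if threshold_method == "otsu":
        thresh = filters.threshold_otsu(image)
    else:
        thresh = float(threshold_method)
    mask = image > thresh
    mask = segmentation.clear_border(mask)
    labels = measure.label(mask)
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < min_area_px)
    mask &= ~np.isin(labels, small[small > 0])
    return measure.label(mask).astype(np.int32)


def build_rois(
    labels: np.ndarray,
    erosion_px: int = 2,
    ring_width_px: int = 3,
    gap_px: int = 0,
    metric: str = "euclidean",
    min_nuclear_px: int = 4,
) -> tuple[list[RoiPair], list[int]]:
    """Build per-cell nuclear and ring ROIs from a labeled nuclear-stain mask.

    Nuclear ROI: the stain mask eroded by ``erosion_px`` (the "circle drawn
    inside" definition, implemented morphologically so it is robust to
    non-circular nuclei and reduces to the concentric-circle definition on
    disks).  Ring ROI: pixels at distance in (gap_px, gap_px + ring_width_px]
    from the stain mask, which is exactly dilation-by-(gap+width) minus
    dilation-by-gap for a disk structuring element.  Ring pixels inside any
    cell's stain mask are never counted; pixels claimed by several rings go
    to the nearest nucleus (ties to the lower label).

    Returns (rois, flagged_labels); a cell whose nucleus erodes away entirely
    is excluded and its label reported in ``flagged_labels``.
    """
    if erosion_px < 0 or ring_width_px < 0 or gap_px < 0:
        raise ValueError("erosion_px, ring_width_px and gap_px must be >= 0")
    labels = np.asarray(labels)
    ids = [int(i) for i in np.unique(labels) if i != 0]
    foreground = labels > 0
    shape = labels.shape

    rois: list[RoiPair] = []
    flagged: list[int] = []
    ring_owner = np.zeros(shape, dtype=np.int32)   # first claimant (lowest label)
    contested = np.zeros(shape, dtype=bool)

    objects = ndi.find_objects(labels)
    pad = gap_px + ring_width_px + 1
    candidate_rings: dict[int, np.ndarray] = {}

    for lab in ids:
        sl = objects[lab - 1]
        rsl = (
            slice(max(sl[0].start - pad, 0), min(sl[0].stop + pad, shape[0])),
            slice(max(sl[1].start - pad, 0), min(sl[1].stop + pad, shape[1])),
        )
        local = labels[rsl] == lab

        d_bg = _distance_to_background(local, metric)
        nuclear_local = d_bg > erosion_px
        # a near-empty eroded nucleus (tiny stain blob) gives a meaningless mean
        if nuclear_local.sum() < max(min_nuclear_px, 1):
            flagged.append(lab)
            continue

        d = _distance_to_mask(local, metric)
        ring_local = (d > gap_px) & (d <= gap_px + ring_width_px)
        ring_local &= ~(labels[rsl] > 0)  # never measure another nucleus as cytoplasm

        nuclear_mask = np.zeros(shape, dtype=bool)
        nuclear_mask[rsl] = nuclear_local
        ring_mask = np.zeros(shape, dtype=bool)
        ring_mask[rsl] = ring_local

        contested |= ring_mask & (ring_owner > 0)
        ring_owner[ring_mask & (ring_owner == 0)] = lab
        candidate_rings[lab] = ring_mask
        rois.append(
            RoiPair(
                label=lab,
                nuclear_mask=nuclear_mask,
                ring_mask=ring_mask,
                erosion_px=erosion_px,
                ring_width_px=ring_width_px,
                gap_px=gap_px,
            )
        )

    if contested.any():
        _resolve_contested(labels, rois, candidate_rings, contested, metric)
    return rois, flagged


def _resolve_contested(
    labels: np.ndarray,
    rois: list[RoiPair],
    candidate_rings: dict[int, np.ndarray],
    contested: np.ndarray,
    metric: str,
) -> None:
    """Assign ring pixels claimed by several cells to the nearest nucleus."""
    claimants = sorted(
        lab for lab, ring in candidate_rings.items() if (ring & contested).any()
    )
    dist = {lab: _distance_to_mask(labels == lab, metric) for lab in claimants}
    coords = np.argwhere(contested)
    best = np.full(len(coords), -1, dtype=np.int64)
    best_d = np.full(len(coords), np.inf)
    for lab in claimants:  # ascending labels: strict < keeps ties at the lower label
        in_ring = candidate_rings[lab][tuple(coords.T)]
        d = dist[lab][tuple(coords.T)]
        take = in_ring & (d < best_d)
        best[take] = lab
        best_d[take] = d[take]
    for roi in rois:
        if roi.label not in claimants:
            continue
        lose = coords[(best != roi.label) & candidate_rings[roi.label][tuple(coords.T)]]
        roi.ring_mask[tuple(lose.T)] = False


def measure_cell(roi: RoiPair, reporter: np.ndarray) -> CellMeasurement:
    """Mean reporter intensity over the two ROIs; ratio = nuclear / ring."""
    reporter = np.asarray(reporter, dtype=float)
    if reporter.shape != roi.nuclear_mask.shape:
        raise ValueError("reporter image shape does not match ROI masks")
    n_nuc = int(roi.nuclear_mask.sum())
    n_ring = int(roi.ring_mask.sum())
    nuc_mean = float(reporter[roi.nuclear_mask].mean()) if n_nuc else float("nan")
    ring_mean = float(reporter[roi.ring_mask].mean()) if n_ring else float("nan")
    flagged = n_nuc == 0 or n_ring == 0 or not ring_mean > 0
    ratio = nuc_mean / ring_mean if not flagged else float("nan")
    return CellMeasurement(
        cell_id=roi.label,
        nuclear_mean_intensity=nuc_mean,
        ring_mean_intensity=ring_mean,
        ratio=ratio,
        n_pixels_nuc=n_nuc,
        n_pixels_ring=n_ring,
        flagged=flagged,
    )


def aggregate_well(
    cells: Sequence[CellMeasurement],
    min_cells: int = 20,
    mode: str = "median",
) -> WellScore:
    """Combine per-cell ratios into one well score.

    Modes: ``median`` (default) or ``mean`` of per-cell ratios, or ``pooled``
    (total nuclear intensity over total ring intensity).  Flagged cells are
    excluded; a well with fewer than ``min_cells`` usable cells is missing.
    """
    usable = [c for c in cells if not c.flagged]
    n = len(usable)
    if n < min_cells:
        return WellScore(score=float("nan"), n_cells=n, missing=True)
    ratios = np.array([c.ratio for c in usable])
    if mode == "median":
        score = float(np.median(ratios))
    elif mode == "mean":
        score = float(ratios.mean())
    elif mode == "pooled":
        nuc = sum(c.nuclear_mean_intensity * c.n_pixels_nuc for c in usable)
        ring = sum(c.ring_mean_intensity * c.n_pixels_ring for c in usable)
        n_nuc = sum(c.n_pixels_nuc for c in usable)
        n_ring = sum(c.n_pixels_ring for c in usable)
        score = (nuc / n_nuc) / (ring / n_ring)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    return WellScore(score=score, n_cells=n, missing=False)


def quantify_field(
    nuclear_image: np.ndarray,
    reporter_image: np.ndarray,
    *,
    threshold_method: str | float = "otsu",
    min_area_px: int = 30,
    erosion_px: int = 2,
    ring_width_px: int = 3,
    gap_px: int = 0,
    metric: str = "euclidean",
) -> list[CellMeasurement]:
    """Segment one field and measure every cell; flagged cells are kept (marked)."""
    labels = segment_nuclei(nuclear_image, threshold_method, min_area_px)
    rois, _ = build_rois(labels, erosion_px, ring_width_px, gap_px, metric)
    return [measure_cell(roi, reporter_image) for roi in rois]


_FIELD_RE = re.compile(r"field_(\d+)_(nuclear|reporter)\.tif$")


def quantify_images(
    images_dir: str | Path,
    platemap: pd.DataFrame,
    *,
    threshold_method: str | float = "otsu",
    min_area_px: int = 30,
    erosion_px: int = 2,
    ring_width_px: int = 3,
    gap_px: int = 0,
    min_cells: int = 20,
    aggregation: str = "median",
    metric: str = "euclidean",
    emit_cells: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Quantify a directory of per-well TIFF fields into a wells table.

    Expects the ``plate_{p}/well_{A01}/field_{k}_{channel}.tif`` layout.
    Wells listed in the plate map but lacking images are emitted as missing.
    """
    images_dir = Path(images_dir)
    well_rows = []
    cell_rows = []
    for rec in platemap.to_dict("records"):
        well_dir = (
            images_dir / f"plate_{rec['plate']}" / f"well_{well_name(rec['row'], rec['col'])}"
        )
        cells: list[CellMeasurement] = []
        if well_dir.is_dir():
            fields: dict[int, dict[str, Path]] = {}
            for path in sorted(well_dir.iterdir()):
                m = _FIELD_RE.search(path.name)
                if m:
                    fields.setdefault(int(m.group(1)), {})[m.group(2)] = path
            for k in sorted(fields):
                pair = fields[k]
                if "nuclear" not in pair or "reporter" not in pair:
                    raise FileNotFoundError(
                        f"well {well_dir} field {k}: need both nuclear and reporter TIFFs"
                    )
                cells.extend(
                    quantify_field(
                        tifffile.imread(pair["nuclear"]),
                        tifffile.imread(pair["reporter"]),
                        threshold_method=threshold_method,
                        min_area_px=min_area_px,
                        erosion_px=erosion_px,
                        ring_width_px=ring_width_px,
                        gap_px=gap_px,
                        metric=metric,
                    )
                )
        agg = aggregate_well(cells, min_cells=min_cells, mode=aggregation)
        well_rows.append(
            {
                "plate": rec["plate"],
                "row": rec["row"],
                "col": rec["col"],
                "well": well_name(rec["row"], rec["col"]),
                "gene_id": rec["gene_id"],
                "sirna_id": rec["sirna_id"],
                "class": rec["class"],
                "well_score": agg.score,
                "n_cells": agg.n_cells,
            }
        )
        if emit_cells:
            for c in cells:
                cell_rows.append(
                    {
                        "plate": rec["plate"],
                        "row": rec["row"],
                        "col": rec["col"],
                        "cell_id": c.cell_id,
                        "nuclear_mean": c.nuclear_mean_intensity,
                        "ring_mean": c.ring_mean_intensity,
                        "ratio": c.ratio,
                        "n_pixels_nuc": c.n_pixels_nuc,
                        "n_pixels_ring": c.n_pixels_ring,
                        "flagged": c.flagged,
                    }
                )
    wells = pd.DataFrame.from_records(well_rows)
    if emit_cells:
        return wells, pd.DataFrame.from_records(cell_rows)
    return wells
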