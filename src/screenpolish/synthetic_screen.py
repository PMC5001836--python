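"""Synthetic screen generation with known ground truth.

Everything the downstream pipeline consumes can be generated here:
microscopy fields (nuclear-stain + reporter channel), 384-well plate maps
with control wells and planted hits, raw well-score matrices carrying
injected row/column positional effects, per-siRNA deconvolution scores,
and Ct tables for the qPCR filter.  All randomness flows from a single
integer seed through a documented stream-splitting scheme, so regeneration
is bit-reproducible.
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "ScreenDesign",
    "FieldGroundTruth",
    "PlacementError",
    "plate_map",
    "generate_field",
    "generate_plate_scores",
    "generate_secondary_wells",
    "generate_ct_table",
    "write_field_images",
    "well_name",
]

# RNG stream ids: every operation draws from default_rng([seed, stream, index])
# so distinct operations (and distinct plates) never share a stream.
_STREAM_FIELD = 1
_STREAM_PLATE = 2
_STREAM_SECONDARY = 3
_STREAM_CT = 4

NEGATIVE_CONTROL = "negative_control"
POSITIVE_CONTROL = "positive_control"
SAMPLE = "sample"


class PlacementError(RuntimeError):
    """Raised when cells cannot be placed without overlap at the requested density."""


def _rng(seed: int, stream: int, index: int = 0) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream), int(index)])


def well_name(row: int, col: int) -> str:
    """Render 0-based (row, col) as a plate coordinate, e.g. (0, 0) -> 'A01'."""
    letters = string.ascii_uppercase
    if row >= len(letters):
        raise ValueError(f"row {row} exceeds the A-Z row naming range")
    return f"{letters[row]}{col + 1:02d}"


@dataclass(frozen=True)
class ScreenDesign:
    """Parameters of a synthetic multi-plate screen.

    ``planted_hits`` maps gene ids (as emitted by :func:`plate_map`) to a
    translocation shift in well-score units; hits reduce the score, so
    shifts are typically negative.  ``positional_gradient`` is
    (row_slope, col_slope) in score units per well index.
    """

    n_plates: int
    plate_shape: tuple[int, int] = (16, 24)
    n_control_wells_per_class: int = 12
    planted_hits: Mapping[str, float] = field(default_factory=dict)
    positional_gradient: tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.05
    seed: int = 0
    baseline_ratio: float = 2.0
    negative_control_shift: float = 0.0
    positive_control_shift: float = -1.2
    negative_control_sd: float | None = None
    positive_control_sd: float | None = None

    def __post_init__(self) -> None:
        rows, cols = self.plate_shape
        if self.n_plates < 1:
            raise ValueError("n_plates must be >= 1")
        if rows < 2 or cols < 2:
            raise ValueError("plate_shape must be at least 2 x 2")
        n_ctrl = self.n_control_wells_per_class
        if n_ctrl < 0:
            raise ValueError("n_control_wells_per_class must be >= 0")
        n_ctrl_cols = math.ceil(n_ctrl / rows) if n_ctrl else 0
        if 2 * n_ctrl_cols >= cols:
            raise ValueError("control wells would leave no sample columns")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for sd in (self.negative_control_sd, self.positive_control_sd):
            if sd is not None and sd < 0:
                raise ValueError("control sd must be >= 0")

    def validate_hits(self) -> None:
        """Check that every planted hit names a gene present in some plate map."""
        known: set[str] = set()
        for p in range(self.n_plates):
            known.update(plate_map(self, p)["gene_id"])
        missing = set(self.planted_hits) - known
        if missing:
            raise ValueError(
                f"planted hits reference unknown gene ids: {sorted(missing)}"
            )


def plate_map(design: ScreenDesign, plate_index: int) -> pd.DataFrame:
    """Deterministic plate layout: controls in fixed edge columns, samples elsewhere.

    Negative controls fill columns from the left edge, positive controls from
    the right edge, ``n_control_wells_per_class`` wells each.  Sample wells get
    gene ids ``G{plate:02d}_{serial:04d}`` unique across the screen.
    """
    if not 0 <= plate_index < design.n_plates:
        raise ValueError(f"plate_index {plate_index} out of range [0, {design.n_plates})")
    rows, cols = design.plate_shape
    neg_wells: set[tuple[int, int]] = set()
    pos_wells: set[tuple[int, int]] = set()
    remaining = design.n_control_wells_per_class
    c = 0
    while remaining > 0:
        for r in range(rows):
            if remaining == 0:
                break
            neg_wells.add((r, c))
            remaining -= 1
        c += 1
    remaining = design.n_control_wells_per_class
    c = cols - 1
    while remaining > 0:
        for r in range(rows):
            if remaining == 0:
                break
            pos_wells.add((r, c))
            remaining -= 1
        c -= 1

    records = []
    serial = 0
    for r in range(rows):
        for c in range(cols):
            if (r, c) in neg_wells:
                cls, gene, sirna = NEGATIVE_CONTROL, "none", "none"
            elif (r, c) in pos_wells:
                cls, gene, sirna = POSITIVE_CONTROL, "VCP", "si_VCP"
            else:
                serial += 1
                cls = SAMPLE
                gene = f"G{plate_index + 1:02d}_{serial:04d}"
                sirna = f"pool_{gene}"
            records.append(
                {
                    "plate": plate_index,
                    "row": r,
                    "col": c,
                    "well": well_name(r, c),
                    "gene_id": gene,
                    "sirna_id": sirna,
                    "class": cls,
                }
            )
    return pd.DataFrame.from_records(records)


@dataclass(frozen=True)
class FieldGroundTruth:
    """Per-cell ground truth for one synthetic field."""

    cell_centers: np.ndarray          # (n, 2) float, (row, col) pixel coordinates
    nuclear_radius_px: np.ndarray     # (n,) float
    cyto_outer_radius_px: np.ndarray  # (n,) float
    true_ratio: np.ndarray            # (n,) float, nucleus:ring reporter ratio
    background_level: float

    @property
    def n_cells(self) -> int:
        return len(self.true_ratio)

    def nuclear_mask(self, index: int, shape: tuple[int, int]) -> np.ndarray:
        cy, cx = self.cell_centers[index]
        return _disk_mask(shape, cy, cx, self.nuclear_radius_px[index])

    def ring_mask(
        self,
        index: int,
        shape: tuple[int, int],
        ring_width_px: int = 3,
        gap_px: int = 0,
    ) -> np.ndarray:
        cy, cx = self.cell_centers[index]
        r = self.nuclear_radius_px[index]
        outer = _disk_mask(shape, cy, cx, r + gap_px + ring_width_px)
        inner = _disk_mask(shape, cy, cx, r + gap_px)
        return outer & ~inner


def _disk_mask(shape: tuple[int, int], cy: float, cx: float, radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2


def generate_field(
    n_cells: int,
    ratio_mean: float,
    ratio_sd: float,
    image_size: int = 512,
    seed: int = 0,
    *,
    nuclear_radius_px: int = 8,
    cyto_outer_radius_px: int = 14,
    nuclear_level: float = 1000.0,
    reporter_ring_level: float = 200.0,
    background_level: float = 100.0,
    reporter_background_level: float = 0.0,
    noise_sd: float = 0.0,
    max_attempts: int | None = None,
) -> tuple[np.ndarray, np.ndarray, FieldGroundTruth]:
    """Render one two-channel field of non-overlapping synthetic cells.

    Each cell is a bright nuclear disk in the nuclear channel; in the reporter
    channel the nucleus has intensity ``reporter_ring_level * true_ratio`` and
    the surrounding cytoplasm annulus has ``reporter_ring_level``, so the
    nuclear/ring mean-intensity ratio equals the cell's true ratio exactly in
    the noiseless case.  Returns float64 images plus the ground truth.
    """
    if n_cells < 0:
        raise ValueError("n_cells must be >= 0")
    if n_cells > 0 and ratio_mean <= 0:
        raise ValueError("ratio_mean must be > 0")
    if ratio_sd < 0:
        raise ValueError("ratio_sd must be >= 0")

    rng = _rng(seed, _STREAM_FIELD)
    shape = (image_size, image_size)
    nuclear = np.full(shape, float(background_level))
    reporter = np.full(shape, float(reporter_background_level))

    margin = cyto_outer_radius_px + 2
    min_sep = 2.0 * cyto_outer_radius_px  # invariant: strict > sum of outer radii
    if n_cells > 0 and image_size <= 2 * margin:
        raise PlacementError(
            f"image_size {image_size} too small for cell radius {cyto_outer_radius_px}"
        )

    centers: list[tuple[float, float]] = []
    attempts = 0
    limit = max_attempts if max_attempts is not None else max(2000, 500 * n_cells)
    while len(centers) < n_cells:
        if attempts >= limit:
            raise PlacementError(
                f"failed to place {n_cells} non-overlapping cells of outer radius "
                f"{cyto_outer_radius_px} px in a {image_size}x{image_size} field "
                f"after {attempts} attempts; reduce density"
            )
        attempts += 1
        cy, cx = rng.uniform(margin, image_size - margin, size=2)
        if all((cy - y) ** 2 + (cx - x) ** 2 > min_sep**2 for y, x in centers):
            centers.append((cy, cx))

    ratios = np.empty(n_cells)
    for i in range(n_cells):
        for _ in range(1000):
            r = rng.normal(ratio_mean, ratio_sd)
            if r > 0:
                ratios[i] = r
                break
        else:
            raise ValueError("could not draw a positive true_ratio; check ratio_mean/sd")

    for (cy, cx), ratio in zip(centers, ratios):
        nuc = _disk_mask(shape, cy, cx, nuclear_radius_px)
        cyto = _disk_mask(shape, cy, cx, cyto_outer_radius_px) & ~nuc
        nuclear[nuc] = background_level + nuclear_level
        reporter[nuc] = reporter_background_level + reporter_ring_level * ratio
        reporter[cyto] = reporter_background_level + reporter_ring_level

    if noise_sd > 0:
        nuclear = nuclear + rng.normal(0.0, noise_sd, shape)
        reporter = reporter + rng.normal(0.0, noise_sd, shape)

    gt = FieldGroundTruth(
        cell_centers=np.array(centers, dtype=float).reshape(n_cells, 2),
        nuclear_radius_px=np.full(n_cells, float(nuclear_radius_px)),
        cyto_outer_radius_px=np.full(n_cells, float(cyto_outer_radius_px)),
        true_ratio=ratios,
        background_level=float(background_level),
    )
    return nuclear, reporter, gt


def generate_plate_scores(
    design: ScreenDesign, plate_index: int
) -> tuple[np.ndarray, pd.DataFrame]:
    """Raw well-score matrix for one plate plus its annotated plate map.

    The score of well (r, c) is the sum of retrievable components:
    baseline + row_slope*r + col_slope*c + hit shift + control shift + noise.
    The returned frame carries each component in ``component_*`` columns so
    the additive decomposition can be asserted exactly.
    """
    pm = plate_map(design, plate_index)
    rows, cols = design.plate_shape
    row_slope, col_slope = design.positional_gradient
    rng = _rng(design.seed, _STREAM_PLATE, plate_index)

    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    row_comp = row_slope * rr.astype(float)
    col_comp = col_slope * cc.astype(float)

    hit_comp = np.zeros((rows, cols))
    ctrl_comp = np.zeros((rows, cols))
    sd = np.full((rows, cols), design.noise_sd)
    neg_sd = design.negative_control_sd
    pos_sd = design.positive_control_sd
    for rec in pm.to_dict("records"):
        r, c = rec["row"], rec["col"]
        if rec["gene_id"] in design.planted_hits and rec["class"] == SAMPLE:
            hit_comp[r, c] = design.planted_hits[rec["gene_id"]]
        if rec["class"] == NEGATIVE_CONTROL:
            ctrl_comp[r, c] = design.negative_control_shift
            if neg_sd is not None:
                sd[r, c] = neg_sd
        elif rec["class"] == POSITIVE_CONTROL:
            ctrl_comp[r, c] = design.positive_control_shift
            if pos_sd is not None:
                sd[r, c] = pos_sd

    # One standard-normal draw per well scaled by the per-well sd, so the
    # noise realization is identical across designs that differ only in
    # deterministic components (paired gradient/no-gradient simulations).
    noise = rng.standard_normal((rows, cols)) * sd

    scores = design.baseline_ratio + row_comp + col_comp + hit_comp + ctrl_comp + noise

    idx = (pm["row"].to_numpy(), pm["col"].to_numpy())
    pm = pm.assign(
        component_baseline=design.baseline_ratio,
        component_row=row_comp[idx],
        component_col=col_comp[idx],
        component_hit=hit_comp[idx],
        component_control=ctrl_comp[idx],
        component_noise=noise[idx],
        raw=scores[idx],
    )
    return scores, pm


def generate_secondary_wells(
    genes: Sequence[str],
    n_active_sirnas: Mapping[str, int],
    seed: int,
    *,
    cell_lines: Sequence[str] = ("HEK293A", "HT1080"),
    n_sirnas: int = 4,
    inactive_score_mean: float = 2.0,
    active_score_mean: float = 1.0,
    noise_sd: float = 0.05,
) -> pd.DataFrame:
    """Per-siRNA deconvolution scores: 4 individual siRNAs per gene per cell line.

    ``n_active_sirnas[gene]`` of the 4 siRNAs reproduce the knockdown phenotype
    (low score near ``active_score_mean``); the rest score like untreated wells.
    """
    rng = _rng(seed, _STREAM_SECONDARY)
    rows = []
    for gene in genes:
        n_active = int(n_active_sirnas.get(gene, 0))
        if not 0 <= n_active <= n_sirnas:
            raise ValueError(f"n_active_sirnas[{gene}]={n_active} outside [0, {n_sirnas}]")
        for cell_line in cell_lines:
            for k in range(n_sirnas):
                mean = active_score_mean if k < n_active else inactive_score_mean
                rows.append(
                    {
                        "gene_id": gene,
                        "sirna_id": f"{gene}_si{k + 1}",
                        "cell_line": cell_line,
                        "score": mean + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame.from_records(rows)


def generate_ct_table(
    genes: Sequence[str],
    attenuation: Mapping[str, float],
    seed: int,
    *,
    base_induction: float = 4.0,
    n_replicates: int = 3,
    noise_sd: float = 0.0,
    reference_ct: float = 25.0,
    target_baseline_ct: float = 28.0,
    min_fold: float = 2.0**-12,
) -> pd.DataFrame:
    """Ct table (target PSMA3-like, reference GUSB-like) for the qPCR filter.

    Constructed so the fold induction recovered by the standard relative
    quantification (delta-delta-Ct, efficiency 2) equals
    ``base_induction * attenuation[gene]`` up to replicate noise.
    attenuation 1 = full bounce-back, 0 = fully blocked (fold clamped to
    ``min_fold`` to keep Ct values finite).
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = _rng(seed, _STREAM_CT)
    rows = []
    for gene in genes:
        att = float(attenuation[gene])
        if not 0.0 <= att <= 1.0:
            raise ValueError(f"attenuation[{gene}]={att} outside [0, 1]")
        induced_fold = max(base_induction * att, min_fold)
        for condition, fold in (("minus_inhibitor", 1.0), ("plus_inhibitor", induced_fold)):
            for rep in range(1, n_replicates + 1):
                rows.append(
                    {
                        "gene_id": gene,
                        "condition": condition,
                        "replicate": rep,
                        "ct_target": target_baseline_ct
                        - math.log2(fold)
                        + rng.normal(0.0, noise_sd),
                        "ct_reference": reference_ct + rng.normal(0.0, noise_sd),
                    }
                )
    return pd.DataFrame.from_records(rows)


def write_field_images(
    out_dir: str | Path,
    plate: int,
    row: int,
    col: int,
    field_index: int,
    nuclear: np.ndarray,
    reporter: np.ndarray,
) -> dict[str, Path]:
    """Write one field as two 16-bit single-channel TIFFs.

    Layout: ``plate_{p}/well_{A01}/field_{k}_{channel}.tif``.  Float images
    are clipped to [0, 65535] and rounded.
    """
    well_dir = Path(out_dir) / f"plate_{plate}" / f"well_{well_name(row, col)}"
    well_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for channel, img in (("nuclear", nuclear), ("reporter", reporter)):
        arr = np.clip(np.rint(img), 0, np.iinfo(np.uint16).max).astype(np.uint16)
        path = well_dir / f"field_{field_index}_{channel}.tif"
        tifffile.imwrite(path, arr)
        paths[channel] = path
    return paths
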