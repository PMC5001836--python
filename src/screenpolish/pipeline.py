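"""End-to-end driver: simulate -> quantify -> normalize -> hits.

Each stage reads/writes documented CSV schemas in a working directory and
the run leaves a JSON manifest (inputs, outputs, config hash, seed,
versions).  Deterministic stages are bit-identical under rerun with the
same config.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .io import read_table, write_table
from .synthetic_screen import (
    NEGATIVE_CONTROL,
    POSITIVE_CONTROL,
    SAMPLE,
    ScreenDesign,
    generate_ct_table,
    generate_field,
    generate_plate_scores,
    generate_secondary_wells,
    write_field_images,
)
from .image_quant import quantify_images
from .plate_stats import b_score_from_values, median_polish, z_prime
from .hit_selection import (
    assemble_hit_table,
    call_primary,
    call_secondary,
    call_tertiary,
    ddct_fold_change,
)

__all__ = [
    "STAGES",
    "design_from_config",
    "parse_stage_range",
    "simulate",
    "quantify",
    "normalize",
    "hits",
    "run_pipeline",
]

logger = logging.getLogger(__name__)

STAGES = ("simulate", "quantify", "normalize", "hits")

CONTROL_GENE = "NTC"  # non-targeting control row in the qPCR table


def design_from_config(config: PipelineConfig) -> ScreenDesign:
    hits_map = dict(config.planted_hits)
    hits_map.update(config.decoy_hits)
    return ScreenDesign(
        n_plates=config.n_plates,
        plate_shape=config.plate_shape,
        n_control_wells_per_class=config.n_control_wells_per_class,
        planted_hits=hits_map,
        positional_gradient=(config.row_slope, config.col_slope),
        noise_sd=config.noise_sd,
        seed=config.seed,
        baseline_ratio=config.baseline_ratio,
        positive_control_shift=config.positive_control_shift,
        negative_control_sd=config.negative_control_sd,
        positive_control_sd=config.positive_control_sd,
    )


def parse_stage_range(spec: str) -> list[str]:
    """Parse 'normalize:hits' (inclusive range) or a single stage name."""
    if ":" in spec:
        first, last = spec.split(":", 1)
    else:
        first = last = spec
    for name in (first, last):
        if name not in STAGES:
            raise ValueError(f"unknown stage {name!r}; stages are {STAGES}")
    i, j = STAGES.index(first), STAGES.index(last)
    if i > j:
        raise ValueError(f"stage range {spec!r} is reversed")
    return list(STAGES[i : j + 1])


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"stage {stage!r}: missing input file {path}")
    return path


def _require_columns(df: pd.DataFrame, cols: set[str], what: str) -> None:
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"{what}: missing column(s) {sorted(missing)}")


def simulate(config: PipelineConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate wells.csv, secondary_wells.csv, and qpcr.csv from the config.

    Well scores are simulated at plate level (no images); planted hits and
    decoys both shift the pooled score, but differ in ground truth: hits
    have ``hit_active_sirnas`` active individual siRNAs and attenuate the
    qPCR bounce-back to ``hit_attenuation``, decoys do not.
    """
    outdir = Path(outdir)
    design = design_from_config(config)
    design.validate_hits()
    chash = config.config_hash()

    frames = []
    for p in range(config.n_plates):
        _, pm = generate_plate_scores(design, p)
        frames.append(pm)
    wells = pd.concat(frames, ignore_index=True)
    wells = wells.rename(columns={"raw": "well_score"})
    wells["n_cells"] = np.nan  # score-level simulation carries no cell counts
    cols = ["plate", "row", "col", "well", "gene_id", "sirna_id", "class", "well_score",
            "component_baseline", "component_row", "component_col", "component_hit",
            "component_control", "component_noise", "n_cells"]
    paths = {"wells": write_table(wells[cols], outdir / "wells.csv", chash, config.seed)}

    followup_genes = list(config.planted_hits) + list(config.decoy_hits)
    n_active = {g: config.hit_active_sirnas for g in config.planted_hits}
    n_active.update({g: config.decoy_active_sirnas for g in config.decoy_hits})
    secondary = generate_secondary_wells(
        followup_genes,
        n_active,
        seed=config.seed,
        cell_lines=config.secondary_cell_lines,
        inactive_score_mean=config.baseline_ratio,
        active_score_mean=config.baseline_ratio + config.positive_control_shift,
        noise_sd=config.secondary_noise_sd,
    )
    paths["secondary"] = write_table(
        secondary, outdir / "secondary_wells.csv", chash, config.seed
    )

    attenuation = {g: config.hit_attenuation for g in config.planted_hits}
    attenuation.update({g: config.decoy_attenuation for g in config.decoy_hits})
    attenuation[CONTROL_GENE] = 1.0
    qpcr = generate_ct_table(
        [CONTROL_GENE] + followup_genes,
        attenuation,
        seed=config.seed,
        base_induction=config.base_induction,
        n_replicates=config.qpcr_replicates,
        noise_sd=config.qpcr_noise_sd,
    )
    paths["qpcr"] = write_table(qpcr, outdir / "qpcr.csv", chash, config.seed)
    return paths


def simulate_well_images(
    config: PipelineConfig,
    images_dir: str | Path,
    wells: pd.DataFrame,
    n_cells: int = 30,
    image_size: int = 512,
    ratio_sd: float = 0.0,
) -> None:
    """Render one image field per well of the given wells table.

    Each field's mean true ratio equals the well's simulated score, so
    quantifying the images approximately reproduces wells.csv.
    """
    for i, rec in enumerate(wells.itertuples(index=False)):
        nuclear, reporter, _ = generate_field(
            n_cells,
            float(rec.well_score),
            ratio_sd,
            image_size=image_size,
            seed=config.seed * 1_000_003 + i,
        )
        write_field_images(images_dir, rec.plate, rec.row, rec.col, 0, nuclear, reporter)


def quantify(
    config: PipelineConfig,
    images_dir: str | Path,
    platemap: pd.DataFrame,
    outdir: str | Path,
) -> dict[str, Path]:
    """Quantify TIFF images into wells.csv."""
    images_dir = Path(images_dir)
    if not images_dir.is_dir():
        raise FileNotFoundError(f"stage 'quantify': missing images directory {images_dir}")
    _require_columns(
        platemap, {"plate", "row", "col", "gene_id", "sirna_id", "class"}, "plate map"
    )
    wells = quantify_images(
        images_dir,
        platemap,
        threshold_method=config.threshold_method,
        min_area_px=config.min_area_px,
        erosion_px=config.erosion_px,
        ring_width_px=config.ring_width_px,
        gap_px=config.gap_px,
        min_cells=config.min_cells,
        aggregation=config.aggregation,
        metric=config.roi_metric,
    )
    out = write_table(wells, Path(outdir) / "wells.csv", config.config_hash(), config.seed)
    return {"wells": out}


def normalize(config: PipelineConfig, wells: pd.DataFrame, outdir: str | Path) -> dict[str, Path]:
    """Per-plate positional-effect removal, B scores, and Z'-factor QC.

    Writes bscores.csv (plate,row,col,gene_id,sirna_id,class,raw,residual,
    b_score) and zprime.csv (one row per plate).
    """
    _require_columns(
        wells, {"plate", "row", "col", "gene_id", "sirna_id", "class", "well_score"}, "wells table"
    )
    chash = config.config_hash()
    b_frames = []
    z_rows = []
    for plate, pdf in wells.groupby("plate", sort=True):
        rows = int(pdf["row"].max()) + 1
        cols = int(pdf["col"].max()) + 1
        mat = np.full((rows, cols), np.nan)
        sample_mask = np.zeros((rows, cols), dtype=bool)
        mat[pdf["row"], pdf["col"]] = pdf["well_score"]
        sample_mask[pdf.loc[pdf["class"] == SAMPLE, "row"], pdf.loc[pdf["class"] == SAMPLE, "col"]] = True

        if config.xi_source == "residual":
            fit = median_polish(mat)
            values = fit.residuals
        else:
            values = mat
        bmat = b_score_from_values(values, sample_mask, mad_scale=config.mad_scale)

        out = pdf.copy()
        out = out.rename(columns={"well_score": "raw"})
        out["residual"] = values[out["row"], out["col"]]
        out["b_score"] = bmat.b_scores[out["row"], out["col"]]
        b_frames.append(
            out[["plate", "row", "col", "well", "gene_id", "sirna_id", "class",
                 "raw", "residual", "b_score"]]
            if "well" in out.columns
            else out[["plate", "row", "col", "gene_id", "sirna_id", "class",
                      "raw", "residual", "b_score"]]
        )

        neg = pdf.loc[pdf["class"] == NEGATIVE_CONTROL, "well_score"].to_numpy()
        pos = pdf.loc[pdf["class"] == POSITIVE_CONTROL, "well_score"].to_numpy()
        if len(neg) >= 2 and len(pos) >= 2:
            rep = z_prime(neg, pos, plate=plate)
            z_rows.append(
                {
                    "plate": plate,
                    "mean_neg": rep.mean_neg,
                    "sd_neg": rep.sd_neg,
                    "mean_pos": rep.mean_pos,
                    "sd_pos": rep.sd_pos,
                    "n_neg": rep.n_neg,
                    "n_pos": rep.n_pos,
                    "z_prime": rep.z_prime,
                    "defined": rep.defined,
                }
            )
        else:
            logger.warning("plate %s: not enough control wells for Z'", plate)

    outdir = Path(outdir)
    paths = {
        "bscores": write_table(
            pd.concat(b_frames, ignore_index=True), outdir / "bscores.csv", chash, config.seed
        ),
        "zprime": write_table(
            pd.DataFrame.from_records(z_rows), outdir / "zprime.csv", chash, config.seed
        ),
    }
    return paths


def hits(
    config: PipelineConfig,
    bscores: pd.DataFrame,
    secondary: pd.DataFrame,
    qpcr: pd.DataFrame,
    outdir: str | Path,
    zprime: pd.DataFrame | None = None,
    overrides: list[str] | None = None,
    secondary_threshold: float | None = None,
) -> dict[str, Path]:
    """Run the three-stage funnel and write hits.tsv.

    The per-siRNA confirmation threshold defaults to the midpoint between
    the plate control means (taken from zprime.csv when available, else
    from the configured control levels).
    """
    _require_columns(bscores, {"gene_id", "class", "b_score"}, "bscores table")
    sample = bscores[bscores["class"] == SAMPLE]
    per_gene = sample.groupby("gene_id")["b_score"].min().to_dict()
    primary = call_primary(per_gene, cutoff=config.primary_cutoff, overrides=overrides or [])
    primary_hits = {c.gene_id for c in primary if c.is_hit}

    if secondary_threshold is None:
        if zprime is not None and len(zprime):
            secondary_threshold = float(
                ((zprime["mean_neg"] + zprime["mean_pos"]) / 2.0).mean()
            )
        else:
            secondary_threshold = config.baseline_ratio + config.positive_control_shift / 2.0
    thresholds = {line: secondary_threshold for line in config.secondary_cell_lines}

    _require_columns(secondary, {"gene_id", "sirna_id", "cell_line", "score"}, "secondary table")
    secondary_in = secondary[secondary["gene_id"].isin(primary_hits)]
    deconv = call_secondary(
        secondary_in,
        thresholds,
        min_hits=config.secondary_min_hits,
        cell_lines=config.secondary_cell_lines,
    )
    secondary_passes = {r.gene_id for r in deconv if r.passes}

    _require_columns(qpcr, {"gene_id", "condition", "ct_target", "ct_reference"}, "qPCR table")
    control_rows = qpcr[qpcr["gene_id"] == CONTROL_GENE]
    if control_rows.empty:
        raise ValueError(
            f"qPCR table lacks the non-targeting control gene {CONTROL_GENE!r} "
            "needed for the reference fold induction"
        )
    fold_control = ddct_fold_change(control_rows)
    tertiary = []
    for gene in sorted(secondary_passes):
        rows = qpcr[qpcr["gene_id"] == gene]
        if rows.empty:
            logger.warning("gene %s has no qPCR data; failing tertiary stage", gene)
            continue
        tertiary.append(
            call_tertiary(
                gene, fold_control, ddct_fold_change(rows), max_ratio=config.tertiary_max_ratio
            )
        )

    table = assemble_hit_table(primary, deconv, tertiary, cell_lines=config.secondary_cell_lines)
    out = write_table(
        table, Path(outdir) / "hits.tsv", config.config_hash(), config.seed, sep="\t"
    )
    return {"hits": out}


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages: str = "simulate:hits",
    images_dir: str | Path | None = None,
    platemap_path: str | Path | None = None,
) -> dict:
    """Execute the requested stage range and write a run manifest.

    ``quantify`` runs only when an images directory is supplied; otherwise
    wells.csv is expected from the simulate stage or a previous run.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    selected = parse_stage_range(stages)
    artifacts: dict[str, str] = {}
    inputs: dict[str, str] = {}

    for stage in selected:
        if stage == "simulate":
            for name, path in simulate(config, outdir).items():
                artifacts[name] = str(path)
        elif stage == "quantify":
            if images_dir is None:
                logger.info("no images directory supplied; skipping quantify stage")
                continue
            pm_path = _require(Path(platemap_path or outdir / "platemap.csv"), "quantify")
            inputs["platemap"] = str(pm_path)
            for name, path in quantify(config, images_dir, read_table(pm_path), outdir).items():
                artifacts[name] = str(path)
        elif stage == "normalize":
            wells_path = Path(artifacts.get("wells", outdir / "wells.csv"))
            _require(wells_path, "normalize")
            inputs["wells"] = str(wells_path)
            for name, path in normalize(config, read_table(wells_path), outdir).items():
                artifacts[name] = str(path)
        elif stage == "hits":
            b_path = _require(Path(artifacts.get("bscores", outdir / "bscores.csv")), "hits")
            s_path = _require(Path(artifacts.get("secondary", outdir / "secondary_wells.csv")), "hits")
            q_path = _require(Path(artifacts.get("qpcr", outdir / "qpcr.csv")), "hits")
            z_path = Path(artifacts.get("zprime", outdir / "zprime.csv"))
            zp = read_table(z_path) if z_path.exists() else None
            inputs.update({"bscores": str(b_path), "secondary": str(s_path), "qpcr": str(q_path)})
            for name, path in hits(
                config, read_table(b_path), read_table(s_path), read_table(q_path), outdir, zprime=zp
            ).items():
                artifacts[name] = str(path)

    manifest = {
        "package": "screenpolish",
        "version": __version__,
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "stages": selected,
        "seed": config.seed,
        "config_sha256": config.config_hash(),
        "config": config.to_dict(),
        "inputs": inputs,
        "outputs": artifacts,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
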