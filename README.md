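# screenpolish

Analysis pipeline for image-based RNAi screens that read out a
nuclear-translocation phenotype:

- **synthetic_screen** — generates every input with known ground truth:
  two-channel microscopy fields (nuclear stain + reporter), 384-well plate
  maps with negative/positive control wells and planted hit genes, raw
  well-score matrices with injectable row/column positional gradients,
  per-siRNA deconvolution scores, and Ct tables for the qPCR filter.
- **image_quant** — Otsu nuclear segmentation, ROI construction (nuclear
  mask eroded 2 px; 3-px-wide perinuclear ring with an optional 1-px gap),
  per-cell nucleus:ring intensity ratios, and per-well aggregation.
- **plate_stats** — two-way median polish to remove positional effects,
  B scores (residuals standardized by the plate's sample-well median and
  MAD, default normal-consistency scale 1.4826), and Z′-factor QC from
  control wells.
- **hit_selection** — the three-stage funnel: primary B-score cutoff
  (default −3.2, strict, with a manual-rescue override channel), secondary
  4-siRNA deconvolution in two cell lines (default ≥2 confirming siRNAs in
  either line), tertiary ΔΔCt attenuation of the proteasome-gene
  bounce-back response (default knockdown/control fold ratio < 0.7).
- **pipeline / cli** — orchestration with provenance-stamped CSV/TSV
  artifacts and a JSON run manifest; reruns are bit-identical.

## CLI

All commands are subcommands of `screenpolish`:

```sh
# full synthetic run: simulate -> normalize -> hits
screenpolish run --config config.yaml --out runs/demo

# individual stages
screenpolish simulate  --config config.yaml --out work/
screenpolish quantify  --images images/ --platemap platemap.csv \
    --gap-px 0 --erosion-px 2 --ring-width-px 3 --min-cells 20 --out work/
screenpolish normalize --wells work/wells.csv --mad-scale 1.4826 --out work/
screenpolish hits --bscores work/bscores.csv --secondary work/secondary_wells.csv \
    --qpcr work/qpcr.csv --cutoff -3.2 --min-hits 2 --max-ratio 0.7 --out work/
```

A minimal `config.yaml` needs only a `seed`; every threshold and geometry
parameter (`erosion_px`, `gap_px`, `mad_scale`, `primary_cutoff`,
`secondary_min_hits`, `tertiary_max_ratio`, plate shape, planted hits, ...)
can be overridden. Unknown keys are rejected. Images are exchanged as
single-channel 16-bit TIFFs laid out as
`plate_{p}/well_{A01}/field_{k}_{channel}.tif`; tables are CSV/TSV with a
`#`-prefixed provenance header (package version, config hash, seed).

## Data model

Plate coordinates are rows A–P × columns 1–24 (0-based internally). Raw
well score = median of per-cell nucleus:ring reporter intensity ratios
(wells with fewer than `min_cells` usable cells are missing). Per plate,
scores decompose as grand + row + column effects + residual via median
polish; `B = (residual − Median) / (1.4826 · MAD)` with Median/MAD over
sample wells only. `Z′ = 1 − 3(sd_neg + sd_pos)/|mean_neg − mean_pos|`.

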