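"""Three-stage hit funnel.

Primary: B-score cutoff (with a manual-rescue override channel).
Secondary: deconvolution of the 4-siRNA pool in two cell lines.
Tertiary: qPCR attenuation of the proteasome-gene bounce-back response.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PrimaryCall",
    "DeconvolutionResult",
    "TertiaryCall",
    "StageOrderError",
    "call_primary",
    "call_secondary",
    "ddct_fold_change",
    "call_tertiary",
    "assemble_hit_table",
]

logger = logging.getLogger(__name__)

DEFAULT_PRIMARY_CUTOFF = -3.2
DEFAULT_SECONDARY_MIN_HITS = 2
DEFAULT_TERTIARY_MAX_RATIO = 0.7


class StageOrderError(ValueError):
    """Raised when a later stage contains genes that did not pass the earlier one."""


@dataclass
class PrimaryCall:
    gene_id: str
    b_score: float
    is_hit: bool
    rescued_by_inspection: bool = False


@dataclass
class DeconvolutionResult:
    gene_id: str
    scores: dict            # cell_line -> {sirna_id: score}
    hit_counts: dict        # cell_line -> confirming-siRNA count
    passes: bool


@dataclass
class TertiaryCall:
    gene_id: str
    fold_induction_control: float
    fold_induction_knockdown: float
    attenuation_ratio: float
    passes: bool


def call_primary(
    b_scores: Mapping[str, float],
    cutoff: float = DEFAULT_PRIMARY_CUTOFF,
    overrides: Iterable[str] = (),
) -> list[PrimaryCall]:
    """Call primary hits: strictly below the cutoff, or rescued by override.

    Returns every gene, ordered by ascending B score; ``overrides`` models
    genes rescued by visual inspection regardless of score.
    """
    overrides = set(overrides)
    unknown = overrides - set(b_scores)
    if unknown:
        raise ValueError(f"override genes not in the screen: {sorted(unknown)}")
    calls = []
    for gene, score in b_scores.items():
        rescued = gene in overrides
        below = np.isfinite(score) and score < cutoff
        calls.append(
            PrimaryCall(
                gene_id=gene,
                b_score=float(score),
                is_hit=bool(below or rescued),
                rescued_by_inspection=rescued,
            )
        )
    calls.sort(key=lambda c: (not np.isfinite(c.b_score), c.b_score))
    return calls


def call_secondary(
    scores: pd.DataFrame,
    thresholds: Mapping[str, float],
    min_hits: int = DEFAULT_SECONDARY_MIN_HITS,
    cell_lines: Sequence[str] | None = None,
    n_sirnas: int = 4,
) -> list[DeconvolutionResult]:
    """Deconvolution calls from a long table (gene_id, sirna_id, cell_line, score).

    An individual siRNA confirms when its score falls strictly below the
    cell line's threshold; missing siRNAs count as non-confirming.  A gene
    passes when its confirming count in at least one cell line reaches
    ``min_hits``.  A gene absent from a cell line gets count 0 there (with a
    logged warning).
    """
    required = {"gene_id", "sirna_id", "cell_line", "score"}
    missing_cols = required - set(scores.columns)
    if missing_cols:
        raise ValueError(f"secondary table missing columns: {sorted(missing_cols)}")
    if cell_lines is None:
        cell_lines = sorted(scores["cell_line"].unique())
    unknown_lines = set(scores["cell_line"].unique()) - set(cell_lines)
    if unknown_lines:
        raise ValueError(f"no threshold provided for cell lines: {sorted(unknown_lines)}")

    results = []
    for gene, gdf in scores.groupby("gene_id", sort=True):
        per_line_scores: dict[str, dict[str, float]] = {}
        hit_counts: dict[str, int] = {}
        for line in cell_lines:
            ldf = gdf[gdf["cell_line"] == line]
            if ldf.empty:
                logger.warning("gene %s absent from cell line %s; count = 0", gene, line)
                per_line_scores[line] = {}
                hit_counts[line] = 0
                continue
            if len(ldf) > n_sirnas:
                raise ValueError(
                    f"gene {gene} has {len(ldf)} siRNA measurements in {line}; "
                    f"expected at most {n_sirnas}"
                )
            vals = dict(zip(ldf["sirna_id"], ldf["score"].astype(float)))
            per_line_scores[line] = vals
            hit_counts[line] = sum(
                1 for v in vals.values() if np.isfinite(v) and v < thresholds[line]
            )
        results.append(
            DeconvolutionResult(
                gene_id=str(gene),
                scores=per_line_scores,
                hit_counts=hit_counts,
                passes=max(hit_counts.values(), default=0) >= min_hits,
            )
        )
    return results


def ddct_fold_change(qpcr: pd.DataFrame) -> float:
    """Fold induction of the target gene by the inhibitor, via delta-delta-Ct.

    Input: rows for one knockdown condition with columns
    (condition in {minus_inhibitor, plus_inhibitor}, replicate, ct_target,
    ct_reference).  Per replicate dCt = ct_target - ct_reference; then
    ddCt = mean dCt(plus) - mean dCt(minus) and fold = 2**(-ddCt), i.e.
    amplification efficiency exactly 2.
    """
    required = {"condition", "ct_target", "ct_reference"}
    missing = required - set(qpcr.columns)
    if missing:
        raise ValueError(f"qPCR table missing columns: {sorted(missing)}")
    if qpcr[["ct_target", "ct_reference"]].isna().any().any():
        bad = qpcr[qpcr[["ct_target", "ct_reference"]].isna().any(axis=1)]
        raise ValueError(
            f"missing Ct values for condition(s) {sorted(bad['condition'].unique())}"
        )
    means = {}
    for condition in ("minus_inhibitor", "plus_inhibitor"):
        sub = qpcr[qpcr["condition"] == condition]
        if sub.empty:
            raise ValueError(f"qPCR table has no rows for condition {condition!r}")
        dct = sub["ct_target"].astype(float) - sub["ct_reference"].astype(float)
        means[condition] = float(dct.mean())
    ddct = means["plus_inhibitor"] - means["minus_inhibitor"]
    return float(2.0 ** (-ddct))


def call_tertiary(
    gene_id: str,
    fold_control: float,
    fold_knockdown: float,
    max_ratio: float = DEFAULT_TERTIARY_MAX_RATIO,
) -> TertiaryCall:
    """Pass when the knockdown attenuates induction: knockdown/control < max_ratio."""
    if not fold_control > 0:
        raise ValueError("fold_control must be > 0")
    ratio = fold_knockdown / fold_control
    return TertiaryCall(
        gene_id=gene_id,
        fold_induction_control=float(fold_control),
        fold_induction_knockdown=float(fold_knockdown),
        attenuation_ratio=float(ratio),
        passes=bool(ratio < max_ratio),
    )


def assemble_hit_table(
    primary: Sequence[PrimaryCall],
    secondary: Sequence[DeconvolutionResult],
    tertiary: Sequence[TertiaryCall],
    cell_lines: Sequence[str] | None = None,
) -> pd.DataFrame:
    """One row per screened gene with every stage outcome and the final verdict.

    Enforces funnel order: each secondary gene must be a primary hit, each
    tertiary gene a secondary pass.  Final hits are the genes passing all
    three stages; ``reason`` records the first failed stage for the rest.
    """
    primary_by_gene = {c.gene_id: c for c in primary}
    secondary_by_gene = {r.gene_id: r for r in secondary}
    tertiary_by_gene = {t.gene_id: t for t in tertiary}

    primary_hits = {g for g, c in primary_by_gene.items() if c.is_hit}
    bad = set(secondary_by_gene) - primary_hits
    if bad:
        raise StageOrderError(
            f"secondary stage contains genes that are not primary hits: {sorted(bad)}"
        )
    secondary_passes = {g for g, r in secondary_by_gene.items() if r.passes}
    bad = set(tertiary_by_gene) - secondary_passes
    if bad:
        raise StageOrderError(
            f"tertiary stage contains genes that did not pass deconvolution: {sorted(bad)}"
        )

    if cell_lines is None:
        seen: list[str] = []
        for r in secondary:
            for line in r.hit_counts:
                if line not in seen:
                    seen.append(line)
        cell_lines = seen

    rows = []
    for call in primary:
        gene = call.gene_id
        sec = secondary_by_gene.get(gene)
        ter = tertiary_by_gene.get(gene)
        final = bool(call.is_hit and sec is not None and sec.passes and ter is not None and ter.passes)
        if not call.is_hit:
            reason = "failed_primary"
        elif sec is None or not sec.passes:
            reason = "failed_deconvolution"
        elif ter is None or not ter.passes:
            reason = "failed_qpcr_attenuation"
        else:
            reason = "final_hit"
        row = {
            "gene_id": gene,
            "b_score": call.b_score,
            "primary_hit": call.is_hit,
            "rescued_by_inspection": call.rescued_by_inspection,
        }
        for line in cell_lines:
            row[f"hits_{line}"] = sec.hit_counts.get(line, np.nan) if sec else np.nan
        row["secondary_pass"] = bool(sec.passes) if sec else False
        row["attenuation_ratio"] = ter.attenuation_ratio if ter else np.nan
        row["tertiary_pass"] = bool(ter.passes) if ter else False
        row["final_hit"] = final
        row["reason"] = reason
        rows.append(row)
    return pd.DataFrame.from_records(rows)
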