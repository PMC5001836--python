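"""Per-plate normalization and QC.

Two-way median polish removes positional (row/column) effects from a plate
matrix; the residuals are standardized by the plate's median and MAD to give
B scores; control wells yield a Z'-factor assay-window statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MedianPolishFit",
    "BScoreMatrix",
    "ZPrimeReport",
    "DegeneratePlateError",
    "median_polish",
    "b_score",
    "b_score_from_values",
    "z_prime",
    "MAD_NORMAL_CONSISTENCY",
]

# Scales the MAD to estimate the standard deviation under normality.
MAD_NORMAL_CONSISTENCY = 1.4826


class DegeneratePlateError(ValueError):
    """Raised when a plate's spread statistic is zero (constant residuals)."""


@dataclass
class MedianPolishFit:
    """Additive decomposition input = grand + row + col + residual."""

    grand_effect: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    residuals: np.ndarray       # NaN where the input was missing
    n_iterations: int
    converged: bool
    flagged_rows: list[int] = field(default_factory=list)  # all-missing rows
    flagged_cols: list[int] = field(default_factory=list)

    def fitted(self) -> np.ndarray:
        return (
            self.grand_effect
            + self.row_effects[:, None]
            + self.col_effects[None, :]
        )


@dataclass
class BScoreMatrix:
    b_scores: np.ndarray
    median_used: float
    mad_used: float           # unscaled MAD
    mad_scale: float
    wells_used: np.ndarray    # bool mask of sample wells entering Median/MAD


@dataclass
class ZPrimeReport:
    plate: int | str | None
    mean_neg: float
    sd_neg: float
    mean_pos: float
    sd_pos: float
    n_neg: int
    n_pos: int
    z_prime: float
    defined: bool


def _nanmedian_axis(x: np.ndarray, axis: int) -> np.ndarray:
    """Row/col medians ignoring NaN; all-NaN slices yield 0 (no adjustment)."""
    counts = np.sum(np.isfinite(x), axis=axis)
    out = np.zeros(x.shape[1 - axis])
    valid = counts > 0
    if valid.any():
        sub = x[valid, :] if axis == 1 else x[:, valid]
        out[valid] = np.nanmedian(sub, axis=axis)
    return out


def median_polish(
    x: np.ndarray, max_iter: int = 500, tol: float = 1e-8
) -> MedianPolishFit:
    """Tukey's two-way median polish with missing (NaN) wells.

    Alternates row and column median sweeps, folding the median of each
    effect vector into the grand effect, until the largest absolute change
    of any effect falls below ``tol`` or ``max_iter`` is reached.  Missing
    wells are ignored by every median and carry NaN residuals.  The final
    residuals are recomputed as input minus fitted so that the
    reconstruction identity grand + row + col + residual = input holds to
    machine precision for every non-missing well.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected a 2-D plate matrix")
    finite = np.isfinite(x)
    if np.sum(finite.any(axis=1)) < 2 or np.sum(finite.any(axis=0)) < 2:
        raise ValueError("need at least 2 rows and 2 columns with non-missing wells")

    n_rows, n_cols = x.shape
    grand = 0.0
    row_eff = np.zeros(n_rows)
    col_eff = np.zeros(n_cols)
    resid = x.copy()

    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        change = 0.0

        rdelta = _nanmedian_axis(resid, axis=1)
        resid -= rdelta[:, None]
        row_eff += rdelta
        change = max(change, float(np.max(np.abs(rdelta))))

        delta = float(np.median(col_eff))
        col_eff -= delta
        grand += delta
        change = max(change, abs(delta))

        cdelta = _nanmedian_axis(resid, axis=0)
        resid -= cdelta[None, :]
        col_eff += cdelta
        change = max(change, float(np.max(np.abs(cdelta))))

        delta = float(np.median(row_eff))
        row_eff -= delta
        grand += delta
        change = max(change, abs(delta))

        if change < tol:
            converged = True
            break

    residuals = np.where(finite, x - (grand + row_eff[:, None] + col_eff[None, :]), np.nan)
    return MedianPolishFit(
        grand_effect=grand,
        row_effects=row_eff,
        col_effects=col_eff,
        residuals=residuals,
        n_iterations=iteration,
        converged=converged,
        flagged_rows=[int(i) for i in np.flatnonzero(~finite.any(axis=1))],
        flagged_cols=[int(j) for j in np.flatnonzero(~finite.any(axis=0))],
    )


def b_score_from_values(
    values: np.ndarray,
    sample_mask: np.ndarray,
    mad_scale: float = MAD_NORMAL_CONSISTENCY,
    min_sample_wells: int = 8,
) -> BScoreMatrix:
    """Standardize a plate of values by the median/MAD of its sample wells.

    score[r, c] = (values[r, c] - Median) / (mad_scale * MAD), where Median
    and MAD are computed over non-missing sample wells only (control wells
    still receive scores but do not influence the estimates).
    """
    values = np.asarray(values, dtype=float)
    sample_mask = np.asarray(sample_mask, dtype=bool)
    if sample_mask.shape != values.shape:
        raise ValueError("sample_mask shape must match the value matrix")
    used = sample_mask & np.isfinite(values)
    if used.sum() < min_sample_wells:
        raise ValueError(
            f"plate unusable: only {int(used.sum())} non-missing sample wells "
            f"(need >= {min_sample_wells})"
        )
    sample_values = values[used]
    median = float(np.median(sample_values))
    mad = float(np.median(np.abs(sample_values - median)))
    if mad == 0.0:
        raise DegeneratePlateError(
            "degenerate plate: MAD of sample-well residuals is zero (constant residuals)"
        )
    with np.errstate(invalid="ignore"):
        scores = (values - median) / (mad_scale * mad)
    return BScoreMatrix(
        b_scores=scores,
        median_used=median,
        mad_used=mad,
        mad_scale=mad_scale,
        wells_used=used,
    )


def b_score(
    fit: MedianPolishFit,
    sample_mask: np.ndarray,
    mad_scale: float = MAD_NORMAL_CONSISTENCY,
    min_sample_wells: int = 8,
) -> BScoreMatrix:
    """B scores from a median-polish fit (residuals standardized by median/MAD)."""
    return b_score_from_values(fit.residuals, sample_mask, mad_scale, min_sample_wells)


def z_prime(
    neg_scores: np.ndarray,
    pos_scores: np.ndarray,
    plate: int | str | None = None,
) -> ZPrimeReport:
    """Z'-factor: 1 - 3 (sd_neg + sd_pos) / |mean_neg - mean_pos|.

    Sample standard deviations (ddof=1).  When the control means coincide
    the statistic is undefined and the report is flagged (z_prime = NaN).
    """
    neg = np.asarray(neg_scores, dtype=float)
    pos = np.asarray(pos_scores, dtype=float)
    neg = neg[np.isfinite(neg)]
    pos = pos[np.isfinite(pos)]
    if len(neg) < 2 or len(pos) < 2:
        raise ValueError("need at least 2 finite wells per control class")
    mean_neg, mean_pos = float(neg.mean()), float(pos.mean())
    sd_neg = float(neg.std(ddof=1))
    sd_pos = float(pos.std(ddof=1))
    window = abs(mean_neg - mean_pos)
    if window == 0.0:
        value, defined = float("nan"), False
    else:
        value, defined = 1.0 - 3.0 * (sd_neg + sd_pos) / window, True
    return ZPrimeReport(
        plate=plate,
        mean_neg=mean_neg,
        sd_neg=sd_neg,
        mean_pos=mean_pos,
        sd_pos=sd_pos,
        n_neg=len(neg),
        n_pos=len(pos),
        z_prime=value,
        defined=defined,
    )
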