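"""Independent brute-force oracles, deliberately kept free of the package's
implementation paths: pure-Python loops and statistics.median only."""

from __future__ import annotations

import statistics


def brute_force_median_polish(matrix, max_iter=500, tol=1e-8):
    """Loop-based two-way median polish; None marks missing wells.

    Same sweep order as any row-first polish (row sweep, fold column-effect
    median into the grand effect, column sweep, fold row-effect median),
    run until the largest effect change drops below tol.
    Returns (grand, row_effects, col_effects, residuals).
    """
    n_rows = len(matrix)
    n_cols = len(matrix[0])
    z = [[matrix[r][c] for c in range(n_cols)] for r in range(n_rows)]
    row_eff = [0.0] * n_rows
    col_eff = [0.0] * n_cols
    grand = 0.0

    def med(values):
        return statistics.median(values) if values else 0.0

    for _ in range(max_iter):
        change = 0.0
        for r in range(n_rows):
            m = med([z[r][c] for c in range(n_cols) if z[r][c] is not None])
            for c in range(n_cols):
                if z[r][c] is not None:
                    z[r][c] -= m
            row_eff[r] += m
            change = max(change, abs(m))
        d = statistics.median(col_eff)
        col_eff = [x - d for x in col_eff]
        grand += d
        change = max(change, abs(d))
        for c in range(n_cols):
            m = med([z[r][c] for r in range(n_rows) if z[r][c] is not None])
            for r in range(n_rows):
                if z[r][c] is not None:
                    z[r][c] -= m
            col_eff[c] += m
            change = max(change, abs(m))
        d = statistics.median(row_eff)
        row_eff = [x - d for x in row_eff]
        grand += d
        change = max(change, abs(d))
        if change < tol:
            break

    residuals = [
        [
            matrix[r][c] - (grand + row_eff[r] + col_eff[c])
            if matrix[r][c] is not None
            else None
            for c in range(n_cols)
        ]
        for r in range(n_rows)
    ]
    return grand, row_eff, col_eff, residuals


def ddct_by_hand(ct_rows):
    """ct_rows: list of (condition, ct_target, ct_reference).

    Per-replicate dCt, per-condition mean, ddCt = plus - minus, fold = 2**-ddCt.
    """
    by_cond = {"minus_inhibitor": [], "plus_inhibitor": []}
    for condition, ct_t, ct_r in ct_rows:
        by_cond[condition].append(ct_t - ct_r)
    mean = {k: sum(v) / len(v) for k, v in by_cond.items()}
    ddct = mean["plus_inhibitor"] - mean["minus_inhibitor"]
    return 2.0 ** (-ddct)


def z_prime_by_hand(neg, pos):
    def mean(xs):
        return sum(xs) / len(xs)

    def sd(xs):
        m = mean(xs)
        return (sum((x - m) ** 2 for x in xs) / (len(xs) - 1)) ** 0.5

    return 1.0 - 3.0 * (sd(neg) + sd(pos)) / abs(mean(neg) - mean(pos))
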