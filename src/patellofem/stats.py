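"""Summary statistics and group comparisons for the stress tables.

Per-angle stress values are pooled into mean and sample SD (divisor n-1),
rounded half-away-from-zero to two decimals for MPa values and to integer
percent for relative changes — the conventions that reproduce the printed
summary rows of the reference tables.  Group comparisons use two-sample
Student (pooled variance) or Welch t-tests, two-sided, with a
summary-statistic variant for literature comparisons.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


class StatsError(ValueError):
    pass


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (1.965 -> 1.97 at 2 digits)."""
    q = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * q + 0.5) / q, x)


@dataclass
class SummaryRow:
    """Pooled summary of per-angle values."""

    values: dict                 # theta -> value (or (theta, factor) -> value)
    pooled_mean: float           # rounded, 2 decimals
    pooled_sd: float             # rounded, 2 decimals
    n: int
    raw_mean: float
    raw_sd: float


@dataclass
class ComparisonResult:
    t_statistic: float
    degrees_of_freedom: float
    p_value: float
    test: str                    # "student" | "welch"


def pool(values, keys=None) -> SummaryRow:
    """Arithmetic mean and sample SD (n-1) of pooled values."""
    vals = np.asarray(list(values), dtype=float)
    if len(vals) < 2:
        raise StatsError("pooling requires at least 2 values (SD undefined)")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if keys is None:
        keys = list(range(len(vals)))
    return SummaryRow(
        values=dict(zip(keys, vals.tolist())),
        pooled_mean=round_half_away(mean, 2),
        pooled_sd=round_half_away(sd, 2),
        n=len(vals),
        raw_mean=mean,
        raw_sd=sd,
    )


def pool_postop(table: dict) -> SummaryRow:
    """Pool a postoperative 4-angle x 3-correction-factor table.

    ``table`` maps (theta, factor) -> value; all 12 cells must be present.
    """
    thetas = sorted({k[0] for k in table})
    factors = sorted({k[1] for k in table})
    cells = [(th, f) for th in thetas for f in factors]
    missing = [c for c in cells if c not in table]
    if missing or len(table) != 12:
        raise StatsError(f"postoperative table incomplete; missing cells {missing}")
    return pool([table[c] for c in cells], keys=cells)


def percent_change(after: float, before: float) -> int:
    """Relative change in integer percent, half away from zero."""
    if before <= 0:
        raise StatsError("reference value must be positive")
    return int(round_half_away(100.0 * (after - before) / before, 0))


def _t_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b, welch):
    va, vb = sd_a**2, sd_b**2
    if welch:
        se2 = va / n_a + vb / n_b
        if se2 == 0:
            return None
        t = (mean_a - mean_b) / math.sqrt(se2)
        df = se2**2 / (
            (va / n_a) ** 2 / (n_a - 1) + (vb / n_b) ** 2 / (n_b - 1)
        ) if (va > 0 or vb > 0) else 0.0
    else:
        sp2 = ((n_a - 1) * va + (n_b - 1) * vb) / (n_a + n_b - 2)
        if sp2 == 0:
            return None
        t = (mean_a - mean_b) / math.sqrt(sp2 * (1 / n_a + 1 / n_b))
        df = n_a + n_b - 2
    return t, df


def t_test_summary(
    mean_a: float, sd_a: float, n_a: int,
    mean_b: float, sd_b: float, n_b: int,
    welch: bool = False,
) -> ComparisonResult:
    """Two-sided two-sample t-test from summary statistics."""
    if n_a < 2 or n_b < 2:
        raise StatsError("t-test requires n >= 2 per group")
    out = _t_from_summary(mean_a, sd_a, n_a, mean_b, sd_b, n_b, welch)
    if out is None:
        # zero variance in both groups: p = 1 when means agree (convention),
        # else the difference is exact and p -> 0
        p = 1.0 if mean_a == mean_b else 0.0
        return ComparisonResult(0.0, float(n_a + n_b - 2), max(p, 1e-300),
                                "welch" if welch else "student")
    t, df = out
    p = 2.0 * sps.t.sf(abs(t), df)
    return ComparisonResult(float(t), float(df), float(p),
                            "welch" if welch else "student")


def t_test(a, b, welch: bool = False) -> ComparisonResult:
    """Two-sided two-sample t-test on raw samples."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("t-test requires n >= 2 per group")
    return t_test_summary(
        float(a.mean()), float(a.std(ddof=1)), len(a),
        float(b.mean()), float(b.std(ddof=1)), len(b),
        welch=welch,
    )
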