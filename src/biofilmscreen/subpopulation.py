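"""Biofilm/planktonic biomass partition and FISH positive-cell fractions.

The sessile fraction is the share of optical density contributed by cells
that stay attached after planktonic removal — a biomass proxy for the
fraction of cells in the biofilm.  FISH fractions count cells with at least
one target-mRNA focus among control-probe-positive (countable) cells, with
Wilson score intervals; two strains' fractions are compared by Fisher's
exact test.
"""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


def sessile_fraction(od_biofilm: float, od_planktonic: float) -> float:
    """Percentage of biomass in the biofilm: 100 · biofilm/(biofilm+planktonic)."""
    if od_biofilm < 0 or od_planktonic < 0:
        raise ValueError("optical densities must be non-negative")
    total = od_biofilm + od_planktonic
    if total <= 0:
        raise ValueError("undefined fraction: biofilm + planktonic OD is zero")
    return 100.0 * od_biofilm / total


def fish_positive_fraction(
    n_countable: int, n_positive: int, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Fraction of countable cells positive for the target mRNA, with Wilson CI.

    Parameters
    ----------
    n_countable : int
        Cells positive for the control probe (> 0).
    n_positive : int
        Cells with ≥ 1 target-mRNA focus (0 ≤ n_positive ≤ n_countable).
    confidence : float
        Interval coverage (default 95%).

    Returns
    -------
    (fraction, (low, high))
        Point estimate and Wilson score interval, all in [0, 1].
    """
    if n_countable <= 0:
        raise ValueError("n_countable must be positive")
    if not 0 <= n_positive <= n_countable:
        raise ValueError(
            f"n_positive must lie in [0, n_countable], got {n_positive}/{n_countable}"
        )
    frac = n_positive / n_countable
    low, high = proportion_confint(
        n_positive, n_countable, alpha=1 - confidence, method="wilson"
    )
    return float(frac), (float(low), float(high))


def compare_fractions(a: dict, b: dict) -> float:
    """Two-sided Fisher exact p-value for two FISH positive fractions.

    Each argument is a count record with keys ``n_countable`` and
    ``n_positive`` (as produced by the synthetic generator).
    """
    for c in (a, b):
        if c["n_countable"] <= 0:
            raise ValueError("n_countable must be positive")
        if not 0 <= c["n_positive"] <= c["n_countable"]:
            raise ValueError("n_positive must lie in [0, n_countable]")
    table = np.array(
        [
            [a["n_positive"], a["n_countable"] - a["n_positive"]],
            [b["n_positive"], b["n_countable"] - b["n_positive"]],
        ]
    )
    return float(stats.fisher_exact(table, alternative="two-sided")[1])
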