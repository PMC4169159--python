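"""Dot-blot expression analysis: control-normalized ratios relative to parental.

Target-probe intensities (FLO11) are normalized per replicate to a control
probe (ACT1); group means over independent experiments give each mutant's
fold relative to the parental strain, tested with a two-sided Welch t-test
and tiered ***/**/* by p-value.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats


class UnusableReplicateError(ValueError):
    """A replicate's control intensity is not positive; the ratio is undefined."""


def normalize_blot(intensity_target: float, intensity_control: float) -> float:
    """Control-normalized signal ratio target/control for one replicate."""
    if intensity_control <= 0:
        raise UnusableReplicateError(
            f"control intensity must be positive, got {intensity_control}"
        )
    if intensity_target < 0:
        raise UnusableReplicateError(
            f"target intensity must be non-negative, got {intensity_target}"
        )
    return float(intensity_target) / float(intensity_control)


def relative_expression(mutant_ratios, parental_ratios) -> tuple[float, float]:
    """Expression fold of a mutant relative to parental, and its log2.

    fold = mean(mutant ratios) / mean(parental ratios); the heat value is
    log2(fold), so parental-vs-itself is exactly 0.

    Requires at least 2 usable replicates in each group and a positive
    parental mean.
    """
    m = np.asarray(mutant_ratios, dtype=float)
    p = np.asarray(parental_ratios, dtype=float)
    if m.size < 2 or p.size < 2:
        raise ValueError(
            f"need >= 2 replicates per group, got {m.size} mutant / {p.size} parental"
        )
    parental_mean = float(np.mean(p))
    if parental_mean <= 0:
        raise ValueError(f"parental mean ratio must be positive, got {parental_mean}")
    fold = float(np.mean(m)) / parental_mean
    heat = float(np.log2(fold)) if fold > 0 else float("-inf")
    return fold, heat


def expression_test(mutant_ratios, parental_ratios, paired: bool = False) -> float:
    """Two-sided p-value for a location difference in replicate ratios.

    Welch's unequal-variance t-test by default (no equal-variance
    assumption at n = 3); ``paired=True`` runs a paired t-test for designs
    where mutant and parental blots share experiments.  Two identical
    constant groups give p = 1 by convention.
    """
    m = np.asarray(mutant_ratios, dtype=float)
    p = np.asarray(parental_ratios, dtype=float)
    if m.size < 2 or p.size < 2:
        raise ValueError("need >= 2 replicates per group for a t-test")
    if np.var(m) == 0 and np.var(p) == 0:
        return 1.0 if np.mean(m) == np.mean(p) else 0.0
    if paired:
        if m.size != p.size:
            raise ValueError("paired test requires equal group sizes")
        res = stats.ttest_rel(m, p)
    else:
        res = stats.ttest_ind(m, p, equal_var=False)
    return float(res.pvalue)


def assign_tier(p_value: float) -> str:
    """Significance tier for a dot-blot p-value.

    "***" for p ≤ 0.01, "**" for 0.01 < p < 0.05, "*" for 0.05 ≤ p < 0.1,
    "" otherwise.  The boundary p = 0.05 falls in the "*" tier so the
    tiers partition [0, 1].
    """
    if not 0 <= p_value <= 1:
        raise ValueError(f"p-value must lie in [0, 1], got {p_value}")
    if p_value <= 0.01:
        return "***"
    if p_value < 0.05:
        return "**"
    if p_value < 0.1:
        return "*"
    return ""


def expression_table(
    dotblots: pd.DataFrame,
    parental_strain: str = "PARENTAL",
    paired: bool = False,
) -> pd.DataFrame:
    """Per-strain expression results from a dot-blot measurement table.

    Parameters
    ----------
    dotblots : DataFrame
        Columns ``strain_id, experiment, intensity_target,
        intensity_control``; must include the parental strain.
    parental_strain : str
        strain_id of the reference whose mean ratio defines fold 1.
    paired : bool
        Pair mutant and parental replicates by experiment index.

    Returns
    -------
    DataFrame
        One row per non-parental strain: ``strain_id, mean_ratio,
        relative_to_parental, heat_value, p_value, tier, n_reps``, sorted
        by strain_id.
    """
    ratios = {
        strain: np.array(
            [
                normalize_blot(t, c)
                for t, c in zip(g["intensity_target"], g["intensity_control"])
            ]
        )
        for strain, g in dotblots.groupby("strain_id")
    }
    if parental_strain not in ratios:
        raise ValueError(f"parental strain {parental_strain!r} absent from dot-blot table")
    parental = ratios[parental_strain]
    rows = []
    for strain in sorted(ratios):
        if strain == parental_strain:
            continue
        r = ratios[strain]
        fold, heat = relative_expression(r, parental)
        p = expression_test(r, parental, paired=paired)
        rows.append(
            {
                "strain_id": strain,
                "mean_ratio": float(np.mean(r)),
                "relative_to_parental": fold,
                "heat_value": heat,
                "p_value": p,
                "tier": assign_tier(p),
                "n_reps": int(r.size),
            }
        )
    return pd.DataFrame(rows)
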