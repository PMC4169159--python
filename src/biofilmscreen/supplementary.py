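"""Re-analysis of published median-score and phenotype tables.

The screen's supplementary tables ship per-mutant median normalized biofilm
scores rather than raw wells.  These helpers run the identical
classification path — fixed printed cutoffs, dual-timepoint same-direction
intersection — directly on such median tables, so a user holding the
published files can reproduce the screen's hit counts with the same code
the synthetic pipeline exercises.
"""

from __future__ import annotations

import pandas as pd

from biofilmscreen.hit_calling import NullModel, classify_table, summarize_hits

#: The screen's printed hit cutoffs on the ln(OD595/OD600) scale, and the
#: parental null they imply (mean = midpoint, sigma = quarter-range, k = 2).
PRINTED_CUTOFF_LOW = 0.584
PRINTED_CUTOFF_HIGH = 1.972

PRINTED_NULL = NullModel(
    timepoint_hr=-1.0,
    mu=(PRINTED_CUTOFF_LOW + PRINTED_CUTOFF_HIGH) / 2,
    sigma=(PRINTED_CUTOFF_HIGH - PRINTED_CUTOFF_LOW) / 4,
    k=2.0,
    n_reference=288,
)


def reanalyze_median_table(
    medians: pd.DataFrame,
    timepoints=(46.0, 96.0),
    null: NullModel = PRINTED_NULL,
) -> tuple[pd.DataFrame, dict]:
    """Classify a per-mutant median-score table with fixed cutoffs.

    Parameters
    ----------
    medians : DataFrame
        Long format: ``strain_id, timepoint_hr, median_score`` (missing
        medians may be NaN). A published per-mutant score table converted
        to TSV fits directly.
    timepoints : sequence
        Timepoints a final hit must be significant at.
    null : NullModel
        The null defining the cutoffs; defaults to the printed pair
        (0.584, 1.972) applied to every timepoint.

    Returns
    -------
    (hit_table, summary)
        Per-strain classes and final calls, and the count summary
        (per-timepoint LESS/MORE counts, dual-timepoint hit counts).
    """
    required = [float(t) for t in timepoints]
    table = medians[["strain_id", "timepoint_hr", "median_score"]].copy()
    table["n_valid"] = 0
    table["n_excluded"] = 0
    nulls = {tp: null for tp in required}
    hit_table = classify_table(table, nulls, required)
    return hit_table, summarize_hits(hit_table)
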