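"""Empirical Gaussian null and ±kσ hit classification.

The screen's significance rule: fit mean and standard deviation to the
parental reference wells' scores at a timepoint, classify each mutant's
median score against mean ± k·sd cutoffs (k = 2 by default, two-sided
P < 0.05 under the Gaussian null), and keep as final hits only strains
called in the same direction at every required timepoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

LESS = "LESS"
NORMAL = "NORMAL"
MORE = "MORE"
NONE = "NONE"
EXCLUDED = "EXCLUDED"

#: Per-timepoint classes and final calls, in reporting order.
TIMEPOINT_CLASSES = (LESS, NORMAL, MORE, EXCLUDED)
FINAL_CALLS = (LESS, MORE, NONE, EXCLUDED)


@dataclass(frozen=True)
class NullModel:
    """Gaussian null for one timepoint, fitted to parental reference scores.

    Attributes
    ----------
    timepoint_hr : float
        Timepoint label in hours.
    mu, sigma : float
        Mean and sample standard deviation (n−1 denominator) of the
        reference scores.
    k : float
        σ-multiplier for the cutoffs; 2 gives the conventional two-sided
        P < 0.05 band under normality.
    n_reference : int
        Number of reference scores the fit used.
    skewness, excess_kurtosis : float
        Shape diagnostics of the reference sample, for judging how
        Gaussian the null actually is.
    """

    timepoint_hr: float
    mu: float
    sigma: float
    k: float = 2.0
    n_reference: int = 0
    skewness: float = field(default=float("nan"))
    excess_kurtosis: float = field(default=float("nan"))

    @property
    def cutoff_low(self) -> float:
        return self.mu - self.k * self.sigma

    @property
    def cutoff_high(self) -> float:
        return self.mu + self.k * self.sigma

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")


def fit_null(reference_scores, timepoint_hr: float = 0.0, k: float = 2.0) -> NullModel:
    """Fit the Gaussian null to parental replicate scores at one timepoint.

    Parameters
    ----------
    reference_scores : array-like
        Normalized biofilm scores of individual parental wells (not
        medians); at least 3, not all equal.
    timepoint_hr : float
        Label carried into the model.
    k : float
        Cutoff multiplier (default 2).

    Raises
    ------
    ValueError
        For fewer than 3 scores or a degenerate (constant) sample.
    """
    x = np.asarray(reference_scores, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 3:
        raise ValueError(
            f"need >= 3 reference scores to fit a null, got {x.size}"
        )
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("degenerate reference sample: all scores equal")
    return NullModel(
        timepoint_hr=timepoint_hr,
        mu=float(np.mean(x)),
        sigma=sd,
        k=k,
        n_reference=int(x.size),
        skewness=float(stats.skew(x, bias=False)),
        excess_kurtosis=float(stats.kurtosis(x, bias=False)),
    )


def classify_score(median_score, null: NullModel):
    """Classify a median score against the null's ±kσ cutoffs.

    Strictly below ``cutoff_low`` → LESS; strictly above ``cutoff_high`` →
    MORE; a missing (NaN/None) median → EXCLUDED; otherwise NORMAL.
    Boundary scores exactly at a cutoff are NORMAL: the rule is strictly
    "less than" / "more than".

    Accepts a scalar or an array; arrays return an object ndarray of class
    labels.
    """
    x = np.asarray(median_score, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.full(x.shape, NORMAL, dtype=object)
    out[~np.isfinite(x)] = EXCLUDED
    finite = np.isfinite(x)
    out[finite & (x < null.cutoff_low)] = LESS
    out[finite & (x > null.cutoff_high)] = MORE
    if scalar:
        return out[0]
    return out


def call_hits(classes_by_timepoint: dict, required_timepoints) -> str:
    """Final call from per-timepoint classes by same-direction intersection.

    LESS (or MORE) only when every required timepoint is LESS (or MORE);
    EXCLUDED at any required timepoint makes the final call EXCLUDED, so
    data-quality failures stay distinguishable from true negatives;
    anything else — including opposite directions — is NONE.

    Raises
    ------
    KeyError
        If a required timepoint has no class.
    """
    required = list(required_timepoints)
    if not required:
        raise ValueError("required_timepoints must be non-empty")
    cls = []
    for tp in required:
        if tp not in classes_by_timepoint:
            raise KeyError(f"no class for required timepoint {tp}")
        cls.append(classes_by_timepoint[tp])
    if EXCLUDED in cls:
        return EXCLUDED
    if all(c == LESS for c in cls):
        return LESS
    if all(c == MORE for c in cls):
        return MORE
    return NONE


def classify_table(
    score_table: pd.DataFrame,
    nulls: dict,
    required_timepoints=None,
) -> pd.DataFrame:
    """Classify a median-score table and call final hits per strain.

    Parameters
    ----------
    score_table : DataFrame
        Output of :func:`biofilmscreen.scoring.median_scores`.
    nulls : dict
        Mapping timepoint_hr → :class:`NullModel`. With a single shared
        null, pass the same model under every timepoint key.
    required_timepoints : sequence, optional
        Timepoints a final hit must be significant at; defaults to all
        timepoints present in ``nulls``.

    Returns
    -------
    DataFrame
        One row per strain: ``strain_id``, ``class_<tp>h`` and
        ``median_<tp>h`` per timepoint, and ``final_call``. A strain
        missing a required timepoint entirely is EXCLUDED.
    """
    if required_timepoints is None:
        required_timepoints = sorted(nulls)
    required_timepoints = list(required_timepoints)
    missing = [tp for tp in required_timepoints if tp not in nulls]
    if missing:
        raise KeyError(f"no null model for required timepoint(s) {missing}")

    wide_median = score_table.pivot(
        index="strain_id", columns="timepoint_hr", values="median_score"
    )
    rows = []
    for strain_id, medians in wide_median.iterrows():
        classes = {}
        for tp in required_timepoints:
            med = medians.get(tp, np.nan)
            classes[tp] = classify_score(med if med is not None else np.nan, nulls[tp])
        row = {"strain_id": strain_id}
        for tp in required_timepoints:
            row[f"class_{_tp_label(tp)}"] = classes[tp]
            row[f"median_{_tp_label(tp)}"] = wide_median.loc[strain_id].get(tp, np.nan)
        row["final_call"] = call_hits(classes, required_timepoints)
        rows.append(row)
    return pd.DataFrame(rows)


def _tp_label(tp) -> str:
    tp = float(tp)
    return f"{int(tp)}h" if tp.is_integer() else f"{tp}h"


def summarize_hits(hit_table: pd.DataFrame, truth: pd.DataFrame | None = None) -> dict:
    """Count calls per class per timepoint and final; confusion matrix if truth given.

    Parameters
    ----------
    hit_table : DataFrame
        Output of :func:`classify_table`.
    truth : DataFrame, optional
        Ground-truth table with ``strain_id`` and ``true_class`` columns
        (the synthetic generator's TruthTable).

    Returns
    -------
    dict
        ``per_timepoint``: {timepoint label: {class: count}};
        ``final``: {final call: count} (a partition of all strains);
        with truth also ``confusion`` (true class × final call counts),
        ``sensitivity`` per planted direction and ``false_call_rate``
        among true-NORMAL strains.
    """
    class_cols = [c for c in hit_table.columns if c.startswith("class_")]
    per_tp = {}
    for col in class_cols:
        counts = hit_table[col].value_counts().to_dict()
        per_tp[col.removeprefix("class_")] = {
            c: int(counts.get(c, 0)) for c in TIMEPOINT_CLASSES
        }
    final_counts = hit_table["final_call"].value_counts().to_dict() if len(hit_table) else {}
    summary = {
        "n_strains": int(len(hit_table)),
        "per_timepoint": per_tp,
        "final": {c: int(final_counts.get(c, 0)) for c in FINAL_CALLS},
    }
    if truth is not None and len(hit_table):
        merged = hit_table.merge(
            truth[["strain_id", "true_class"]], on="strain_id", how="left"
        )
        confusion = (
            merged.groupby(["true_class", "final_call"]).size().unstack(fill_value=0)
        )
        summary["confusion"] = {
            t: {c: int(n) for c, n in row.items()} for t, row in confusion.iterrows()
        }
        sens = {}
        for direction in (LESS, MORE):
            planted = merged[merged["true_class"] == direction]
            if len(planted):
                sens[direction] = float(
                    (planted["final_call"] == direction).mean()
                )
        summary["sensitivity"] = sens
        nulls_only = merged[merged["true_class"] == NORMAL]
        if len(nulls_only):
            summary["false_call_rate"] = float(
                nulls_only["final_call"].isin([LESS, MORE]).mean()
            )
    return summary
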