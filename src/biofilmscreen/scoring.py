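"""Normalized biofilm scores from plate-reader well measurements.

A well's biofilm score is the natural log of the crystal-violet stain
absorbance over the total-biomass absorbance, ln(OD595/OD600).  Wells whose
biomass falls below an exclusion threshold (default OD600 < 0.01) are
dropped before aggregation; each strain × timepoint group is then summarized
by the median of its valid replicate scores.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Biomass absorbance below which a well is excluded from analysis.
EXCLUSION_THRESHOLD = 0.01

#: Minimum valid replicates required to report a median score.
MIN_VALID_REPLICATES = 2


class InvalidMeasurementError(ValueError):
    """A well carries a non-positive absorbance where a positive one is required."""


def normalized_score(od_stain, od_biomass):
    """Normalized biofilm score ln(od_stain / od_biomass).

    Parameters
    ----------
    od_stain : float or array-like
        Crystal-violet absorbance (OD595-equivalent). Must be > 0.
    od_biomass : float or array-like
        Total-biomass absorbance (OD600-equivalent). Must be > 0.

    Returns
    -------
    float or ndarray
        Dimensionless log-ratio score. Scalar inputs give a scalar.

    Raises
    ------
    InvalidMeasurementError
        If any stain or biomass value is not strictly positive — zero or
        negative absorbances indicate instrument or parsing faults and are
        never silently clamped.
    """
    stain = np.asarray(od_stain, dtype=float)
    biomass = np.asarray(od_biomass, dtype=float)
    if np.any(~np.isfinite(stain)) or np.any(~np.isfinite(biomass)):
        raise InvalidMeasurementError("non-finite absorbance value")
    if np.any(stain <= 0) or np.any(biomass <= 0):
        bad = np.flatnonzero((stain <= 0) | (biomass <= 0))
        raise InvalidMeasurementError(
            f"non-positive absorbance at position(s) {bad.tolist()[:10]}; "
            "scores are defined only for positive OD values"
        )
    out = np.log(stain / biomass)
    if np.isscalar(od_stain) and np.isscalar(od_biomass):
        return float(out)
    return out


def apply_exclusion(
    measurements: pd.DataFrame, threshold: float = EXCLUSION_THRESHOLD
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split well measurements into retained and biomass-excluded sets.

    A well is excluded when its ``od_biomass`` is strictly below
    ``threshold``. Row order is preserved in both outputs and the two
    outputs partition the input.
    """
    if threshold <= 0:
        raise ValueError(f"exclusion threshold must be positive, got {threshold}")
    mask = measurements["od_biomass"].to_numpy(dtype=float) < threshold
    excluded = measurements.loc[mask]
    retained = measurements.loc[~mask]
    return retained, excluded


def median_scores(
    measurements: pd.DataFrame,
    threshold: float = EXCLUSION_THRESHOLD,
    min_valid: int = MIN_VALID_REPLICATES,
) -> pd.DataFrame:
    """Median normalized biofilm score per strain × timepoint.

    Applies the biomass exclusion rule per well, scores the retained wells,
    and takes the median over valid replicates within each
    (strain_id, timepoint_hr) group.  Groups with fewer than ``min_valid``
    valid wells get a missing (NaN) median — downstream they are EXCLUDED,
    not silently averaged from a single well.

    Returns
    -------
    DataFrame
        Columns ``strain_id, timepoint_hr, median_score, n_valid,
        n_excluded``; one row per strain × timepoint present in the input
        (also groups whose every well was excluded).
    """
    if min_valid < 1:
        raise ValueError("min_valid must be >= 1")
    retained, _ = apply_exclusion(measurements, threshold)
    retained = retained.copy()
    retained["score"] = normalized_score(
        retained["od_stain"].to_numpy(), retained["od_biomass"].to_numpy()
    )

    submitted = (
        measurements.groupby(["strain_id", "timepoint_hr"], sort=True)
        .size()
        .rename("n_submitted")
    )
    valid = (
        retained.groupby(["strain_id", "timepoint_hr"], sort=True)
        .agg(median_score=("score", "median"), n_valid=("score", "size"))
    )
    table = submitted.to_frame().join(valid, how="left")
    table["n_valid"] = table["n_valid"].fillna(0).astype(int)
    table["n_excluded"] = table["n_submitted"] - table["n_valid"]
    table.loc[table["n_valid"] < min_valid, "median_score"] = np.nan
    table = table.reset_index().drop(columns="n_submitted")
    return table[["strain_id", "timepoint_hr", "median_score", "n_valid", "n_excluded"]]
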