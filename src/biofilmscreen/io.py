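"""Table schemas, validated readers/writers and run configuration.

All tables are TSV with a header (UTF-8, "." decimal separator); CSV is
accepted on read by sniffing the delimiter.  Readers validate rather than
coerce: malformed rows fail with the offending line named.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

MEASUREMENT_COLUMNS = [
    "strain_id",
    "gene_id",
    "timepoint_hr",
    "replicate",
    "od_biomass",
    "od_stain",
]
OPTIONAL_MEASUREMENT_COLUMNS = ["plate_id", "well"]

DOTBLOT_COLUMNS = ["strain_id", "experiment", "intensity_target", "intensity_control"]
FISH_COLUMNS = ["strain_id", "n_countable", "n_positive"]
PARTITION_COLUMNS = ["strain_id", "time_hr", "od_biofilm", "od_planktonic"]
PHENOTYPE_COLUMNS = [
    "gene_id",
    "biofilm_deficient",
    "mat_deficient",
    "invasion_deficient",
]


class ParseError(ValueError):
    """An input table violates its schema."""


@dataclass
class RunConfig:
    """End-to-end pipeline configuration with the screen's printed defaults."""

    exclusion_threshold: float = 0.01
    k_sigma: float = 2.0
    required_timepoints: tuple = (46.0, 96.0)
    min_valid_replicates: int = 2
    shared_null: bool = False
    seed: int = 0
    out_dir: str = "results"
    correction: str = "bonferroni"

    def __post_init__(self):
        if self.exclusion_threshold <= 0:
            raise ValueError("exclusion_threshold must be positive")
        if self.k_sigma <= 0:
            raise ValueError("k_sigma must be positive")
        if self.min_valid_replicates < 1:
            raise ValueError("min_valid_replicates must be >= 1")
        self.required_timepoints = tuple(float(t) for t in self.required_timepoints)
        if not self.required_timepoints:
            raise ValueError("required_timepoints must be non-empty")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParseError(f"config file {path} must hold a flat mapping")
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["required_timepoints"] = list(self.required_timepoints)
        return d


def _read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep=None, engine="python")


def read_measurements(path) -> pd.DataFrame:
    """Read and validate a well-measurement table.

    Requires the columns ``strain_id, gene_id, timepoint_hr, replicate,
    od_biomass, od_stain``; optional ``plate_id, well`` pass through.
    Raises :class:`ParseError` naming the row for missing columns,
    unparseable or negative OD values, and duplicated
    (strain_id, timepoint_hr, replicate) keys.
    """
    df = _read_table(path)
    missing = [c for c in MEASUREMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in ("timepoint_hr", "od_biomass", "od_stain"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna()].tolist()
        if bad:
            raise ParseError(
                f"{path}: column {col!r} not numeric at data row(s) {bad[:10]}"
            )
        df[col] = values.astype(float)
    rep = pd.to_numeric(df["replicate"], errors="coerce")
    bad = df.index[rep.isna()].tolist()
    if bad:
        raise ParseError(f"{path}: column 'replicate' not numeric at data row(s) {bad[:10]}")
    df["replicate"] = rep.astype(int)
    neg = df.index[(df["od_biomass"] < 0) | (df["od_stain"] < 0)].tolist()
    if neg:
        raise ParseError(f"{path}: negative OD value at data row(s) {neg[:10]}")
    if not np.isfinite(df[["timepoint_hr", "od_biomass", "od_stain"]].to_numpy()).all():
        raise ParseError(f"{path}: non-finite numeric value")
    key = ["strain_id", "timepoint_hr", "replicate"]
    dup = df[df.duplicated(key, keep=False)]
    if len(dup):
        first = dup.iloc[0]
        raise ParseError(
            f"{path}: duplicate (strain_id, timepoint_hr, replicate) key "
            f"({first['strain_id']}, {first['timepoint_hr']}, {first['replicate']})"
        )
    keep = MEASUREMENT_COLUMNS + [c for c in OPTIONAL_MEASUREMENT_COLUMNS if c in df.columns]
    return df[keep]


def read_dotblots(path) -> pd.DataFrame:
    df = _read_table(path)
    missing = [c for c in DOTBLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in ("intensity_target", "intensity_control"):
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna()].tolist()
        if bad:
            raise ParseError(f"{path}: column {col!r} not numeric at data row(s) {bad[:10]}")
        df[col] = values.astype(float)
    return df[DOTBLOT_COLUMNS]


def read_fish_counts(path) -> pd.DataFrame:
    df = _read_table(path)
    missing = [c for c in FISH_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in ("n_countable", "n_positive"):
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            raise ParseError(f"{path}: column {col!r} not numeric")
        df[col] = values.astype(int)
    bad = df.index[(df["n_positive"] < 0) | (df["n_positive"] > df["n_countable"])].tolist()
    if bad:
        raise ParseError(f"{path}: n_positive outside [0, n_countable] at row(s) {bad[:10]}")
    return df[FISH_COLUMNS]


def read_phenotypes(path) -> pd.DataFrame:
    df = _read_table(path)
    missing = [c for c in PHENOTYPE_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    for col in PHENOTYPE_COLUMNS[1:]:
        df[col] = df[col].map(_parse_bool)
        if df[col].isna().any():
            raise ParseError(f"{path}: column {col!r} not boolean")
        df[col] = df[col].astype(bool)
    return df[PHENOTYPE_COLUMNS]


def _parse_bool(v):
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    s = str(v).strip().lower()
    if s in ("true", "1", "yes", "t"):
        return True
    if s in ("false", "0", "no", "f"):
        return False
    return None


def read_gene_list(path) -> list[str]:
    """One gene identifier per line; blank lines and '#' comments ignored."""
    genes = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return genes


def read_annotation(path) -> dict:
    """Two-column (gene, category) TSV → gene → list-of-categories map."""
    df = _read_table(path)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: annotation map needs two columns (gene, category)")
    gene_col, cat_col = df.columns[:2]
    mapping: dict[str, list] = {}
    for gene, cat in zip(df[gene_col], df[cat_col]):
        mapping.setdefault(str(gene), []).append(str(cat))
    return mapping


def write_table(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def write_null_models(nulls: dict, path) -> None:
    """Serialize fitted null models as a small JSON metadata block."""
    payload = {
        str(tp): {
            "timepoint_hr": m.timepoint_hr,
            "mu": m.mu,
            "sigma": m.sigma,
            "k": m.k,
            "cutoff_low": m.cutoff_low,
            "cutoff_high": m.cutoff_high,
            "n_reference": m.n_reference,
            "skewness": m.skewness,
            "excess_kurtosis": m.excess_kurtosis,
        }
        for tp, m in nulls.items()
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
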