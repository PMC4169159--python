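"""End-to-end screen analysis: score, fit nulls, call hits, write results.

`run_pipeline` composes the stages on validated input tables and writes a
result bundle (score table, null metadata, hit table, summary JSON, and —
when the optional inputs are present — expression, FISH-fraction and
phenotype-overlap tables) plus a run log with config, seed and input
checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from biofilmscreen import io as bio
from biofilmscreen import hit_calling, scoring
from biofilmscreen.expression import expression_table
from biofilmscreen.setstats import GeneSet, overlap, venn3
from biofilmscreen.subpopulation import fish_positive_fraction

log = logging.getLogger("biofilmscreen")


def _checksum(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def fit_nulls_from_measurements(
    measurements: pd.DataFrame, config: bio.RunConfig
) -> dict:
    """Fit per-timepoint null models to the parental reference wells.

    Parental wells are those with gene_id "PARENTAL". The fit uses
    individual well scores after biomass exclusion, never medians. With
    ``config.shared_null`` one model is fitted to all parental wells
    pooled across timepoints and applied everywhere.
    """
    parental = measurements[measurements["gene_id"] == "PARENTAL"]
    if not len(parental):
        raise ValueError("no parental reference wells (gene_id == 'PARENTAL')")
    retained, excluded = scoring.apply_exclusion(parental, config.exclusion_threshold)
    log.info("parental wells: %d retained, %d biomass-excluded", len(retained), len(excluded))
    if config.shared_null:
        scores = scoring.normalized_score(
            retained["od_stain"].to_numpy(), retained["od_biomass"].to_numpy()
        )
        model = hit_calling.fit_null(scores, timepoint_hr=-1.0, k=config.k_sigma)
        return {tp: model for tp in config.required_timepoints}
    nulls = {}
    for tp in config.required_timepoints:
        sub = retained[retained["timepoint_hr"] == tp]
        if len(sub) < 3:
            raise ValueError(f"fewer than 3 parental wells at timepoint {tp}")
        scores = scoring.normalized_score(
            sub["od_stain"].to_numpy(), sub["od_biomass"].to_numpy()
        )
        nulls[tp] = hit_calling.fit_null(scores, timepoint_hr=tp, k=config.k_sigma)
        log.info(
            "null @ %g h: mu=%.4f sigma=%.4f cutoffs (%.4f, %.4f) n=%d",
            tp, nulls[tp].mu, nulls[tp].sigma,
            nulls[tp].cutoff_low, nulls[tp].cutoff_high, nulls[tp].n_reference,
        )
    return nulls


def analyze_screen(
    measurements: pd.DataFrame,
    config: bio.RunConfig,
    truth: pd.DataFrame | None = None,
):
    """Score wells, fit nulls, classify and summarize one screen.

    Returns (score_table, nulls, hit_table, summary).
    """
    nulls = fit_nulls_from_measurements(measurements, config)
    mutants = measurements[measurements["gene_id"] != "PARENTAL"]
    scores = scoring.median_scores(
        mutants,
        threshold=config.exclusion_threshold,
        min_valid=config.min_valid_replicates,
    )
    hit_table = hit_calling.classify_table(scores, nulls, config.required_timepoints)
    gene_map = mutants[["strain_id", "gene_id"]].drop_duplicates()
    hit_table = gene_map.merge(hit_table, on="strain_id", how="right")
    summary = hit_calling.summarize_hits(hit_table, truth)
    return scores, nulls, hit_table, summary


def phenotype_overlap_report(phenotypes: pd.DataFrame, universe_size: int) -> dict:
    """Venn partition and invasive-overlap percentage from a phenotype table."""
    biofilm = GeneSet("biofilm_deficient", phenotypes.loc[phenotypes["biofilm_deficient"], "gene_id"])
    mat = GeneSet("mat_deficient", phenotypes.loc[phenotypes["mat_deficient"], "gene_id"])
    inv = GeneSet("invasion_deficient", phenotypes.loc[phenotypes["invasion_deficient"], "gene_id"])
    regions = venn3(biofilm, mat, inv)
    ov = overlap(biofilm, inv, universe_size)
    return {
        "venn": {k: v for k, v in regions.items() if k != "labels"},
        "n_biofilm_deficient": len(biofilm),
        "n_mat_deficient": len(mat),
        "n_invasion_deficient": len(inv),
        "percent_of_biofilm_also_invasion": round(ov.percent_of_a),
        "overlap_p_value": ov.p_value,
    }


def run_pipeline(
    config: bio.RunConfig,
    measurement_path,
    dotblot_path=None,
    fish_path=None,
    phenotype_path=None,
    truth_path=None,
) -> Path:
    """Run the full analysis on disk inputs; returns the output directory.

    Optional stages (expression, FISH fractions, phenotype overlap) run
    only when their input is supplied; a skipped stage is noted in the run
    log. Any stage error aborts with the stage named.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    run_log = {"config": config.to_dict(), "inputs": {}, "stages": []}

    measurements = bio.read_measurements(measurement_path)
    run_log["inputs"]["measurements"] = {
        "path": str(measurement_path),
        "sha256_16": _checksum(measurement_path),
        "n_rows": int(len(measurements)),
    }
    truth = None
    if truth_path is not None:
        truth = pd.read_csv(truth_path, sep="\t")
        run_log["inputs"]["truth"] = {"path": str(truth_path), "sha256_16": _checksum(truth_path)}

    scores, nulls, hit_table, summary = analyze_screen(measurements, config, truth)
    bio.write_table(scores, out / "score_table.tsv")
    bio.write_null_models(nulls, out / "null_models.json")
    bio.write_table(hit_table, out / "hit_table.tsv")
    (out / "hit_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    run_log["stages"].append("screen")

    if dotblot_path is not None:
        blots = bio.read_dotblots(dotblot_path)
        run_log["inputs"]["dotblots"] = {"path": str(dotblot_path), "sha256_16": _checksum(dotblot_path)}
        bio.write_table(expression_table(blots), out / "expression_table.tsv")
        run_log["stages"].append("expression")
    else:
        log.info("no dot-blot input; expression stage skipped")

    if fish_path is not None:
        fish = bio.read_fish_counts(fish_path)
        run_log["inputs"]["fish"] = {"path": str(fish_path), "sha256_16": _checksum(fish_path)}
        rows = []
        for _, r in fish.iterrows():
            frac, (lo, hi) = fish_positive_fraction(r["n_countable"], r["n_positive"])
            rows.append(
                {"strain_id": r["strain_id"], "n_countable": r["n_countable"],
                 "n_positive": r["n_positive"], "fraction": frac,
                 "wilson_low": lo, "wilson_high": hi}
            )
        bio.write_table(pd.DataFrame(rows), out / "fish_fractions.tsv")
        run_log["stages"].append("fish")
    else:
        log.info("no FISH input; subpopulation stage skipped")

    if phenotype_path is not None:
        phenotypes = bio.read_phenotypes(phenotype_path)
        run_log["inputs"]["phenotypes"] = {"path": str(phenotype_path), "sha256_16": _checksum(phenotype_path)}
        n_strains = hit_table["strain_id"].nunique()
        report = phenotype_overlap_report(phenotypes, universe_size=max(n_strains, len(phenotypes)))
        (out / "phenotype_overlap.json").write_text(json.dumps(report, indent=2) + "\n")
        run_log["stages"].append("phenotypes")
    else:
        log.info("no phenotype input; overlap stage skipped")

    (out / "run_log.json").write_text(json.dumps(run_log, indent=2) + "\n")
    return out
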