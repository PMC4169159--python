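"""Synthetic screen, dot-blot, FISH and phenotype data with known ground truth.

The generator emulates the study conditions of a genome-wide deletion-library
biofilm screen: 4019 mutant strains plus 288 parental reference wells per
timepoint, triplicate wells at 46 h and 96 h, per-well normalized scores
Gaussian around the parental mean (the null N(1.278, 0.347²) is back-derived
from the screen's printed ±2σ cutoffs 0.584 / 1.972), planted LESS/MORE
mutants as mean shifts on the score scale, lognormal biomass with occasional
low-biomass dropouts that exercise the OD600 < 0.01 exclusion rule, dot-blot
intensity pairs with multiplicative replicate noise, binomial FISH counts,
and binary mat/invasive phenotype labels with conditional overlap structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from biofilmscreen.scoring import EXCLUSION_THRESHOLD
from biofilmscreen.hit_calling import LESS, NORMAL, MORE

PARENTAL = "PARENTAL"

#: Null parameters back-derived from the screen's printed cutoffs:
#: mu = (0.584 + 1.972) / 2, sigma = (1.972 − 0.584) / 4.
DEFAULT_NULL_MU = 1.278
DEFAULT_NULL_SIGMA = 0.347


class ConfigurationError(ValueError):
    """A simulation configuration violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition parameters for the synthetic screen.

    Defaults reproduce the screen's design: 4019 deletion mutants, 288
    parental wells per timepoint, triplicates at 46 h and 96 h, and the
    parental score null N(1.278, 0.347²).

    Attributes
    ----------
    n_mutants : int
        Number of deletion strains.
    n_parental_wells : int
        Independent parental reference wells per timepoint.
    timepoints_hr : tuple of float
        Assay timepoints in hours.
    replicates : int
        Wells per mutant per timepoint.
    null_mu, null_sigma : float
        Mean and sd of the parental score distribution (ln OD595/OD600).
    frac_less, frac_more : float
        Fractions of mutants planted as LESS / MORE hits.
    effect_less, effect_more : float
        Planted mean shifts in units of ``null_sigma`` (both given as
        positive magnitudes; LESS shifts are applied downward).
    mutant_sigma : float or None
        Per-well score sd of mutant strains; None means use ``null_sigma``.
    biomass_log_mean, biomass_log_sd : float
        Lognormal parameters of well biomass (OD600). Defaults give a
        median around 0.5 with a realistic 0.15–1.6 spread.
    dropout_prob : float
        Probability a well's biomass is redrawn uniformly in
        [0, 0.01) — below the exclusion threshold.
    seed : int
        Seed for the single pseudo-random stream of the dataset.
    """

    n_mutants: int = 4019
    n_parental_wells: int = 288
    timepoints_hr: tuple = (46.0, 96.0)
    replicates: int = 3
    null_mu: float = DEFAULT_NULL_MU
    null_sigma: float = DEFAULT_NULL_SIGMA
    frac_less: float = 0.0
    frac_more: float = 0.0
    effect_less: float = 4.0
    effect_more: float = 4.0
    mutant_sigma: float | None = None
    biomass_log_mean: float = -0.7
    biomass_log_sd: float = 0.5
    dropout_prob: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_mutants < 0 or self.n_parental_wells < 0:
            raise ConfigurationError("counts must be non-negative")
        if self.replicates < 1:
            raise ConfigurationError("replicates must be >= 1")
        if self.null_sigma <= 0 or self.biomass_log_sd <= 0:
            raise ConfigurationError("all sigma/sd parameters must be positive")
        if self.mutant_sigma is not None and self.mutant_sigma <= 0:
            raise ConfigurationError("mutant_sigma must be positive")
        if not 0 <= self.frac_less <= 1 or not 0 <= self.frac_more <= 1:
            raise ConfigurationError("hit fractions must lie in [0, 1]")
        if self.frac_less + self.frac_more > 1:
            raise ConfigurationError("frac_less + frac_more must not exceed 1")
        if not 0 <= self.dropout_prob <= 1:
            raise ConfigurationError("dropout_prob must lie in [0, 1]")
        tps = tuple(float(t) for t in self.timepoints_hr)
        if len(set(tps)) != len(tps) or not tps:
            raise ConfigurationError("timepoints must be non-empty and distinct")
        object.__setattr__(self, "timepoints_hr", tps)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["timepoints_hr"] = list(self.timepoints_hr)
        return d


def generate_screen(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate well measurements and a ground-truth table for one screen.

    Each well draws biomass ~ Lognormal(biomass_log_mean, biomass_log_sd²)
    and a score = null_mu + shift + Normal(0, sd); the stain absorbance is
    biomass × exp(score), so well noise lives on the log-score scale where
    the null is Gaussian, independent of biomass.  With probability
    ``dropout_prob`` a well's biomass is redrawn uniformly in [0, 0.01),
    putting it under the exclusion threshold while its stain value still
    follows biomass × exp(score).

    Returns
    -------
    measurements : DataFrame
        Columns ``strain_id, gene_id, timepoint_hr, replicate, od_biomass,
        od_stain``; mutant wells plus ``n_parental_wells`` parental wells
        (gene_id PARENTAL, replicate = well index) per timepoint.
    truth : DataFrame
        One row per mutant: ``strain_id, gene_id, true_class, true_shift``
        (shift in score units; negative for LESS).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_mutants
    n_less = int(round(config.frac_less * n))
    n_more = int(round(config.frac_more * n))
    if n_less + n_more > n:  # rounding can overshoot by one
        n_more = n - n_less

    classes = np.array([NORMAL] * n, dtype=object)
    shifts = np.zeros(n)
    classes[:n_less] = LESS
    shifts[:n_less] = -config.effect_less * config.null_sigma
    classes[n_less : n_less + n_more] = MORE
    shifts[n_less : n_less + n_more] = config.effect_more * config.null_sigma
    perm = rng.permutation(n)
    classes, shifts = classes[perm], shifts[perm]

    width = max(4, len(str(max(n, 1))))
    strain_ids = np.array([f"MUT{i + 1:0{width}d}" for i in range(n)])
    gene_ids = np.array([f"GENE{i + 1:0{width}d}" for i in range(n)])

    truth = pd.DataFrame(
        {
            "strain_id": strain_ids,
            "gene_id": gene_ids,
            "true_class": classes,
            "true_shift": shifts,
        }
    )

    mut_sd = config.null_sigma if config.mutant_sigma is None else config.mutant_sigma
    frames = []
    for tp in config.timepoints_hr:
        # parental reference wells: independent wells, one per replicate index
        frames.append(
            _draw_wells(
                rng,
                config,
                strain_id=np.repeat(PARENTAL, config.n_parental_wells),
                gene_id=np.repeat(PARENTAL, config.n_parental_wells),
                timepoint_hr=tp,
                replicate=np.arange(1, config.n_parental_wells + 1),
                shift=np.zeros(config.n_parental_wells),
                score_sd=config.null_sigma,
            )
        )
        for rep in range(1, config.replicates + 1):
            frames.append(
                _draw_wells(
                    rng,
                    config,
                    strain_id=strain_ids,
                    gene_id=gene_ids,
                    timepoint_hr=tp,
                    replicate=np.repeat(rep, n),
                    shift=shifts,
                    score_sd=mut_sd,
                )
            )
    measurements = pd.concat(frames, ignore_index=True)
    return measurements, truth


def _draw_wells(rng, config, strain_id, gene_id, timepoint_hr, replicate, shift, score_sd):
    k = len(strain_id)
    biomass = rng.lognormal(config.biomass_log_mean, config.biomass_log_sd, size=k)
    if config.dropout_prob > 0:
        drop = rng.random(k) < config.dropout_prob
        biomass[drop] = rng.uniform(0.0, EXCLUSION_THRESHOLD, size=int(drop.sum()))
    score = config.null_mu + shift + rng.normal(0.0, score_sd, size=k)
    return pd.DataFrame(
        {
            "strain_id": strain_id,
            "gene_id": gene_id,
            "timepoint_hr": float(timepoint_hr),
            "replicate": np.asarray(replicate, dtype=int),
            "od_biomass": biomass,
            "od_stain": biomass * np.exp(score),
        }
    )


def generate_dotblots(
    strain_folds: dict,
    replicate_cv: float = 0.1,
    n_reps: int = 3,
    seed: int = 0,
    parental_mean_ratio: float = 1.0,
) -> pd.DataFrame:
    """Generate dot-blot (target, control) intensity pairs per strain.

    Each replicate draws a control intensity around a nominal level and a
    target intensity whose expected target/control ratio is
    ``fold × parental_mean_ratio``; both carry multiplicative lognormal
    noise of coefficient of variation ``replicate_cv``.  A parental entry
    (fold 1) should be included by the caller under the key it prefers.

    Parameters
    ----------
    strain_folds : dict
        Mapping strain_id → true expression fold (> 0) relative to parental.
    replicate_cv : float
        Coefficient of variation of replicate noise (≥ 0).
    n_reps : int
        Independent experiments per strain (≥ 2).
    seed : int
        RNG seed.
    parental_mean_ratio : float
        Expected target/control ratio of a fold-1 strain.

    Returns
    -------
    DataFrame
        Columns ``strain_id, experiment, intensity_target, intensity_control``.
    """
    if n_reps < 2:
        raise ValueError(f"n_reps must be >= 2, got {n_reps}")
    if replicate_cv < 0:
        raise ValueError("replicate_cv must be non-negative")
    bad = {s: f for s, f in strain_folds.items() if f <= 0}
    if bad:
        raise ValueError(f"non-positive expression fold for strain(s) {sorted(bad)}")
    rng = np.random.default_rng(seed)
    # lognormal with unit mean: sigma from CV, mu = -sigma^2/2
    sig = float(np.sqrt(np.log1p(replicate_cv**2)))
    rows = []
    control_level = 100.0
    for strain_id, fold in strain_folds.items():
        for exp_idx in range(1, n_reps + 1):
            control = control_level * rng.lognormal(-sig**2 / 2, sig)
            target = (
                fold
                * parental_mean_ratio
                * control
                * rng.lognormal(-sig**2 / 2, sig)
            )
            rows.append(
                {
                    "strain_id": strain_id,
                    "experiment": exp_idx,
                    "intensity_target": target,
                    "intensity_control": control,
                }
            )
    return pd.DataFrame(rows)


def generate_fish_counts(true_fraction: float, n_cells: int, seed: int = 0) -> dict:
    """Binomial FISH count: positives ~ Binomial(n_cells, true_fraction).

    Returns a record with ``n_countable`` (control-probe-positive cells)
    and ``n_positive`` (cells with ≥ 1 target-mRNA focus).
    """
    if not 0 <= true_fraction <= 1:
        raise ValueError(f"true_fraction must lie in [0, 1], got {true_fraction}")
    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    rng = np.random.default_rng(seed)
    return {
        "n_countable": int(n_cells),
        "n_positive": int(rng.binomial(n_cells, true_fraction)),
    }


def generate_phenotype_table(
    n_biofilm_deficient: int,
    p_mat_given_biofilm: float,
    p_inv_given_mat: float,
    seed: int = 0,
) -> pd.DataFrame:
    """Binary mat/invasive labels for biofilm-deficient genes.

    Each biofilm-deficient gene loses mat formation with probability
    ``p_mat_given_biofilm``; mat-deficient genes additionally lose invasive
    growth with probability ``p_inv_given_mat`` (invasion loss is nested
    under mat loss, mirroring the observed phenotype chain).

    Returns
    -------
    DataFrame
        Columns ``gene_id, biofilm_deficient, mat_deficient,
        invasion_deficient`` (booleans; biofilm_deficient is always True).
    """
    for name, p in (
        ("p_mat_given_biofilm", p_mat_given_biofilm),
        ("p_inv_given_mat", p_inv_given_mat),
    ):
        if not 0 <= p <= 1:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    if n_biofilm_deficient < 0:
        raise ValueError("n_biofilm_deficient must be non-negative")
    rng = np.random.default_rng(seed)
    n = n_biofilm_deficient
    mat = rng.random(n) < p_mat_given_biofilm
    inv = mat & (rng.random(n) < p_inv_given_mat)
    width = max(3, len(str(max(n, 1))))
    return pd.DataFrame(
        {
            "gene_id": [f"BF{i + 1:0{width}d}" for i in range(n)],
            "biofilm_deficient": np.ones(n, dtype=bool),
            "mat_deficient": mat,
            "invasion_deficient": inv,
        }
    )
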