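"""Ground-truth generators: determinism, marginals, and parameter recovery."""

import numpy as np
import pandas as pd
import pytest

from biofilmscreen.hit_calling import LESS, MORE, NORMAL
from biofilmscreen.scoring import EXCLUSION_THRESHOLD
from biofilmscreen.synthetic import (
    ConfigurationError,
    SimulationConfig,
    generate_dotblots,
    generate_fish_counts,
    generate_phenotype_table,
    generate_screen,
)


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"replicates": 0},
            {"null_sigma": 0.0},
            {"null_sigma": -1.0},
            {"frac_less": 0.7, "frac_more": 0.5},
            {"timepoints_hr": (46.0, 46.0)},
            {"dropout_prob": 1.5},
            {"mutant_sigma": -0.1},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimulationConfig(**kwargs)

    def test_defaults_are_the_study_conditions(self):
        cfg = SimulationConfig()
        assert cfg.n_mutants == 4019
        assert cfg.n_parental_wells == 288
        assert cfg.replicates == 3
        assert cfg.timepoints_hr == (46.0, 96.0)
        assert cfg.null_mu == pytest.approx((0.584 + 1.972) / 2)
        assert cfg.null_sigma == pytest.approx((1.972 - 0.584) / 4)


class TestGenerateScreen:
    def test_shapes_and_partition(self):
        cfg = SimulationConfig(n_mutants=50, n_parental_wells=20, seed=3)
        m, truth = generate_screen(cfg)
        assert len(truth) == 50
        expected_wells = 50 * 2 * 3 + 20 * 2
        assert len(m) == expected_wells
        parental = m[m["gene_id"] == "PARENTAL"]
        assert len(parental) == 40
        assert not m.duplicated(["strain_id", "timepoint_hr", "replicate"]).any()

    def test_no_mutants_only_parental_wells(self):
        cfg = SimulationConfig(n_mutants=0, n_parental_wells=10, seed=1)
        m, truth = generate_screen(cfg)
        assert truth.empty
        assert (m["gene_id"] == "PARENTAL").all()
        assert len(m) == 20

    def test_no_planted_hits_truth_all_normal(self):
        cfg = SimulationConfig(n_mutants=100, frac_less=0, frac_more=0, seed=2)
        _, truth = generate_screen(cfg)
        assert (truth["true_class"] == NORMAL).all()
        assert (truth["true_shift"] == 0).all()

    def test_truth_classes_consistent_with_shifts(self):
        cfg = SimulationConfig(n_mutants=200, frac_less=0.2, frac_more=0.3, seed=4)
        _, truth = generate_screen(cfg)
        assert (truth.loc[truth["true_shift"] < 0, "true_class"] == LESS).all()
        assert (truth.loc[truth["true_shift"] > 0, "true_class"] == MORE).all()
        assert (truth.loc[truth["true_shift"] == 0, "true_class"] == NORMAL).all()
        assert (truth["true_class"] == LESS).sum() == 40
        assert (truth["true_class"] == MORE).sum() == 60

    def test_determinism_same_seed_identical_tables(self):
        cfg = SimulationConfig(n_mutants=30, seed=11, frac_less=0.1)
        m1, t1 = generate_screen(cfg)
        m2, t2 = generate_screen(cfg)
        pd.testing.assert_frame_equal(m1, m2)
        pd.testing.assert_frame_equal(t1, t2)
        m3, _ = generate_screen(SimulationConfig(n_mutants=30, seed=12, frac_less=0.1))
        assert not m3["od_stain"].equals(m1["od_stain"])

    def test_no_dropout_all_biomass_above_threshold(self):
        cfg = SimulationConfig(n_mutants=200, dropout_prob=0.0, seed=6)
        m, _ = generate_screen(cfg)
        assert (m["od_biomass"] >= EXCLUSION_THRESHOLD).all()

    def test_dropout_wells_below_threshold_exist(self):
        cfg = SimulationConfig(n_mutants=500, dropout_prob=0.2, seed=6)
        m, _ = generate_screen(cfg)
        assert (m["od_biomass"] < EXCLUSION_THRESHOLD).sum() > 0

    def test_parental_score_marginals_recover_null(self):
        """At full screen size the parental wells' score sample mean and sd
        sit within ±0.07 / ±0.05 of the generating 1.278 / 0.347."""
        cfg = SimulationConfig(n_mutants=4019, seed=9)
        m, _ = generate_screen(cfg)
        parental = m[(m["gene_id"] == "PARENTAL") & (m["od_biomass"] >= EXCLUSION_THRESHOLD)]
        for tp in cfg.timepoints_hr:
            sub = parental[parental["timepoint_hr"] == tp]
            scores = np.log(sub["od_stain"] / sub["od_biomass"])
            assert scores.mean() == pytest.approx(1.278, abs=0.07)
            assert scores.std(ddof=1) == pytest.approx(0.347, abs=0.05)


class TestGenerateDotblots:
    def test_noise_free_folds_exact(self):
        blots = generate_dotblots({"PARENTAL": 1.0, "m1": 1.0}, replicate_cv=0.0, seed=0)
        ratios = blots["intensity_target"] / blots["intensity_control"]
        assert ratios.to_numpy() == pytest.approx(np.ones(len(blots)))

    def test_fold_recovered_in_expectation(self):
        """fold 2.7 (the strongest printed dot-blot change), CV 10%, n=3:
        the mean recovered fold over many seeds is within ±0.3."""
        from biofilmscreen.expression import expression_table

        folds = []
        for seed in range(200):
            blots = generate_dotblots(
                {"PARENTAL": 1.0, "mut": 2.7}, replicate_cv=0.1, n_reps=3, seed=seed
            )
            folds.append(
                expression_table(blots).set_index("strain_id").loc["mut", "relative_to_parental"]
            )
        assert np.mean(folds) == pytest.approx(2.7, abs=0.3)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            generate_dotblots({"m": 2.0}, n_reps=1)
        with pytest.raises(ValueError):
            generate_dotblots({"m": 0.0})
        with pytest.raises(ValueError):
            generate_dotblots({"m": 1.0}, replicate_cv=-0.2)


class TestGenerateFish:
    def test_degenerate_fractions(self):
        assert generate_fish_counts(0.0, 542, seed=1)["n_positive"] == 0
        assert generate_fish_counts(1.0, 100, seed=1)["n_positive"] == 100

    def test_binomial_mean_recovery(self):
        """Empirical mean fraction over many seeds within ±0.01 of 0.21
        (the screen's wild-type FISH-positive fraction at n=1329)."""
        fracs = [
            generate_fish_counts(0.21, 1329, seed=s)["n_positive"] / 1329
            for s in range(10_000)
        ]
        assert np.mean(fracs) == pytest.approx(0.21, abs=0.01)

    def test_invalid_fraction(self):
        with pytest.raises(ValueError):
            generate_fish_counts(1.2, 100)
        with pytest.raises(ValueError):
            generate_fish_counts(-0.1, 100)


class TestGeneratePhenotypes:
    def test_degenerate_probabilities(self):
        all_lost = generate_phenotype_table(10, 1.0, 1.0, seed=0)
        assert all_lost["mat_deficient"].all()
        assert all_lost["invasion_deficient"].all()
        none_lost = generate_phenotype_table(10, 0.0, 1.0, seed=0)
        assert not none_lost["mat_deficient"].any()
        assert not none_lost["invasion_deficient"].any()

    def test_invasion_nested_under_mat(self):
        table = generate_phenotype_table(500, 0.7, 0.6, seed=3)
        assert not (table["invasion_deficient"] & ~table["mat_deficient"]).any()

    def test_conditional_frequencies_in_expectation(self):
        """With the observed chain (71 biofilm, 69/71 mat, 49/69 invasive),
        the mean mat-deficient count over seeds is ≈ 69."""
        counts = [
            generate_phenotype_table(71, 69 / 71, 49 / 69, seed=s)["mat_deficient"].sum()
            for s in range(500)
        ]
        assert np.mean(counts) == pytest.approx(69.0, abs=0.5)

    def test_invalid_probability(self):
        with pytest.raises(ValueError):
            generate_phenotype_table(10, 1.2, 0.5)
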