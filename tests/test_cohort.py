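"""Virtual-cohort generation: distributions, determinism, recovery."""

import numpy as np
import pytest

from neocrea import CohortSpec, ValidationError, generate_cohort, recovery_experiment

NOISELESS = dict(
    bsv_cv={"emax": 0.0, "production_rate": 0.0, "cl_bl": 0.0},
    residual_proportional=0.0,
    residual_additive=0.0,
)


@pytest.fixture(scope="module")
def typical(calibrated):
    return calibrated.fitted


class TestCohortSpec:
    def test_invalid_specs_rejected(self):
        with pytest.raises(ValidationError):
            CohortSpec(n_neonates=0)
        with pytest.raises(ValidationError):
            CohortSpec(exposure_fraction=1.5)
        with pytest.raises(ValidationError):
            CohortSpec(ga_probabilities={24: 0.5, 27: 0.4})  # does not sum to 1
        with pytest.raises(ValidationError):
            CohortSpec(residual_additive=-0.01)

    def test_from_config_defaults_match_source_cohort(self):
        spec = CohortSpec.from_config()
        assert spec.n_neonates == 217
        assert spec.samples_poisson_mean == pytest.approx(17.6)


class TestGenerateCohort:
    def test_deterministic_given_seed(self, typical):
        spec = CohortSpec(n_neonates=25, seed=42)
        a = generate_cohort(spec, typical)
        b = generate_cohort(spec, typical)
        assert a.observations.to_csv(index=False) == b.observations.to_csv(index=False)
        assert a.truth.to_csv(index=False) == b.truth.to_csv(index=False)

    def test_neonate_records_independent_of_cohort_size(self, typical):
        """Records are keyed by (seed, neonate index): enlarging the cohort
        leaves earlier neonates' draws untouched."""
        small = generate_cohort(CohortSpec(n_neonates=10, seed=9), typical)
        large = generate_cohort(CohortSpec(n_neonates=30, seed=9), typical)
        ids = small.truth["id"]
        sub = large.truth[large.truth["id"].isin(ids)].reset_index(drop=True)
        assert sub.equals(small.truth)

    def test_degenerate_noise_reproduces_typical_trajectory(self, typical):
        spec = CohortSpec(n_neonates=40, seed=3, weight_sigma_log=0.0,
                          exposure_fraction=0.0, schedule="grid", **NOISELESS)
        ds = generate_cohort(spec, typical)
        merged = ds.observations.merge(ds.truth[["id", "ga_weeks"]].drop_duplicates(),
                                       on="id", suffixes=("", "_t"))
        # all same-GA neonates coincide at every sampling time
        for (_, _), grp in merged.groupby(["ga_weeks", "time_day"]):
            assert grp["creatinine_mg_dl"].nunique() == 1

    def test_observation_count_near_source_cohort(self, typical):
        for seed in (1, 2, 3):
            ds = generate_cohort(CohortSpec(seed=seed), typical)
            assert abs(len(ds.observations) - 4026) <= 0.1 * 4026

    def test_ga_and_weight_distributions_converge_to_targets(self, typical):
        ds = generate_cohort(CohortSpec(n_neonates=2000, seed=5), typical)
        ga = ds.truth["ga_weeks"]
        assert ga.median() == 27
        assert ga.quantile(0.25) == 26 and ga.quantile(0.75) == 28
        w = ds.truth["weight_g"]
        assert w.median() == pytest.approx(830, rel=0.05)
        assert w.quantile(0.25) == pytest.approx(720, rel=0.07)
        assert w.quantile(0.75) == pytest.approx(910, rel=0.07)

    def test_observations_positive_and_truth_separate(self, typical):
        ds = generate_cohort(CohortSpec(n_neonates=60, seed=8,
                                        residual_additive=0.2), typical)
        assert (ds.observations["creatinine_mg_dl"] > 0).all()
        assert "emax_l_day" not in ds.observations.columns

    def test_exposed_dominate_counterfactual(self, typical):
        """Ground-truth trajectories of exposed neonates lie above their
        unexposed counterfactuals during and after the course."""
        from neocrea import (
            ModelParameters,
            NeonateProfile,
            TreatmentCourse,
            simulate_concentration,
        )

        spec = CohortSpec(n_neonates=20, seed=13, exposure_fraction=1.0)
        ds = generate_cohort(spec, typical)
        row = ds.truth.iloc[0]
        base_params = typical[24]
        p = ModelParameters(
            emax=row["emax_l_day"],
            production_rate=row["production_rate_mg_day"],
            t50=row["t50_day"],
            hill=row["hill"],
            cl_bl_raw=base_params.cl_bl_raw * row["cl_bl_multiplier"],
        )
        prof = NeonateProfile(id=row["id"], gestational_age=int(row["ga_weeks"]),
                              birth_weight=row["weight_g"],
                              initial_creatinine=row["initial_creatinine_mg_dl"])
        course = TreatmentCourse(start_day=int(row["course_start_day"]))
        expo = simulate_concentration(prof, p, (course,), t_end=42.0, step=0.05)
        cf = simulate_concentration(prof, p, (), t_end=42.0, step=0.05)
        assert np.all(expo.concentration >= cf.concentration - 1e-12)


class TestRecoveryExperiment:
    def test_noise_free_identifiability(self, typical):
        spec = CohortSpec(seed=3, weight_sigma_log=0.0, exposure_fraction=0.0,
                          **NOISELESS)
        report = recovery_experiment(spec, 1, typical)
        assert report["errors"]["rel_error"].abs().max() <= 0.01

    def test_smaller_cohort_not_more_informative(self, typical):
        spec = dict(exposure_fraction=0.0, residual_additive=0.01,
                    residual_proportional=0.0,
                    bsv_cv={"emax": 0.0, "production_rate": 0.0, "cl_bl": 0.0})
        big = recovery_experiment(CohortSpec(seed=21, **spec), 2, typical)
        small = recovery_experiment(CohortSpec(seed=21, n_neonates=20, **spec), 2,
                                    typical, min_group_size=3)
        m_big = big["errors"]["rel_error"].abs().median()
        m_small = small["errors"]["rel_error"].abs().median()
        # loose: a 10x smaller cohort must not beat the full one by >2x
        assert m_small >= 0.5 * m_big
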