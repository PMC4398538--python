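import numpy as np
import pandas as pd
import pytest

from agingnet.atlas import Atlas, Lobe
from agingnet.metrics import lobe_strength
from agingnet.netbuild import Modality, filter_fibers, structural_network, tally_fibers
from agingnet.pipeline import build_functional_networks, build_structural_networks
from agingnet.stats import fit_reduced
from agingnet.synthetic import (
    STRATA_COUNTS,
    STRATA_AGE_MEAN,
    CohortSpec,
    EffectSpec,
    MediationSpec,
    PlantedEffect,
    generate_cohort,
    generate_demographics,
    generate_functional,
    generate_structural,
    generate_thickness,
    plant_mediation,
    planted_strengths,
    records_from_tally,
    nearest_pd_correlation,
    tally_from_weights,
)

F, S = Modality.FUNCTIONAL, Modality.STRUCTURAL


def three_lobe_atlas(names_per_lobe=3):
    entries = []
    for h in ("lh", "rh"):
        for lobe in ("prefrontal", "occipital", "lateral_temporal"):
            for k in range(names_per_lobe):
                entries.append({"name": f"{lobe[:4]}{k}", "hemisphere": h, "lobe": lobe})
    return Atlas.from_dict(entries)


class TestDemographics:
    def test_stratified_totals_173(self):
        demo = generate_demographics(CohortSpec(seed=5))
        assert len(demo) == sum(STRATA_COUNTS) == 173

    def test_stratified_decade_counts_and_means(self):
        demo = generate_demographics(CohortSpec(seed=5))
        bins = [(21, 29), (30, 39), (40, 49), (50, 59), (60, 80)]
        for (lo, hi), n, mu in zip(bins, STRATA_COUNTS, STRATA_AGE_MEAN):
            decade = demo[(demo.age >= lo) & (demo.age <= hi)]
            assert len(decade) == n
            assert decade.age.mean() == pytest.approx(mu, abs=2.0)

    def test_uniform_age_distribution(self):
        demo = generate_demographics(
            CohortSpec(n_subjects=1000, age_model="uniform", seed=9)
        )
        assert len(demo) == 1000
        assert demo.age.mean() == pytest.approx((21 + 80) / 2, abs=1.5)
        assert demo.age.between(21, 80).all()

    def test_sex_is_binary_with_sensible_fraction(self):
        demo = generate_demographics(CohortSpec(seed=5))
        assert set(demo.sex) == {0, 1}
        assert 0.5 < demo.sex.mean() < 0.75  # decade percentages are 50-71%

    def test_same_seed_identical(self):
        a = generate_demographics(CohortSpec(seed=11))
        b = generate_demographics(CohortSpec(seed=11))
        pd.testing.assert_frame_equal(a, b)

    def test_different_seed_differs(self):
        a = generate_demographics(CohortSpec(seed=11))
        b = generate_demographics(CohortSpec(seed=12))
        assert not a.age.equals(b.age)


class TestThickness:
    def cohort(self, n=500, seed=3):
        return generate_demographics(
            CohortSpec(n_subjects=n, age_model="uniform", seed=seed)
        )

    def test_zero_slope_means_no_age_effect(self, toy_atlas6):
        demo = self.cohort()
        eff = EffectSpec(thickness_slope_mm_per_year=0.0)
        th = generate_thickness(demo, eff, toy_atlas6, seed=1)
        res = fit_reduced(th["prefrontal"], demo.age, demo.sex)
        assert abs(res.beta_age) < 0.1

    def test_planted_decline_recovered(self, toy_atlas6):
        demo = self.cohort()
        eff = EffectSpec(thickness_slope_mm_per_year=0.005, thickness_noise_sd=0.05)
        th = generate_thickness(demo, eff, toy_atlas6, seed=1)
        slope = np.polyfit(demo.age, th["occipital"], 1)[0]
        assert slope == pytest.approx(-0.005, rel=0.2)

    def test_noiseless_is_exact_linear_function(self, toy_atlas6):
        demo = self.cohort(n=50)
        eff = EffectSpec(thickness_noise_sd=1e-12)
        th = generate_thickness(demo, eff, toy_atlas6, seed=1)
        expect = 2.8 - 0.005 * (demo.age.to_numpy() - 21.0)
        np.testing.assert_allclose(th["prefrontal"].to_numpy(), expect, atol=1e-9)

    def test_values_positive(self, toy_atlas6):
        demo = self.cohort()
        th = generate_thickness(demo, EffectSpec(), toy_atlas6, seed=2)
        assert (th.drop(columns="subject_id") >= 1.0).all().all()


class TestStructuralRoundTrip:
    def test_single_edge_inversion_example(self):
        # w = 0.002, C_i = 200 voxels x 1000, V_j = 5400 -> fcount = 205
        vox = np.array([200, 200])
        vol = np.array([5400.0, 5400.0])
        w = np.array([[0.0, 0.002], [0.002, 0.0]])
        tally = tally_from_weights(w, vox, vol, 1000)
        assert tally.fcount[0, 1] == round(0.002 * (200_000 + 5400) / 2) == 205
        rebuilt = structural_network(tally)
        assert rebuilt.weights[0, 1] == pytest.approx(0.002, rel=0.01)

    def test_zero_weights_give_zero_network(self):
        vox = np.array([50, 60, 70])
        tally = tally_from_weights(np.zeros((3, 3)), vox, vox * 27.0, 1000)
        assert not tally.fcount.any()
        assert not structural_network(tally).weights.any()

    def test_cohort_roundtrip_within_rounding(self, rng):
        atlas = three_lobe_atlas()
        eff = EffectSpec(effects=(PlantedEffect(S, Lobe.PREFRONTAL, Lobe.OCCIPITAL, beta_age=0.3),))
        demo = generate_demographics(CohortSpec(n_subjects=10, age_model="uniform", seed=21))
        latent = planted_strengths(demo, eff, 21)
        tallies = generate_structural(demo, eff, atlas, 21, latent)
        planted = eff.structural_base + eff.structural_scale * latent[
            "structural:prefrontal:occipital"
        ].to_numpy()
        for i, tally in enumerate(tallies):
            got = lobe_strength(structural_network(tally), atlas, "prefrontal", "occipital")
            assert got == pytest.approx(max(planted[i], 0.0), rel=0.01)

    def test_infeasible_density_rejected(self):
        vox = np.array([1, 1])
        vol = np.array([1.0, 1.0])
        w = np.array([[0.0, 5.0], [5.0, 0.0]])  # needs more fibers than sampled
        with pytest.raises(ValueError, match="more fibers"):
            tally_from_weights(w, vox, vol, 1)

    def test_record_mode_matches_direct_tally_after_filtering(self, toy_atlas6):
        vox = np.array([3, 3, 3, 3, 3, 3])
        w = np.full((6, 6), 0.02)
        np.fill_diagonal(w, 0.0)
        tally = tally_from_weights(w, vox, vox * 27.0, 10)
        records = records_from_tally(tally, seed=4, loop_fraction=0.1, short_fraction=0.2)
        clean = filter_fibers(records)
        assert len(clean) < len(records)
        np.testing.assert_array_equal(tally_fibers(clean, toy_atlas6), tally.fcount)


class TestFunctionalGeneration:
    def test_planted_strength_recovered_at_large_t(self):
        atlas = three_lobe_atlas()
        eff = EffectSpec(
            effects=(PlantedEffect(F, Lobe.OCCIPITAL, Lobe.LATERAL_TEMPORAL),),
            functional_base=0.4,
            functional_scale=0.0,
        )
        spec = CohortSpec(n_subjects=2, age_model="uniform", seed=31, t_points=4096)
        demo = generate_demographics(spec)
        subjects = generate_functional(demo, eff, atlas, spec)
        from agingnet.preprocess import preprocess_panel
        from agingnet.netbuild import functional_network

        net = functional_network(preprocess_panel(subjects[0].panel, subjects[0].nuisance))
        got = lobe_strength(net, atlas, "occipital", "lateral_temporal")
        assert got == pytest.approx(0.4, abs=0.03)

    def test_null_structure_gives_near_zero_strengths(self):
        atlas = three_lobe_atlas()
        eff = EffectSpec(
            functional_within_lobe=0.0, functional_between_lobe=0.0, drift_sd=0.0,
            nuisance_load_sd=0.0,
        )
        spec = CohortSpec(n_subjects=2, age_model="uniform", seed=32, t_points=1024)
        demo = generate_demographics(spec)
        subjects = generate_functional(demo, eff, atlas, spec)
        from agingnet.netbuild import functional_network
        from agingnet.preprocess import preprocess_panel

        net = functional_network(preprocess_panel(subjects[0].panel, subjects[0].nuisance))
        for la, lb in [("prefrontal", "occipital"), ("occipital", "lateral_temporal")]:
            assert abs(lobe_strength(net, atlas, la, lb)) < 0.05

    def test_pd_projection_diagnostic_small_for_defaults(self):
        cohort = generate_cohort(CohortSpec(n_subjects=5, age_model="uniform", seed=33))
        assert max(s.pd_projection_drift for s in cohort.functional) < 0.02

    def test_nearest_pd_projection_properties(self, rng):
        c = rng.uniform(-0.6, 0.9, size=(10, 10))
        c = 0.5 * (c + c.T)
        np.fill_diagonal(c, 1.0)
        x = nearest_pd_correlation(c)
        assert np.linalg.eigvalsh(x).min() > 0
        np.testing.assert_allclose(np.diag(x), 1.0, atol=1e-8)
        # already-PD input passes through unchanged
        pd_in = np.eye(4) * 0.5 + 0.5
        np.testing.assert_allclose(nearest_pd_correlation(pd_in), pd_in, atol=1e-8)
        # not much farther from the input than statsmodels' near-optimal
        # Frobenius projection (an independent implementation)
        from statsmodels.stats.correlation_tools import corr_nearest

        ref = corr_nearest(c, threshold=1e-6, n_fact=1000)
        assert np.linalg.norm(x - c) < 1.5 * np.linalg.norm(ref - c) + 1e-6

    def test_determinism_and_seed_sensitivity(self):
        spec = CohortSpec(n_subjects=3, age_model="uniform", seed=34, t_points=64)
        a = generate_cohort(spec)
        b = generate_cohort(spec)
        np.testing.assert_array_equal(a.functional[0].panel.data, b.functional[0].panel.data)
        np.testing.assert_array_equal(a.tallies[1].fcount, b.tallies[1].fcount)
        pd.testing.assert_frame_equal(a.latent, b.latent)
        c = generate_cohort(CohortSpec(n_subjects=3, age_model="uniform", seed=35, t_points=64))
        assert not np.array_equal(a.functional[0].panel.data, c.functional[0].panel.data)


class TestPlantMediation:
    def demo(self, n=4000):
        return generate_demographics(CohortSpec(n_subjects=n, age_model="uniform", seed=41))

    def effects(self, a, b, c_prime):
        return EffectSpec(
            mediations=(
                MediationSpec(
                    a=a, b=b, c_prime=c_prime,
                    mediator=("structural", Lobe.OCCIPITAL, Lobe.LATERAL_TEMPORAL),
                    outcome=("structural", Lobe.PREFRONTAL, Lobe.LATERAL_TEMPORAL),
                ),
            )
        )

    def test_total_effect_is_c_prime_plus_ab(self):
        demo = self.demo()
        latents = plant_mediation(demo, self.effects(0.5, 0.4, 0.2), seed=42)
        y = latents[("structural", "prefrontal", "lateral_temporal")]
        res = fit_reduced(y, demo.age, demo.sex)
        assert res.beta_age == pytest.approx(0.2 + 0.5 * 0.4, abs=0.03)

    def test_mediator_latent_carries_a(self):
        demo = self.demo()
        latents = plant_mediation(demo, self.effects(0.5, 0.4, 0.2), seed=42)
        m = latents[("structural", "occipital", "lateral_temporal")]
        assert fit_reduced(m, demo.age, demo.sex).beta_age == pytest.approx(0.5, abs=0.03)

    def test_unit_variance_of_planted_latents(self):
        demo = self.demo()
        latents = plant_mediation(demo, self.effects(0.5, 0.4, 0.2), seed=42)
        for v in latents.values():
            assert np.std(v, ddof=1) == pytest.approx(1.0, abs=0.05)

    def test_cyclic_spec_rejected(self):
        key1 = ("structural", Lobe.OCCIPITAL, Lobe.LATERAL_TEMPORAL)
        key2 = ("structural", Lobe.PREFRONTAL, Lobe.LATERAL_TEMPORAL)
        with pytest.raises(ValueError, match="cyclic"):
            EffectSpec(
                mediations=(
                    MediationSpec(0.4, 0.4, 0.1, mediator=key1, outcome=key2),
                    MediationSpec(0.4, 0.4, 0.1, mediator=key2, outcome=key1),
                )
            )

    def test_infeasible_paths_rejected(self):
        demo = self.demo(100)
        with pytest.raises(ValueError, match="< 1"):
            plant_mediation(demo, self.effects(1.2, 0.1, 0.1), seed=1)
        with pytest.raises(ValueError, match="variance"):
            plant_mediation(demo, self.effects(0.9, 0.9, 0.9), seed=1)

    def test_overconstrained_latent_effect_rejected(self):
        demo = self.demo(100)
        eff = EffectSpec(
            effects=(PlantedEffect(S, Lobe.PREFRONTAL, Lobe.OCCIPITAL, beta_age=1.3),)
        )
        with pytest.raises(ValueError, match="unit variance"):
            planted_strengths(demo, eff, seed=1)


class TestClosedLoop:
    """Generate -> preprocess -> networks -> strengths -> regression recovers
    the planted standardized age effects (at reduced cohort scale)."""

    def test_planted_betas_recovered_through_full_pipeline(self):
        atlas = three_lobe_atlas()
        effects = EffectSpec(
            effects=(
                PlantedEffect(F, Lobe.OCCIPITAL, Lobe.LATERAL_TEMPORAL, beta_age=0.25),
                PlantedEffect(S, Lobe.PREFRONTAL, Lobe.LATERAL_TEMPORAL, beta_age=0.29),
            )
        )
        reps, n = 60, 100
        est_f, est_s = [], []
        for r in range(reps):
            cohort = generate_cohort(
                CohortSpec(n_subjects=n, age_model="uniform", seed=5000 + r),
                effects,
                atlas,
            )
            fn = build_functional_networks(cohort)
            sn = build_structural_networks(cohort)
            sf = [lobe_strength(w, atlas, "occipital", "lateral_temporal") for w in fn]
            ss = [lobe_strength(w, atlas, "prefrontal", "lateral_temporal") for w in sn]
            demo = cohort.demographics
            est_f.append(fit_reduced(sf, demo.age, demo.sex).beta_age)
            est_s.append(fit_reduced(ss, demo.age, demo.sex).beta_age)
        # functional recovery is attenuated by correlation-estimation noise
        # (errors-in-variables); the design keeps that bias inside +-0.05
        assert np.mean(est_f) == pytest.approx(0.25, abs=0.05)
        assert np.mean(est_s) == pytest.approx(0.29, abs=0.05)
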