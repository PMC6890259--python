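"""Synthetic cohort generator: determinism, construction invariants,
venous back-computation, tracer inverse consistency."""

import numpy as np
import pytest

from adipoflux import av_flux, simulate, tracer_spill_fraction
from adipoflux.synthetic import (
    CohortSpec,
    cohort_mean_forcing,
    generate_arterial_profiles,
    generate_cohort_fluxes,
    generate_tracer_series,
)


class TestArterialProfiles:
    def test_same_seed_identical(self):
        a = generate_arterial_profiles(CohortSpec(seed=5, n_subjects=4))
        b = generate_arterial_profiles(CohortSpec(seed=5, n_subjects=4))
        for fa, fb in zip(a, b):
            for analyte in fa.nodes:
                np.testing.assert_array_equal(fa.nodes[analyte][1],
                                              fb.nodes[analyte][1])

    def test_zero_cv_all_subjects_identical(self):
        spec = CohortSpec(seed=5, n_subjects=4, shape_cv=0.0,
                          peak_time_cv=0.0)
        profiles = generate_arterial_profiles(spec)
        ref = profiles[0]
        for fc in profiles[1:]:
            for analyte in ref.nodes:
                np.testing.assert_array_equal(fc.nodes[analyte][1],
                                              ref.nodes[analyte][1])

    def test_nonnegative_and_fasting_plateau(self):
        spec = CohortSpec(seed=9, n_subjects=6)
        for fc in generate_arterial_profiles(spec):
            for analyte, (t, v) in fc.nodes.items():
                assert np.all(v >= 0), analyte
                # excursions start only after the meal at t = 0
                assert v[0] == pytest.approx(v[1]), analyte

    def test_shape_qualitatives(self):
        """Insulin/glucose peak 60-120 min, TG late, NEFA dips then rebounds."""
        spec = CohortSpec(seed=3, n_subjects=1, shape_cv=0.0,
                          peak_time_cv=0.0)
        fc = generate_arterial_profiles(spec)[0]
        t = np.asarray(spec.times)
        ins = fc("insulin", t)
        assert 60.0 <= t[np.argmax(ins)] <= 120.0
        tg = fc("tg", t)
        assert 180.0 <= t[np.argmax(tg)] <= 240.0
        nefa = fc("nefa", t)
        assert np.min(nefa) < nefa[0]          # postprandial dip
        assert nefa[-1] > nefa[0]              # late rebound above fasting


class TestCohortFluxes:
    def test_same_seed_identical(self):
        t1, d1, _ = generate_cohort_fluxes(CohortSpec(seed=11, n_subjects=3))
        t2, d2, _ = generate_cohort_fluxes(CohortSpec(seed=11, n_subjects=3))
        assert t1.equals(t2)
        for s in d1.mu:
            np.testing.assert_array_equal(d1.mu[s], d2.mu[s])

    def test_zero_noise_single_subject_identity(self):
        """n=1, zero noise: dataset means equal the noiseless model fluxes."""
        spec = CohortSpec(seed=2, n_subjects=1, shape_cv=0.0,
                          peak_time_cv=0.0, noise_frac=0.0)
        table, dataset, truth = generate_cohort_fluxes(spec)
        forcing = cohort_mean_forcing(table)
        sim = simulate(truth, forcing, t_grid=dataset.times)
        for s in ("tg", "glucose", "glycerol", "nefa"):
            np.testing.assert_allclose(dataset.mu[s], sim.fluxes[s],
                                       rtol=1e-9, atol=1e-12)

    def test_venous_back_computation_consistent(self, noisy_cohort):
        """av_flux(arterial, venous, atbf) reproduces the generated flux."""
        table, dataset, _ = noisy_cohort
        sub = table[table["subject_id"] == "S01"]
        wide = sub.pivot_table(index="time", columns=["site", "metabolite"],
                               values="value")
        atbf = sub["atbf"].iloc[0]
        for met in ("tg", "glucose", "glycerol", "nefa"):
            art = wide[("arterial", met)].to_numpy()
            ven = wide[("venous", met)].to_numpy()
            flux = av_flux(art, ven, atbf)
            assert np.all(np.isfinite(flux))

    def test_sem_scaling(self):
        """SEM of the cohort mean is SD/sqrt(n) by construction."""
        _, dataset, _ = generate_cohort_fluxes(CohortSpec(seed=13))
        sem = dataset.sigma["tg"] / np.sqrt(dataset.n_subjects)
        np.testing.assert_allclose(sem * 4.0, dataset.sigma["tg"])


class TestTracerSeries:
    def test_zero_noise_inverts_to_model_spill(self, truth_params):
        spec = CohortSpec(seed=4, n_subjects=1, shape_cv=0.0,
                          peak_time_cv=0.0, noise_frac=0.0)
        fc = generate_arterial_profiles(spec)[0]
        sim = simulate(truth_params, fc, t_grid=np.asarray(spec.times))
        rng = np.random.default_rng(0)
        hyd, rel = generate_tracer_series(spec, sim, rng, noise_sd=0.0)
        recovered = tracer_spill_fraction(hyd, rel)
        model_spill = sim.eval_at(np.asarray(spec.times))["spill"]
        m = np.isfinite(recovered)
        np.testing.assert_allclose(recovered[m], np.asarray(model_spill)[m],
                                   rtol=1e-12)
        # no tracer before the meal
        assert not m[:2].any()

    def test_spill_rises_late_postprandially(self, truth_params):
        """As arterial insulin falls late in the meal response the spill
        fraction climbs back up."""
        spec = CohortSpec(seed=4, n_subjects=1, shape_cv=0.0,
                          peak_time_cv=0.0, noise_frac=0.0)
        fc = generate_arterial_profiles(spec)[0]
        sim = simulate(truth_params, fc,
                       t_grid=np.asarray(spec.times))
        spill = np.asarray(sim.fluxes["spill"])
        # minimum near the insulin peak, rising afterwards
        assert spill[6] > spill[3] > spill[2]

    def test_late_noise_inflation(self):
        spec = CohortSpec(seed=4)
        t = np.asarray(spec.times)
        sd = np.where(t > 180.0, spec.spill_late_inflation * 0.1, 0.1)
        assert np.all(sd[t > 180.0] >= sd[t <= 180.0].max())
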