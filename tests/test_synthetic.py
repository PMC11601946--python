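"""Synthetic cohort generator: determinism, stoichiometric fidelity,
configured effect structure."""

import numpy as np
import pandas as pd
import pytest

from chamberlab import calorimetry as cal
from chamberlab import qc, synthetic
from chamberlab.synthetic import SimConfig, simulate_participants, simulate_study, simulate_trace


def noiseless_config(**kw):
    base = dict(trace_noise_sd=0.0, measurement_noise_sd=0.0, mix_jitter_sd=0.0)
    base.update(kw)
    return SimConfig(**base)


class TestDeterminism:
    def test_same_seed_reproduces_study_exactly(self):
        cfg = SimConfig(seed=42, n_participants=4, n_metabolites=12)
        a, b = simulate_study(cfg), simulate_study(cfg)
        pd.testing.assert_frame_equal(a.traces, b.traces)
        pd.testing.assert_frame_equal(a.metabolome, b.metabolome)
        pd.testing.assert_frame_equal(a.nefa, b.nefa)
        assert a.truth.energy_need == b.truth.energy_need

    def test_different_seeds_differ(self):
        a = simulate_study(SimConfig(seed=1, n_participants=3, n_metabolites=8))
        b = simulate_study(SimConfig(seed=2, n_participants=3, n_metabolites=8))
        assert not a.traces["vo2_l_min"].equals(b.traces["vo2_l_min"])


class TestParticipants:
    def test_female_fraction_near_configured(self):
        cfg = SimConfig(n_participants=1000, seed=3)
        participants, _ = simulate_participants(cfg)
        frac = np.mean([p.sex == "F" for p in participants])
        se = np.sqrt(0.2 * 0.8 / 1000)
        assert abs(frac - 0.20) < 3 * se

    def test_empty_cohort_allowed(self):
        participants, need = simulate_participants(SimConfig(n_participants=0))
        assert participants == [] and need == {}

    def test_cohort_is_eligible_by_construction(self):
        from chamberlab.protocol import eligibility_filter
        participants, _ = simulate_participants(SimConfig(n_participants=200, seed=5))
        retained, reasons = eligibility_filter(participants)
        assert len(retained) == 200 and not reasons


class TestTraces:
    def test_pure_fat_day_hits_stoichiometric_rq(self, diets_by_name):
        cfg = noiseless_config()
        tr, _, _ = simulate_trace("P1", diets_by_name["EB"], 2400, cfg,
                                  np.random.default_rng(0),
                                  mix_override=(0, 1, 0), noise=False)
        _, rq24 = cal.aggregate_24h(tr)
        assert rq24 == pytest.approx(1.427 / 2.019, abs=1e-6)

    def test_carb_overfeeding_rq_exceeds_fat_overfeeding(self, diets_by_name):
        cfg = noiseless_config()
        rng = np.random.default_rng(0)
        rqs = {}
        for name in ("CNP", "FNP", "FAST"):
            tr, _, _ = simulate_trace("P1", diets_by_name[name], 2400, cfg, rng,
                                      noise=False)
            rqs[name] = cal.aggregate_24h(tr)[1]
        assert rqs["CNP"] > rqs["FNP"] > rqs["FAST"]

    def test_noiseless_round_trip_recovers_truth(self, diets_by_name):
        cfg = noiseless_config()
        rng = np.random.default_rng(1)
        for name in ("EB", "FAST", "HPF"):
            tr, nitro, truth = simulate_trace("P1", diets_by_name[name], 2200,
                                              cfg, rng, noise=False)
            s = cal.summarize_session(tr, nitro)
            total = truth["carb_g"] + truth["fat_g"] + truth["prot_g"]
            assert s.carbox_g == pytest.approx(truth["carb_g"], abs=0.02 * total)
            assert s.lipox_g == pytest.approx(truth["fat_g"], abs=0.02 * total)
            assert s.protox_g == pytest.approx(truth["prot_g"], abs=0.02 * total)
            assert s.ee24 == pytest.approx(truth["ee_kcal"], rel=0.01)

    def test_nitrogen_consistent_with_protein_oxidised(self, diets_by_name):
        cfg = noiseless_config()
        tr, nitro, truth = simulate_trace("P1", diets_by_name["EB"], 2400, cfg,
                                          np.random.default_rng(2), noise=False)
        assert nitro.nitrogen_g_per_day == pytest.approx(truth["prot_g"] / 6.25)

    def test_meal_bumps_raise_daytime_ee(self, diets_by_name):
        cfg = noiseless_config()
        tr, _, _ = simulate_trace("P1", diets_by_name["EB"], 2400, cfg,
                                  np.random.default_rng(3), noise=False)
        # post-lunch window vs sleeping window
        assert tr.vo2[280:340].mean() > tr.vo2[1100:1300].mean()


class TestMetabolome:
    @staticmethod
    def sessions_frame(n_participants=20, seed=0):
        rng = np.random.default_rng(seed)
        diets = ["EB", "FAST", "SOF", "LPF", "FNP", "HPF", "CNP"]
        rows = []
        for i in range(n_participants):
            for k, d in enumerate(diets):
                rows.append({"participant_id": f"P{i:03d}",
                             "chamber_id": f"P{i:03d}_{d}", "diet": d,
                             "chamber_order": k + 1,
                             "lipox_kcal": 600 + 400 * (d in ("FAST", "FNP", "HPF"))
                             + rng.normal(0, 50)})
        return pd.DataFrame(rows)

    def test_zero_effects_zero_noise_gives_zero_fold_changes(self):
        cfg = SimConfig(n_metabolites=10, participant_sd=0.0, residual_sd=0.0,
                        missing_metabolite_frac=0.0, n_outliers=0,
                        effect_matrix=synthetic.DEFAULT_EFFECT_MATRIX * 0.0,
                        lipox_coupling={c: 0.0 for c in synthetic.METABOLITE_CLASSES})
        panel, _, _ = synthetic.simulate_metabolome(
            self.sessions_frame(), cfg, np.random.default_rng(0))
        fc = qc.log2_fold_change(panel)
        assert np.allclose(fc["log2_fc"], 0.0, atol=1e-9)

    def test_injected_class_effect_recovered_in_mean_fold_change(self):
        eff = synthetic.DEFAULT_EFFECT_MATRIX * 0.0
        eff.loc["FAST", "acylcarnitines"] = 1.0
        cfg = SimConfig(n_metabolites=40, effect_matrix=eff,
                        missing_metabolite_frac=0.0, n_outliers=0,
                        lipox_coupling={c: 0.0 for c in synthetic.METABOLITE_CLASSES})
        sessions = self.sessions_frame(n_participants=40)
        panel, _, _ = synthetic.simulate_metabolome(sessions, cfg,
                                                    np.random.default_rng(1))
        fc = qc.log2_fold_change(panel)
        sub = fc[(fc["diet"] == "FAST") & (fc["met_class"] == "acylcarnitines")
                 & (fc["subclass"] != "bcaa")]
        se = sub["log2_fc"].std(ddof=1) / np.sqrt(len(sub))
        assert abs(sub["log2_fc"].mean() - 1.0) < 3 * se

    def test_injected_outlier_is_flagged_by_qc(self):
        cfg = SimConfig(n_metabolites=12, n_outliers=3, outlier_z=8.0,
                        missing_metabolite_frac=0.0)
        panel, _, truth = synthetic.simulate_metabolome(
            self.sessions_frame(n_participants=50), cfg, np.random.default_rng(2))
        _, log = qc.remove_outliers(panel)
        injected = {(o["metabolite"], o["diet"]) for o in truth.injected_outliers}
        flagged = set(zip(log["metabolite"], log["diet"]))
        assert injected <= flagged

    def test_missingness_injection_counts(self):
        cfg = SimConfig(n_metabolites=40, missing_metabolite_frac=0.10, n_outliers=0)
        panel, _, truth = synthetic.simulate_metabolome(
            self.sessions_frame(), cfg, np.random.default_rng(3))
        assert len(truth.injected_missing) == 4
        retained, excluded = qc.missingness_filter(panel)
        assert sorted(excluded) == sorted(truth.injected_missing)
        assert len(retained) == 36

    def test_sign_pattern_matches_configured_matrix(self):
        cfg = SimConfig(n_participants=50, n_metabolites=80, seed=11,
                        missing_metabolite_frac=0.0, n_outliers=0)
        sessions = self.sessions_frame(n_participants=50, seed=11)
        panel, _, _ = synthetic.simulate_metabolome(sessions, cfg,
                                                    np.random.default_rng(11))
        fc = qc.log2_fold_change(panel)
        fc = fc[fc["subclass"] != "bcaa"]
        observed = fc.groupby(["diet", "met_class"], observed=True)["log2_fc"].mean()
        eff = cfg.resolved_effect_matrix()
        cells = ok = 0
        for diet in eff.index:
            for klass in eff.columns:
                true = eff.loc[diet, klass]
                if true == 0:
                    continue
                cells += 1
                ok += np.sign(observed.loc[(diet, klass)]) == np.sign(true)
        assert ok / cells >= 0.95


class TestNefa:
    def test_zero_slope_zero_noise_means_no_change(self):
        cfg = SimConfig(nefa_lipox_slope=0.0, nefa_noise_sd=0.0)
        sessions = TestMetabolome.sessions_frame()
        nefa, _ = synthetic.simulate_nefa(sessions, cfg, np.random.default_rng(0))
        assert np.allclose(nefa["nefa_pre"], nefa["nefa_post"])

    def test_positive_slope_couples_nefa_to_lipox(self):
        sessions = TestMetabolome.sessions_frame(n_participants=15)  # 105 sessions
        nefa, _ = synthetic.simulate_nefa(sessions, SimConfig(),
                                          np.random.default_rng(1))
        r = np.corrcoef(nefa["nefa_post"], sessions["lipox_kcal"])[0, 1]
        assert r > 0.3

    def test_fasting_sessions_show_largest_nefa_rise(self, study):
        merged = study.nefa.copy()
        merged["delta"] = merged["nefa_post"] - merged["nefa_pre"]
        by_diet = merged.groupby("diet")["delta"].mean()
        assert by_diet.idxmax() == "FAST"


class TestStudyBundle:
    def test_truth_records_every_session(self, study):
        n_sessions = study.nitrogen.shape[0]
        assert len(study.truth.session_substrate_g) == n_sessions
        assert len(study.truth.session_lipox_kcal) == n_sessions
        assert set(study.truth.metabolite_effects) == set(study.metabolome["metabolite"])

    def test_dataset_round_trips_through_disk(self, tmp_path):
        cfg = SimConfig(seed=9, n_participants=3, n_metabolites=10)
        study = simulate_study(cfg)
        study.write(tmp_path)
        for name in ("participants", "schedule", "traces", "nitrogen",
                     "metabolome", "qc_replicates", "nefa"):
            assert (tmp_path / f"{name}.csv").exists()
        reread = pd.read_csv(tmp_path / "traces.csv")
        pd.testing.assert_frame_equal(reread, study.traces)
        assert (tmp_path / "truth.json").exists()
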