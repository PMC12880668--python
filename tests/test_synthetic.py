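"""The virtual-cohort generator: reproducibility, composition, noise level,
defect injection."""

import numpy as np
import pytest

from glucotwin import CohortConfig, build_dataset, generate_cohort, inject_defects


class TestGeneration:
    def test_seed_reproducibility_bytewise(self):
        cfg = CohortConfig(n_patients=2, samples_per_patient=3, seed=7)
        t1, r1 = generate_cohort(cfg)
        t2, r2 = generate_cohort(CohortConfig(n_patients=2, samples_per_patient=3, seed=7))
        assert np.array_equal(t1.draws.Z, t2.draws.Z)
        for pid in r1.patients:
            assert r1.patients[pid].cgm.equals(r2.patients[pid].cgm)
            assert r1.patients[pid].events.equals(r2.patients[pid].events)
            assert r1.patients[pid].hr.equals(r2.patients[pid].hr)

    def test_event_density_matches_study_composition(self, small_cohort):
        """~2.7 meals, ~1.9 boluses, ~0.33 activities per 24 h sample."""
        truth, _ = small_cohort
        n = sum(len(row) for row in truth.events)
        meals = sum(len(e.meals) for row in truth.events for e in row) / n
        boluses = sum(len(e.boluses) for row in truth.events for e in row) / n
        ex = sum(len(e.exercises) for row in truth.events for e in row) / n
        assert 2.3 < meals < 3.1
        assert 1.4 < boluses < 2.4
        assert 0.1 < ex < 0.7

    def test_ground_truth_respects_prior_supports(self, small_cohort):
        truth, _ = small_cohort
        sites = truth.draws.sites
        assert np.all(truth.draws.Z >= sites.lo) and np.all(truth.draws.Z <= sites.hi)

    def test_noise_level_matches_latent_sigma(self):
        cfg = CohortConfig(n_patients=1, samples_per_patient=4, sigma_range=(9.0, 9.0), seed=3)
        truth, raw = generate_cohort(cfg)
        from glucotwin import simulate_sample

        resid_sds = []
        pr = raw.patients["p00"]
        for s in range(4):
            params, events = truth.params[0][s], truth.events[0][s]
            day = pr.cgm.iloc[s * 288:(s + 1) * 288]
            hr = pr.hr.iloc[s * 288:(s + 1) * 288]
            t_min = np.arange(288) * 5.0
            tb = simulate_sample(params, events, t_min, hr["bpm"].to_numpy())
            resid = day["glucose_mgdl"].to_numpy() - tb.sg_at(t_min)
            resid_sds.append(resid.std())
        assert abs(np.mean(resid_sds) - 9.0) / 9.0 < 0.10

    def test_generated_windows_pass_filters_at_designed_rate(self, small_cohort):
        truth, raw = small_cohort
        _, report = build_dataset(raw, min_stride=1440.0)
        assert int(report["passed"].sum()) == truth.manifest["designed_pass_count"]

    def test_truth_json_written(self, small_cohort, tmp_path):
        truth, _ = small_cohort
        truth.to_json(tmp_path / "truth.json")
        import json

        payload = json.loads((tmp_path / "truth.json").read_text())
        assert "latents" in payload and "manifest" in payload
        assert payload["manifest"]["designed_pass_count"] == truth.manifest["designed_pass_count"]


class TestDefectInjection:
    @pytest.fixture()
    def cohort(self):
        return generate_cohort(CohortConfig(n_patients=2, samples_per_patient=5,
                                            sigma_range=(8.0, 10.0), seed=13))

    def test_each_defect_fails_its_rule_only(self, cohort):
        truth, raw = cohort
        spec = [{"patient": "p00", "day": 1, "kind": "gap"},
                {"patient": "p00", "day": 3, "kind": "jump"},
                {"patient": "p01", "day": 0, "kind": "no_meals"},
                {"patient": "p01", "day": 2, "kind": "no_bolus"},
                {"patient": "p01", "day": 4, "kind": "hr_sparse"}]
        bad, expected = inject_defects(raw, spec)
        _, report = build_dataset(bad, min_stride=1440.0)
        failed = report[~report.passed]
        assert len(failed) >= len(spec)
        for e in expected:
            row = report[report.start == e["window_start"]]
            row = row[row.window_id.str.startswith(e["patient"])]
            assert len(row) == 1
            assert not row.iloc[0][f"pass_{e['fails_rule']}"]

    def test_manifest_updates_designed_count(self, cohort):
        truth, raw = cohort
        before = truth.manifest["designed_pass_count"]
        manifest = {k: (dict(v) if isinstance(v, dict) else v) for k, v in truth.manifest.items()}
        _, _ = inject_defects(raw, [{"patient": "p00", "day": 1, "kind": "gap"}], manifest)
        assert manifest["designed_pass_count"] == before - 1

    def test_defect_outside_span_rejected(self, cohort):
        _, raw = cohort
        with pytest.raises(ValueError):
            inject_defects(raw, [{"patient": "p00", "day": 99, "kind": "gap"}])
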