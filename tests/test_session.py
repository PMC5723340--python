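"""Pipeline orchestration, synthetic experts, session persistence."""

import json

import numpy as np
import pytest

from snelicit.fitting import BoundsElicitation, fit_from_bounds
from snelicit.roulette import chips_to_values
from snelicit.session import (
    ElicitationRecord,
    ExpertPanel,
    load_session,
    run_five_steps,
    save_session,
    simulate_expert,
)
from snelicit.skewnorm import SkewNormal, quantile
from snelicit.transform import ScaleSpec

OWN = ScaleSpec(1.0, 0.0, "own")


class TestSimulateExpert:
    def test_seed_determinism(self):
        d = SkewNormal(10.0, 1.0, 2.0)
        g1 = simulate_expert(d, 50, 6.0, 16.0, seed=3)
        g2 = simulate_expert(d, 50, 6.0, 16.0, seed=3)
        assert g1 == g2

    def test_chips_within_range_and_fit_ready(self):
        g = simulate_expert(SkewNormal(10.0, 1.0, 2.0), 30, 6.0, 16.0, seed=9)
        cols = g.columns
        assert cols.min() == 0 and cols.max() == g.n_columns - 1
        assert np.all((0 <= cols) & (cols < g.n_columns))
        assert g.is_fit_ready()

    def test_large_n_recovers_shape(self):
        # 200 chips from a shape-2 generator; the median recovered shape
        # over five seeds absorbs per-draw sampling noise
        from snelicit.fitting import fit_shape

        d = SkewNormal(10.0, 1.0, 2.0)
        lo, hi = quantile(0.002, d), quantile(0.998, d)
        shapes = [
            fit_shape(chips_to_values(simulate_expert(d, 200, lo, hi, seed=s))).shape
            for s in range(5)
        ]
        assert 1.6 <= float(np.median(shapes)) <= 2.4

    def test_insufficient_coverage_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            simulate_expert(SkewNormal(10.0, 5.0, 1.0), 20, 9.0, 11.0, seed=1)

    def test_too_few_chips_rejected(self):
        with pytest.raises(ValueError):
            simulate_expert(SkewNormal(10.0, 1.0, 1.0), 5, 5.0, 15.0, seed=1)


class TestRunFiveSteps:
    def test_grid_path_symmetric_stays_symmetric(self):
        grid = simulate_expert(SkewNormal(10.0, 1.0, 1.0), 150, 5.0, 15.0, seed=4)
        rec = run_five_steps(
            expert_id="e1", scale=OWN, target_scale=OWN,
            bounds=(8.0, 12.0), grid=grid,
        )
        assert rec.step2_fit is not None and rec.step4_prior is not None
        assert rec.step4_prior.shape == pytest.approx(1.0, abs=0.15)

    def test_direct_path_equals_bounds_fit_after_transform(self):
        per_type = ScaleSpec(1.0 / 9.0, 0.0, "per-type")
        total = ScaleSpec(1.0, 0.0, "total")
        rec = run_five_steps(
            expert_id="e2", scale=per_type, target_scale=total,
            bounds=(180.0, 260.0), mu0=23.0,
        )
        direct = fit_from_bounds(BoundsElicitation(207.0, 180.0, 260.0))
        assert rec.step1_grid is None and rec.step2_fit is None
        assert rec.step4_prior.mean == pytest.approx(direct.mean)
        assert rec.step4_prior.sd == pytest.approx(direct.sd, rel=1e-6)
        assert rec.step4_prior.shape == pytest.approx(direct.shape, rel=1e-4)

    def test_iteration_log_records_each_fit(self):
        grid = simulate_expert(SkewNormal(10.0, 1.0, 1.0), 100, 5.0, 15.0, seed=8)
        rec = run_five_steps(
            expert_id="e3", scale=OWN, target_scale=OWN,
            bounds=(8.0, 12.0), grid=grid,
        )
        assert [it["step"] for it in rec.iterations] == [2, 4]
        assert rec.iterations[-1]["fit"] == rec.step4_prior

    def test_requires_exactly_one_entry_path(self):
        with pytest.raises(ValueError, match="exactly one"):
            run_five_steps(scale=OWN, target_scale=OWN, bounds=(0.0, 1.0))

    def test_stage_errors_are_labeled(self):
        with pytest.raises(ValueError, match="steps 3-4"):
            run_five_steps(
                scale=OWN, target_scale=OWN, bounds=(12.0, 11.0), mu0=10.0
            )

    def test_panel_level_mean_recovery(self):
        # ten seeded synthetic experts; the mean recovery error across the
        # panel stays within 0.1 sigma (a single 100-chip elicitation has
        # sampling error of exactly sigma/10, so recovery is a panel-level
        # property; each pipeline individually stays within 3.5 such SEs)
        mu, sigma = 10.0, 1.5
        errors = []
        for seed in range(10):
            gamma = 0.5 + 1.5 * (seed / 9)
            d = SkewNormal(mu, sigma, gamma)
            lo, hi = quantile(0.001, d), quantile(0.999, d)
            grid = simulate_expert(d, 100, lo, hi, seed=seed)
            bounds = (quantile(0.05, d), quantile(0.95, d))
            rec = run_five_steps(
                expert_id=f"e{seed}", scale=OWN, target_scale=OWN,
                bounds=bounds, grid=grid,
            )
            errors.append(rec.step4_prior.mean - mu)
        errors = np.asarray(errors)
        assert np.all(np.abs(errors) < 0.35 * sigma)
        assert abs(errors.mean()) < 0.1 * sigma


class TestPersistence:
    def _panel(self):
        grid = simulate_expert(SkewNormal(10.0, 1.0, 1.5), 60, 5.0, 16.0, seed=2)
        recs = [
            run_five_steps(expert_id="e1", scale=OWN, target_scale=OWN,
                           bounds=(8.0, 12.0), grid=grid),
            run_five_steps(expert_id="e2", scale=ScaleSpec(2.0, 0.0, "double"),
                           target_scale=OWN, bounds=(3.0, 7.0), mu0=9.0),
        ]
        post = SkewNormal(2.29, 0.10, 0.99)
        return ExpertPanel(recs, OWN, posterior=post)

    def test_round_trip_bit_exact(self, tmp_path):
        panel = self._panel()
        path = tmp_path / "session.json"
        save_session(panel, path)
        loaded = load_session(path)
        assert loaded.common_scale == panel.common_scale
        assert loaded.posterior == panel.posterior
        for a, b in zip(loaded.records, panel.records):
            assert a.expert_id == b.expert_id
            assert a.step1_grid == b.step1_grid
            assert a.step2_fit == b.step2_fit
            assert a.step3_bounds == b.step3_bounds
            assert a.step4_prior == b.step4_prior

    def test_save_is_deterministic(self, tmp_path):
        panel = self._panel()
        p1, p2 = tmp_path / "a.json", tmp_path / "b.json"
        save_session(panel, p1)
        save_session(panel, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_version_mismatch_rejected(self, tmp_path):
        path = tmp_path / "v.json"
        save_session(self._panel(), path)
        doc = json.loads(path.read_text())
        doc["version"] = 99
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="version"):
            load_session(path)

    def test_invalid_bounds_in_file_rejected(self, tmp_path):
        path = tmp_path / "bad.json"
        save_session(self._panel(), path)
        doc = json.loads(path.read_text())
        doc["records"][1]["step3_bounds"]["upper"] = -1e9
        path.write_text(json.dumps(doc))
        with pytest.raises(ValueError, match="step3_bounds"):
            load_session(path)

    def test_duplicate_expert_ids_rejected(self):
        rec = run_five_steps(expert_id="e1", scale=OWN, target_scale=OWN,
                             bounds=(8.0, 12.0), mu0=10.0)
        rec2 = ElicitationRecord(expert_id="e1", scale=OWN)
        with pytest.raises(ValueError, match="unique"):
            ExpertPanel([rec, rec2], OWN)

    def test_prior_without_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            ElicitationRecord(
                expert_id="x", scale=OWN,
                step4_prior=SkewNormal(0.0, 1.0, 1.0),
            )
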