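"""Active-learning loop, refinement, target matching, baseline, islands."""

import numpy as np
import pytest

from lols import (
    ConformerRecord,
    RunConfig,
    VAEConfig,
    VAEModel,
    generate_initial_data,
    make_rectangle,
    map_latent_islands,
    match_targets,
    oracle_targets,
    refine_candidates,
    run_lols,
    run_parallel,
    run_real_space_baseline,
    stop_check,
)

FULL2 = [(0.0, 360.0, True)] * 2

QUICK = dict(
    initdata=50,
    max_iterations=4,
    energy_model_interval=2,
    batch_size=20,
    beta=-1.0,
    layersize=32,
    vae_epochs=1500,
    vae_patience=500,
)


@pytest.fixture(scope="module")
def targets2(pes2):
    return oracle_targets(pes2, window=0.25)


class TestInitialData:
    def test_in_range_valid_and_seeded(self, pes2):
        p1 = generate_initial_data(pes2, pes2.ranges, 40, seed=5)
        p2 = generate_initial_data(pes2, pes2.ranges, 40, seed=5)
        assert len(p1) == 40
        ang = p1.angles()
        assert np.all(ang >= 0.0) and np.all(ang <= 360.0)
        assert np.array_equal(ang, p2.angles())
        assert np.array_equal(p1.energies(), p2.energies())

    def test_invalid_draws_resampled(self, pes2):
        from lols import CallableBackend

        backend = CallableBackend(
            lambda a: None if a[0] < 180.0 else float(pes2.energy(a))
        )
        pool = generate_initial_data(backend, pes2.ranges, 25, seed=0)
        assert len(pool) == 25
        assert np.all(pool.angles()[:, 0] >= 180.0)


@pytest.fixture(scope="module")
def result(pes2, targets2):
    cfg = RunConfig(seed=0, **QUICK)
    return run_lols(pes2, pes2.ranges, cfg, targets=targets2)


class TestRunLols:
    def test_pool_bookkeeping_identity(self, result):
        c = result.counters
        # pool size = initdata + sum of valid batch draws = single count
        assert len(result.pool) == c["single"]
        n_iters = result.pool.frame["iteration"].max()
        assert c["single"] + c["invalid"] == 50 + 20 * n_iters

    def test_model_fit_schedule(self, pes2):
        cfg = RunConfig(seed=1, **{**QUICK, "max_iterations": 4})
        res = run_lols(pes2, pes2.ranges, cfg)  # no targets: runs to M
        # fits at t = 2, 4 (M divisible by k -> M//k fits)
        assert [s["iteration"] for s in res.curve] == [2, 4]

    def test_candidates_banked_across_models(self, result):
        tags = {tag for _, _, tag in result.candidates}
        assert len(tags) >= 1
        assert all(tag.startswith("run0/model_t") for tag in tags)

    def test_conformers_sorted_with_nonnegative_relative_energy(self, result):
        rel = [c.relative_energy for c in result.conformers]
        assert rel == sorted(rel)
        assert all(r >= 0.0 for r in rel)
        assert rel[0] == 0.0

    def test_finds_oracle_global_minimum(self, result):
        assert result.report["global_min_found"]

    def test_end_to_end_determinism(self, pes2, targets2, result):
        res2 = run_lols(
            pes2, pes2.ranges, RunConfig(seed=0, **QUICK), targets=targets2
        )
        assert len(res2.conformers) == len(result.conformers)
        for a, b in zip(res2.conformers, result.conformers):
            assert np.array_equal(a.angles, b.angles)
            assert a.energy == b.energy

    def test_latent_snapshots_recorded(self, result):
        assert all(s["L"] > 0 for s in result.latent_snapshots)

    def test_abort_on_high_invalid_rate(self, pes2):
        from lols import CallableBackend

        calls = {"n": 0}

        def dying_engine(a):
            calls["n"] += 1
            # engine fails permanently after the initial pool is built
            return float(pes2.energy(a)) if calls["n"] <= 20 else None

        flaky = CallableBackend(dying_engine)
        cfg = RunConfig(seed=0, **{**QUICK, "initdata": 20})
        with pytest.raises(RuntimeError, match="rejected"):
            run_lols(flaky, pes2.ranges, cfg)


class TestRefine:
    def test_candidate_at_minimum_unchanged(self, pes2, oracle2):
        angles, energy = oracle2[0]
        records = refine_candidates([(angles, 0.0)], pes2, pes2.ranges)
        assert len(records) == 1
        assert records[0].energy == pytest.approx(energy, abs=1e-8)
        assert np.abs(records[0].angles - angles).max() < 1e-3

    def test_synthetic_candidates_all_converge(self, pes2, oracle2):
        rng = np.random.default_rng(8)
        cands = [
            (a + rng.uniform(-10, 10, 2), 0.0) for a, _ in oracle2
        ]
        records, stats = refine_candidates(
            cands, pes2, pes2.ranges, return_stats=True
        )
        assert stats["converged"] == stats["relaxed"] == len(cands)
        # perturbed starts all fall back into their oracle basins
        assert len(records) == len(oracle2)

    def test_nonconverged_candidates_excluded(self, pes2, oracle2):
        records, stats = refine_candidates(
            [(oracle2[0][0] + 25.0, 0.0)], pes2, pes2.ranges,
            max_steps=1, force_tol=1e-12, return_stats=True,
        )
        assert stats["converged"] == 0
        assert records == []


class TestMatchTargets:
    TARGETS = [
        (np.array([100.0, 200.0]), -1.0),  # global minimum
        (np.array([300.0, 40.0]), -0.5),
    ]

    def test_within_15_everywhere_is_achieved(self):
        results = [(np.array([114.0, 214.0]), -1.0)]
        rep = match_targets(results, self.TARGETS, FULL2)
        assert rep["achieved"] == 1 and rep["global_min_found"]

    def test_single_dimension_over_15_misses(self):
        results = [(np.array([116.0, 200.0]), -1.0)]  # mean diff 8 < 15
        rep = match_targets(results, self.TARGETS, FULL2)
        assert rep["achieved"] == 0

    def test_new_conformers_counted_below_energy_cap(self):
        results = [
            (np.array([10.0, 10.0]), -0.7),  # new, below cap -0.5
            (np.array([50.0, 120.0]), -0.1),  # above cap: not counted
        ]
        rep = match_targets(results, self.TARGETS, FULL2)
        assert rep["new"] == 1

    def test_empty_target_list(self):
        rep = match_targets([(np.array([0.0, 0.0]), -2.0)], [], FULL2)
        assert rep["n_targets"] == 0
        assert rep["new"] == 1

    def test_accepts_conformer_records(self):
        recs = [ConformerRecord(np.array([100.0, 200.0]), -1.0, 0.0)]
        assert match_targets(recs, self.TARGETS, FULL2)["achieved"] == 1


class TestStopCheck:
    def test_eight_of_eleven_with_global_min(self):
        rep = {
            "n_targets": 11,
            "achieved_fraction": 8 / 11,
            "global_min_found": True,
        }
        assert stop_check(rep) is True

    def test_global_min_missing_blocks_stop(self):
        rep = {
            "n_targets": 11,
            "achieved_fraction": 1.0,
            "global_min_found": False,
        }
        assert stop_check(rep) is False

    def test_disabled_without_targets(self):
        assert stop_check({"n_targets": 0}) is False


class TestBaseline:
    def test_sample_accounting_and_determinism(self, pes2, targets2):
        cfg = RunConfig(seed=3, **QUICK)
        res = run_real_space_baseline(pes2, pes2.ranges, cfg, targets=targets2)
        assert len(res.pool) == 50 + 4 * 20 - res.counters["invalid"]
        res2 = run_real_space_baseline(pes2, pes2.ranges, cfg, targets=targets2)
        assert np.array_equal(res.pool.angles(), res2.pool.angles())

    def test_separable_pes_all_minima_found(self, pes2_separable):
        cfg = RunConfig(
            seed=0, initdata=100, max_iterations=4, batch_size=100,
            energy_model_interval=4, layersize=16, vae_epochs=10,
        )
        targets = oracle_targets(pes2_separable, window=1.0)
        res = run_real_space_baseline(
            pes2_separable, pes2_separable.ranges, cfg, targets=targets
        )
        assert res.report["achieved"] == 4


class TestParallelRuns:
    def test_merged_achieved_at_least_each_run(self, pes2, targets2):
        cfg = RunConfig(**QUICK)
        records, report, results = run_parallel(
            pes2, pes2.ranges, cfg, seeds=[0, 1, 2], targets=targets2
        )
        for res in results:
            assert report["achieved"] >= res.report.get("achieved", 0)
        assert report["single"] == sum(r.counters["single"] for r in results)
        rel = [c.relative_energy for c in records]
        assert rel == sorted(rel)

    def test_accumulative_curve_nondecreasing(self, pes2, targets2):
        cfg = RunConfig(seed=4, **{**QUICK, "max_iterations": 6,
                                   "energy_model_interval": 2})
        res = run_lols(pes2, pes2.ranges, cfg, targets=targets2)
        achieved = [s["achieved"] for s in res.curve if "achieved" in s]
        assert all(b >= a for a, b in zip(achieved, achieved[1:]))


class TestLatentIslands:
    def _constant_decoder(self, target_normalized):
        model = VAEModel(VAEConfig(input_dim=2, layersize=8, seed=0))
        model.params["out_w"][:] = 0.0
        model.params["out_b"][:] = np.asarray(target_normalized)
        return model

    def test_constant_decoder_fills_whole_grid(self):
        # decoder pinned to a target -> every grid point assigned to it
        model = self._constant_decoder([0.0, 0.0])  # 180, 180 deg
        rect = make_rectangle(np.array([[0.0, 0.0], [1.0, 1.0]]))
        report = map_latent_islands(
            model, rect, FULL2,
            targets=[(np.array([180.0, 180.0]), -1.0)],
            grid_n=20,
        )
        assert report["total_fraction"] == pytest.approx(1.0)

    def test_no_decoded_point_near_targets_gives_zero(self):
        model = self._constant_decoder([0.0, 0.0])
        rect = make_rectangle(np.array([[0.0, 0.0], [1.0, 1.0]]))
        report = map_latent_islands(
            model, rect, FULL2,
            targets=[(np.array([30.0, 30.0]), -1.0)],
            grid_n=20,
        )
        assert report["total_fraction"] == 0.0

    def test_energy_window_filters_targets(self):
        model = self._constant_decoder([0.0, 0.0])
        rect = make_rectangle(np.array([[0.0, 0.0], [1.0, 1.0]]))
        report = map_latent_islands(
            model, rect, FULL2,
            targets=[
                (np.array([30.0, 30.0]), 0.0),
                (np.array([180.0, 180.0]), 0.9),  # outside 0.5 eV window
            ],
            grid_n=10,
        )
        assert report["n_targets"] == 1
        assert report["total_fraction"] == 0.0

    def test_area_fractions_sum_at_most_one(self, pes2, targets2):
        rng = np.random.default_rng(0)
        model = VAEModel(VAEConfig(input_dim=2, layersize=16, seed=1))
        rect = make_rectangle(rng.normal(0, 1, (50, 2)))
        report = map_latent_islands(model, rect, pes2.ranges, targets2,
                                    grid_n=30)
        assert 0.0 <= report["total_fraction"] <= 1.0
        assert sum(report["per_target_fraction"]) == pytest.approx(
            report["total_fraction"]
        )
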