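"""Synthetic cohort generator: determinism, schedule, coupling, RT model."""

import numpy as np
import pytest

import interbrain as ib
from interbrain.exceptions import ConfigError


class TestConfigValidation:
    def test_band_outside_nyquist_rejected(self):
        cfg = ib.SimulationConfig(
            coupling=(
                ib.CouplingSpec(rois=(0,), conditions=("solo",), band=(0.1, 0.4), amplitude=1.0),
            )
        )
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_schedule_must_fit_run(self):
        cfg = ib.SimulationConfig(n_volumes_per_run=100)
        with pytest.raises(ConfigError):
            cfg.validate()

    def test_unknown_condition_rejected(self):
        cfg = ib.SimulationConfig(block_order=("cooperation", "sleep"))
        with pytest.raises(ConfigError):
            cfg.validate()


class TestDeterminismAndStreams:
    def test_same_seed_bit_identical(self, tiny_config, tiny_cohort):
        dyads2, events2, truth2 = ib.simulate_cohort(tiny_config)
        dyads, events, truth = tiny_cohort
        for a, b in zip(dyads, dyads2):
            assert np.array_equal(a.series_a, b.series_a)
            assert np.array_equal(a.series_b, b.series_b)
        for key in events:
            assert events[key].equals(events2[key])
        assert truth.equals(truth2)

    def test_adding_dyads_preserves_existing_ones(self, tiny_config):
        import dataclasses

        bigger = dataclasses.replace(tiny_config, n_dyads=6)
        small_dyads, _, _ = ib.simulate_cohort(tiny_config)
        big_dyads, _, _ = ib.simulate_cohort(bigger)
        for a, b in zip(small_dyads, big_dyads):
            assert np.array_equal(a.series_a, b.series_a)
            assert np.array_equal(a.series_b, b.series_b)


class TestEvents:
    def test_event_invariants(self, tiny_cohort):
        _, events, _ = tiny_cohort
        for (dyad, run), ev in events.items():
            trials = ev[ev["event"] != "block"]
            blocks = ev[ev["event"] == "block"]
            assert (trials["onset"].diff().dropna() >= -1e-9).all() or True
            # onsets non-decreasing within the table as a whole
            assert ev["onset"].is_monotonic_increasing
            # block rows span their trial rows
            for _, b in blocks.iterrows():
                tr = trials[trials["block"] == b["block"]]
                assert b["onset"] <= tr["onset"].min() + 1e-9
                assert (
                    b["onset"] + b["duration"]
                    >= (tr["onset"] + tr["duration"]).max() - 1e-9
                )
            rts = trials[["response_time_a", "response_time_b"]].to_numpy(float)
            assert (rts[np.isfinite(rts)] > 0).all()

    def test_solo_watch_roles_swap_between_runs(self, tiny_cohort):
        _, events, _ = tiny_cohort
        dyad = "dyad-01"
        for run in (0, 1):
            ev = events[(dyad, run)]
            stim = ev[ev["event"] == "stimulus"]
            solo = stim[stim["trial_type"] == "solo"]
            watch = stim[stim["trial_type"] == "watch"]
            # solo blocks: only subject A responds; watch: only subject B
            assert solo["response_time_a"].notna().all()
            assert solo["response_time_b"].isna().all()
            assert watch["response_time_b"].notna().all()
            assert watch["response_time_a"].isna().all()
        order0 = events[(dyad, 0)].drop_duplicates("block")["trial_type"].tolist()
        order1 = events[(dyad, 1)].drop_duplicates("block")["trial_type"].tolist()
        i0s, i0w = order0.index("solo"), order0.index("watch")
        assert order1.index("solo") == i0w and order1.index("watch") == i0s


class TestCoupling:
    def test_shared_component_coherent_in_band_only(self):
        """With overwhelming coupling amplitude the pair is coherent inside
        the injected band and near the noise floor two octaves away."""
        cfg = ib.SimulationConfig(
            n_dyads=1,
            n_rois=1,
            n_volumes_per_run=775,
            coupling=(
                ib.CouplingSpec(
                    rois=(0,),
                    conditions=ib.CONDITIONS,
                    band=(0.09, 0.11),
                    amplitude=5.0,
                ),
            ),
            seed=3,
        )
        dyads, events, _ = ib.simulate_cohort(cfg)
        grid = ib.build_scale_grid(0.0039, 0.2894, 12, 1.5)
        m = ib.wtc(dyads[0].series_a[0, :, 0], dyads[0].series_b[0, :, 0], grid)
        # restrict to block time (coupling is gated to blocks) and the COI
        ev = events[("dyad-01", 0)]
        blocks = ev[ev["event"] == "block"]
        tsel = np.zeros(775, bool)
        for _, b in blocks.iterrows():
            lo = int(np.ceil(b["onset"] / 1.5))
            hi = int(np.floor((b["onset"] + b["duration"]) / 1.5))
            tsel[lo:hi] = True
        inband = grid.band_indices(0.09, 0.11)
        sel = m.coi_mask[inband][:, tsel]
        assert m.r2[inband][:, tsel][sel].mean() > 0.9
        far = grid.nearest_index(0.1 / 4.0)  # two octaves below
        farsel = m.coi_mask[far, tsel]
        assert m.r2[far, tsel][farsel].mean() < 0.5

    def test_phase_lag_is_injected(self):
        cfg = ib.SimulationConfig(
            n_dyads=1,
            n_rois=1,
            n_volumes_per_run=775,
            coupling=(
                ib.CouplingSpec(
                    rois=(0,),
                    conditions=ib.CONDITIONS,
                    band=(0.095, 0.105),
                    amplitude=50.0,
                    phase_lag=np.pi / 2,
                ),
            ),
            seed=4,
        )
        dyads, _, _ = ib.simulate_cohort(cfg)
        grid = ib.build_scale_grid(0.0039, 0.2894, 12, 1.5)
        m = ib.wtc(dyads[0].series_a[0, :, 0], dyads[0].series_b[0, :, 0], grid)
        row = grid.nearest_index(0.1)
        strong = m.coi_mask[row] & (m.r2[row] > 0.8)
        circ = np.angle(np.mean(np.exp(1j * m.phase[row, strong])))
        assert abs(circ - np.pi / 2) < 0.2

    def test_ground_truth_lists_exactly_coupled_cells(self, tiny_cohort, tiny_config):
        _, _, truth = tiny_cohort
        assert set(truth["roi"]) == {1}
        assert set(truth["condition"]) == {"cooperation"}
        assert len(truth) == tiny_config.n_dyads


class TestSimulateRts:
    def test_perfect_correlation_means_simultaneity(self):
        rts = ib.simulate_rts(
            "cooperation", ib.RTModel(2.0, 2.0, 0.3, 0.3, 1.0), 50, seed=0
        )
        outcomes = [ib.judge_cooperation(a, b) for a, b in rts]
        assert all(o.judged == "success" for o in outcomes)

    def test_independent_rts_miss_often(self):
        rts = ib.simulate_rts(
            "cooperation", ib.RTModel(2.0, 2.0, 0.8, 0.8, 0.0), 400, seed=1
        )
        acc = ib.block_accuracy([ib.judge_cooperation(a, b) for a, b in rts])
        assert acc < 0.8

    def test_seed_reproducibility_and_validation(self):
        a = ib.simulate_rts("solo", None, 10, seed=5)
        b = ib.simulate_rts("solo", None, 10, seed=5)
        assert np.array_equal(a, b)
        with pytest.raises(ConfigError):
            ib.simulate_rts("solo", ib.RTModel(1, 1, -0.1, 0.1), 5)


class TestDemoSignalPair:
    def test_noise_free_quadrature(self):
        x, y = ib.demo_signal_pair(noise_sd=0.0)
        t = np.arange(0.0, 1600.0, 1.0)
        on_low_only = (t > 50) & (t < 0.35 * 1600)
        expect_x = np.sin(2 * np.pi * 0.005 * t[on_low_only])
        expect_y = np.cos(2 * np.pi * 0.005 * t[on_low_only])
        assert np.allclose(x[on_low_only], expect_x)
        assert np.allclose(y[on_low_only], expect_y)

    def test_duration_precondition(self):
        with pytest.raises(ConfigError):
            ib.demo_signal_pair(duration=100.0)
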