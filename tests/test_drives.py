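"""Exogenous drive routing and event-train sampling."""

import numpy as np
import pytest

from neocolumn.drives import (
    EvokedDriveSpec,
    PoissonDriveSpec,
    RhythmicDriveSpec,
    TonicDriveSpec,
    route_drive,
    sample_evoked_events,
    sample_poisson_events,
    sample_rhythmic_events,
    tonic_current,
)
from neocolumn.network import build_network


class TestRouting:
    def test_distal_skips_l5_baskets(self, tiny_network):
        targets = route_drive("distal", tiny_network)
        pops = {p for _, p, _ in targets}
        assert "L5_basket" not in pops
        assert {"L2_pyramidal", "L5_pyramidal", "L2_basket"} <= pops

    def test_proximal_reaches_basal_oblique_of_every_pn(self, tiny_network):
        targets = route_drive("proximal", tiny_network)
        pn_gids = {
            c.gid for c in tiny_network.cells if c.cell_class != "Basket"
        }
        reached = {}
        for gid, pop, comp in targets:
            if gid in pn_gids:
                reached.setdefault(gid, set()).add(comp)
        assert set(reached) == pn_gids
        for comps in reached.values():
            assert comps == {"Bdend1", "Bdend2", "Bdend3", "Adend_oblique"}

    def test_toy_network_hand_enumeration(self):
        # 2x2 grid: 4 PNs and 1 basket per layer (3:1 rounding)
        net = build_network(2, 2)
        distal = route_drive("distal", net)
        expected = set()
        for c in net.cells:
            if c.population in ("L2_pyramidal", "L5_pyramidal"):
                expected.add((c.gid, c.population, "Adend_tuft"))
            elif c.population == "L2_basket":
                expected.add((c.gid, c.population, "soma"))
        assert set(distal) == expected
        assert len([x for x in distal if x[1] == "L2_basket"]) == 1

    def test_unknown_class_rejected(self, tiny_network):
        with pytest.raises(ValueError, match="oblique_only"):
            route_drive("oblique_only", tiny_network)


class TestEvoked:
    def _spec(self, **kw):
        defaults = dict(
            name="ev1",
            drive_class="proximal",
            start_time_mean=25.0,
            start_time_stdev=2.5,
            n_spikes_per_synapse=1,
            weights={("L2_pyramidal", "ampa"): 1e-3},
        )
        defaults.update(kw)
        return EvokedDriveSpec(**defaults)

    def test_zero_stdev_exact_times(self, tiny_network):
        spec = self._spec(start_time_stdev=0.0)
        trains = sample_evoked_events(spec, tiny_network, duration=100.0)
        assert trains
        for tr in trains:
            assert np.allclose(tr.times, 25.0)

    def test_synchronous_shares_one_draw(self, tiny_network):
        spec = self._spec(synchronous=True)
        trains = sample_evoked_events(spec, tiny_network, duration=100.0)
        times = {tuple(tr.times) for tr in trains}
        assert len(times) == 1

    def test_async_draws_differ_across_cells(self, tiny_network):
        spec = self._spec(
            weights={
                ("L2_pyramidal", "ampa"): 1e-3,
                ("L5_pyramidal", "ampa"): 1e-3,
            }
        )
        trains = sample_evoked_events(spec, tiny_network, duration=100.0)
        per_cell = {tr.target_gid: tuple(tr.times) for tr in trains}
        assert len(set(per_cell.values())) > 1

    def test_sample_mean_matches_distribution(self, tiny_network):
        # Monte-Carlo: mean of many draws within 3 standard errors
        spec = self._spec()
        draws = []
        for trial in range(400):
            trains = sample_evoked_events(
                spec, tiny_network, trial_index=trial, duration=1000.0
            )
            # one independent draw per cell (compartments share the draw)
            per_cell = {tr.target_gid: tr.times[0] for tr in trains}
            draws.extend(per_cell.values())
        draws = np.array(draws)
        se = 2.5 / np.sqrt(len(draws))
        assert abs(draws.mean() - 25.0) < 3 * se

    def test_trial_increment_shifts_mean(self, tiny_network):
        spec = self._spec(start_time_stdev=0.0, increment_per_trial=10.0)
        t0 = sample_evoked_events(spec, tiny_network, trial_index=0,
                                  duration=200.0)
        t2 = sample_evoked_events(spec, tiny_network, trial_index=2,
                                  duration=200.0)
        assert np.allclose(t0[0].times + 20.0, t2[0].times)

    def test_distal_with_l5_basket_weight_rejected(self):
        with pytest.raises(ValueError):
            EvokedDriveSpec(
                "bad", "distal", 25.0, 1.0,
                weights={("L5_basket", "ampa"): 1e-3},
            )

    def test_reproducible_and_trial_dependent(self, tiny_network):
        spec = self._spec()
        a = sample_evoked_events(spec, tiny_network, trial_index=1,
                                 master_seed=7, duration=100.0)
        b = sample_evoked_events(spec, tiny_network, trial_index=1,
                                 master_seed=7, duration=100.0)
        c = sample_evoked_events(spec, tiny_network, trial_index=2,
                                 master_seed=7, duration=100.0)
        assert all(
            np.array_equal(x.times, y.times) for x, y in zip(a, b)
        )
        assert any(
            not np.array_equal(x.times, y.times) for x, y in zip(a, c)
        )


class TestRhythmic:
    def _spec(self, **kw):
        defaults = dict(
            name="rhy",
            drive_class="proximal",
            start_time_mean=50.0,
            start_time_stdev=0.0,
            stop_time=1050.0,
            burst_frequency=10.0,
            burst_stdev=0.0,
            spikes_per_burst=1,
            n_bursts=1,
            weights={("L2_pyramidal", "ampa"): 1e-4},
        )
        defaults.update(kw)
        return RhythmicDriveSpec(**defaults)

    def test_zero_jitter_strictly_periodic(self, tiny_network):
        spec = self._spec()
        trains = sample_rhythmic_events(spec, tiny_network, duration=1050.0)
        t = trains[0].times
        assert np.allclose(np.diff(t), 100.0)

    def test_mean_interburst_interval(self, tiny_network):
        # Monte-Carlo over many sampled trains
        spec = self._spec(burst_stdev=5.0)
        intervals = []
        for trial in range(300):
            trains = sample_rhythmic_events(
                spec, tiny_network, trial_index=trial, duration=1050.0
            )
            intervals.extend(np.diff(np.sort(trains[0].times)))
        m = np.mean(intervals)
        se = np.std(intervals) / np.sqrt(len(intervals))
        assert abs(m - 100.0) < max(3 * se, 1.0)

    def test_repeats_accumulate(self, tiny_network):
        one = self._spec(n_bursts=1)
        five = self._spec(n_bursts=5)
        t1 = sample_rhythmic_events(one, tiny_network, duration=1050.0)
        t5 = sample_rhythmic_events(five, tiny_network, duration=1050.0)
        assert len(t5[0].times) == 5 * len(t1[0].times)

    def test_stop_before_start_empty(self, tiny_network):
        spec = self._spec(stop_time=10.0)
        trains = sample_rhythmic_events(spec, tiny_network, duration=1050.0)
        assert all(len(tr.times) == 0 for tr in trains)

    def test_rejects_zero_frequency(self):
        with pytest.raises(ValueError):
            self._spec(burst_frequency=0.0)


class TestPoisson:
    def test_zero_rate_empty(self, tiny_network):
        spec = PoissonDriveSpec(
            "p", rates={"L2_pyramidal": 0.0},
            weights={("L2_pyramidal", "ampa"): 1e-3},
        )
        trains = sample_poisson_events(spec, tiny_network, duration=500.0)
        assert all(len(tr.times) == 0 for tr in trains)

    def test_event_count_matches_rate(self, tiny_network):
        # 140 Hz for 550 ms: expectation 77 events per target
        spec = PoissonDriveSpec(
            "p", rates={"L2_pyramidal": 140.0},
            weights={("L2_pyramidal", "ampa"): 1e-3},
        )
        counts = []
        for trial in range(150):
            trains = sample_poisson_events(
                spec, tiny_network, trial_index=trial, duration=550.0
            )
            counts.extend(len(tr.times) for tr in trains)
        mean = np.mean(counts)
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(mean - 77.0) < 3 * se

    def test_stop_minus_one_spans_duration(self, tiny_network):
        spec = PoissonDriveSpec(
            "p", rates={"L2_pyramidal": 500.0},
            weights={("L2_pyramidal", "ampa"): 1e-3}, stop=-1.0,
        )
        trains = sample_poisson_events(spec, tiny_network, duration=800.0)
        tmax = max(tr.times.max() for tr in trains if len(tr.times))
        assert tmax > 700.0
        assert tmax <= 800.0


class TestTonic:
    def test_window(self):
        spec = TonicDriveSpec(
            "t", amplitudes={"L5_pyramidal": 1.0}, start=100.0, stop=200.0
        )
        assert tonic_current(spec, "L5_pyramidal", 50.0) == 0.0
        assert tonic_current(spec, "L5_pyramidal", 150.0) == 1.0
        assert tonic_current(spec, "L5_pyramidal", 250.0) == 0.0
        assert tonic_current(spec, "L2_basket", 150.0) == 0.0

    def test_positive_clamp_depolarizes_isolated_cell(self, l5_template):
        from neocolumn.engine import simulate_single_cell

        t, v0 = simulate_single_cell(l5_template, duration=300.0)
        _, v1 = simulate_single_cell(
            l5_template, duration=300.0, i_soma=0.02, i_start=0.0
        )
        _, v2 = simulate_single_cell(
            l5_template, duration=300.0, i_soma=0.04, i_start=0.0
        )
        assert v1[-1, 0] > v0[-1, 0]
        assert v2[-1, 0] > v1[-1, 0]


class TestInvariants:
    def test_events_within_duration(self, tiny_network):
        specs = [
            EvokedDriveSpec(
                "e", "proximal", 95.0, 30.0, 3,
                weights={("L2_pyramidal", "ampa"): 1e-3},
            ),
            RhythmicDriveSpec(
                "r", "distal", -20.0, 30.0, 1e9, 10.0, 50.0, 2, 5,
                weights={("L2_pyramidal", "ampa"): 1e-3},
            ),
        ]
        from neocolumn.drives import sample_drive_events

        for spec in specs:
            for trial in range(5):
                for tr in sample_drive_events(
                    spec, tiny_network, trial_index=trial, duration=100.0
                ):
                    assert np.all(tr.times >= 0.0)
                    assert np.all(tr.times <= 100.0)

    def test_erp_scenario_drive_sequence(self):
        """The packaged evoked scenario: proximal ~25, distal ~60, proximal ~125."""
        from neocolumn.scenarios import scenario_config

        cfg = scenario_config("erp", n_pyr=5)
        evoked = sorted(cfg.drives, key=lambda d: d.start_time_mean)
        assert len(evoked) == 3
        classes = [d.drive_class for d in evoked]
        means = [d.start_time_mean for d in evoked]
        assert classes == ["proximal", "distal", "proximal"]
        assert abs(means[0] - 25) <= 5
        assert abs(means[1] - 60) <= 5
        assert abs(means[2] - 125) <= 10
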