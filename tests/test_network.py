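"""Cell placement, distance-profiled connectivity, synaptic kinetics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neocolumn.network import (
    RECEPTORS,
    ConnectivityRule,
    biexp_norm,
    biexp_peak_time,
    build_connectivity,
    build_network,
    default_connectivity_rules,
    distance_delay,
    distance_weight,
    place_cells,
    synaptic_current,
)


class TestPlacement:
    def test_full_grid_counts(self):
        config = place_cells(10, 10)
        assert len(config.population("L2_pyramidal")) == 100
        assert len(config.population("L5_pyramidal")) == 100
        assert config.n_pyramidal == 200
        # 3:1 pyramidal-to-basket ratio per layer
        assert len(config.population("L2_basket")) == 33
        assert len(config.population("L5_basket")) == 33

    def test_small_grid_counts(self):
        config = place_cells(3, 3)
        assert len(config.population("L2_pyramidal")) == 9
        assert len(config.population("L2_basket")) == 3

    def test_determinism(self):
        a = place_cells(4, 5)
        b = place_cells(4, 5)
        assert [(c.population, c.x, c.y) for c in a.cells] == [
            (c.population, c.x, c.y) for c in b.cells
        ]

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            place_cells(0, 3)


class TestDistanceProfiles:
    def test_weight_at_zero_and_lambda(self):
        assert distance_weight(0.0, 3.0, 2.0) == 2.0
        assert distance_weight(3.0, 3.0, 2.0) == pytest.approx(2.0 / math.e)

    def test_delay_at_zero_and_lambda(self):
        assert distance_delay(0.0, 3.0, 1.0) == 1.0
        assert distance_delay(3.0, 3.0, 1.0) == pytest.approx(math.e)

    @given(
        d1=st.floats(0, 20),
        d2=st.floats(0, 20),
        lam=st.floats(0.5, 100),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_weight_decays_while_delay_grows(self, d1, d2, lam):
        lo, hi = sorted([d1, d2])
        assert distance_weight(lo, lam, 1.0) >= distance_weight(hi, lam, 1.0)
        assert distance_delay(lo, lam, 1.0) <= distance_delay(hi, lam, 1.0)

    def test_rejects_bad_lambda(self):
        with pytest.raises(ValueError):
            distance_weight(1.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            distance_delay(1.0, -1.0, 1.0)

    def test_pathway_space_constants(self):
        """Per-pathway lambda values follow the published table."""
        lam = {
            (r.pre_population, r.post_population): r.space_constant
            for r in default_connectivity_rules()
        }
        assert lam[("L2_pyramidal", "L2_pyramidal")] == 3.0
        assert lam[("L2_pyramidal", "L5_pyramidal")] == 3.0
        assert lam[("L2_basket", "L2_pyramidal")] == 50.0
        assert lam[("L2_basket", "L5_pyramidal")] == 50.0
        assert lam[("L2_basket", "L2_basket")] == 20.0
        assert lam[("L5_basket", "L5_pyramidal")] == 70.0
        assert lam[("L5_basket", "L5_basket")] == 20.0


class TestConnectivity:
    def test_no_l5_basket_projections_to_l23(self):
        net = build_network(3, 3)
        gids_l2 = {
            c.gid for c in net.cells if c.layer == "L2"
        }
        pre_l5b = {
            c.gid for c in net.cells if c.population == "L5_basket"
        }
        assert not any(
            s.pre_gid in pre_l5b and s.post_gid in gids_l2
            for s in net.synapses
        )

    def test_inhibition_targets_pyramidal_soma(self):
        net = build_network(3, 3)
        baskets = {c.gid for c in net.cells if c.population == "L2_basket"}
        pyr = {c.gid for c in net.cells if c.population == "L2_pyramidal"}
        onto_pyr = [
            s for s in net.synapses
            if s.pre_gid in baskets and s.post_gid in pyr
        ]
        assert onto_pyr
        assert all(s.post_compartment == "soma" for s in onto_pyr)
        assert all(s.receptor in ("gabaa", "gabab") for s in onto_pyr)

    def test_excitation_targets_basal_oblique(self):
        net = build_network(3, 3)
        pyr = {c.gid for c in net.cells if c.population == "L5_pyramidal"}
        ee = [
            s for s in net.synapses
            if s.pre_gid in pyr and s.post_gid in pyr
        ]
        assert ee
        allowed = {"Bdend1", "Bdend2", "Bdend3", "Adend_oblique"}
        assert all(s.post_compartment in allowed for s in ee)

    def test_synapse_count_matches_bruteforce_enumeration(self):
        """2x2 grid: count synapses by exhaustive pairing per rule."""
        config = place_cells(2, 2)
        rules = default_connectivity_rules()
        syns = build_connectivity(config, rules)
        site_size = {"soma": 1, "proximal": 4, "distal": 1}
        expected = 0
        for rule in rules:
            pre = config.population(rule.pre_population)
            post = config.population(rule.post_population)
            pairs = sum(
                1 for a in pre for b in post if a.gid != b.gid
            )
            expected += pairs * site_size[rule.target_site]
        assert len(syns) == expected

    def test_empty_population_rule_rejected(self):
        config = place_cells(2, 2)
        rule = ConnectivityRule(
            "L5_basket", "L2_pyramidal", "gabaa", 1e-3, 50.0, "soma"
        )
        config.cells = [c for c in config.cells if c.population != "L5_basket"]
        with pytest.raises(ValueError):
            build_connectivity(config, [rule])

    def test_inhibitory_gain_scales_only_gaba_weights(self):
        base = build_network(3, 3)
        doubled = build_network(
            3, 3, gains={("i", "e"): 2.0, ("i", "i"): 2.0}
        )
        key = lambda s: (s.pre_gid, s.post_gid, s.post_compartment, s.receptor)
        ws = {key(s): s.weight for s in base.synapses}
        for s in doubled.synapses:
            w0 = ws[key(s)]
            if s.receptor in ("gabaa", "gabab"):
                assert s.weight == pytest.approx(2.0 * w0)
            else:
                assert s.weight == pytest.approx(w0)
            # delays untouched by gains
        assert len(base.synapses) == len(doubled.synapses)

    def test_positive_weights_and_delays(self):
        net = build_network(2, 2)
        assert all(s.weight >= 0 for s in net.synapses)
        assert all(s.delay > 0 for s in net.synapses)


class TestSynapticKinetics:
    def test_receptor_defaults(self):
        assert (RECEPTORS["ampa"].tau_rise, RECEPTORS["ampa"].tau_decay,
                RECEPTORS["ampa"].reversal) == (0.5, 1.0, 0.0)
        assert (RECEPTORS["nmda"].tau_rise, RECEPTORS["nmda"].tau_decay,
                RECEPTORS["nmda"].reversal) == (1.0, 20.0, 0.0)
        assert (RECEPTORS["gabaa"].tau_rise, RECEPTORS["gabaa"].tau_decay,
                RECEPTORS["gabaa"].reversal) == (0.5, 5.0, -80.0)
        assert (RECEPTORS["gabab"].tau_rise, RECEPTORS["gabab"].tau_decay,
                RECEPTORS["gabab"].reversal) == (1.0, 20.0, -80.0)

    def test_conductance_zero_at_spike_time(self):
        i = synaptic_current(0.0, RECEPTORS["ampa"], 1e-3, -65.0)
        assert i == pytest.approx(0.0)

    def test_zero_current_at_reversal(self):
        t = np.linspace(0, 10, 100)
        i = synaptic_current(t, RECEPTORS["gabaa"], 1e-3, -80.0)
        assert np.allclose(i, 0.0)

    def test_peak_time_closed_form_vs_brute_force(self):
        kin = RECEPTORS["ampa"]
        t_star = biexp_peak_time(kin)
        tr, td = kin.tau_rise, kin.tau_decay
        assert t_star == pytest.approx(tr * td / (td - tr) * math.log(td / tr))
        # fine-grid numerical maximization of the conductance profile
        t = np.linspace(0, 10, 200001)
        g = np.exp(-t / td) - np.exp(-t / tr)
        assert t[np.argmax(g)] == pytest.approx(t_star, abs=1e-3)

    def test_peak_conductance_normalized_to_weight(self):
        kin = RECEPTORS["nmda"]
        w = 2.5e-3
        t = np.linspace(0, 100, 100001)
        g = w * biexp_norm(kin) * (
            np.exp(-t / kin.tau_decay) - np.exp(-t / kin.tau_rise)
        )
        assert g.max() == pytest.approx(w, rel=1e-6)

    def test_invalid_taus_rejected(self):
        from neocolumn.network import ReceptorKinetics

        with pytest.raises(ValueError):
            ReceptorKinetics("bad", 5.0, 1.0, 0.0)
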