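import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dendrite_credit import biophysics as B
from dendrite_credit import morphology as M
from tests.conftest import random_trains


class TestSpec:
    def test_defaults_are_study_values(self):
        s = B.BiophysicsSpec()
        assert s.c_m == 1.0 and s.r_m == 1.0e4 and s.r_a == 150.0
        assert s.e_l == -75.0 and s.g_na_soma == 80.0 and s.g_k_soma == 40.0
        assert s.g_km_soma == 3.0 and s.tau_km == 200.0
        assert s.gamma == 2.0 and s.rho_nmda == 0.062
        assert s.c_nmda == pytest.approx(1 / 3.75)

    def test_mode_validation(self):
        with pytest.raises(ValueError):
            B.BiophysicsSpec(mode="bogus")

    def test_negative_density_rejected(self):
        with pytest.raises(ValueError):
            B.BiophysicsSpec(g_na_soma=-1.0)

    def test_yaml_round_trip(self, tmp_path):
        s = B.BiophysicsSpec(mode="extended", g_ih=0.2)
        p = tmp_path / "spec.yaml"
        s.to_yaml(p)
        assert B.BiophysicsSpec.from_yaml(p) == s


class TestSynActivation:
    def test_causality(self):
        out = B.syn_activation(np.array([0.0, 0.5]), [1.0], 0.1, 2.0)
        np.testing.assert_array_equal(out, 0.0)

    def test_unit_peak_at_closed_form_time(self):
        tr, td = 0.1, 2.0
        tp = B.peak_time(tr, td)
        assert B.syn_activation(np.array([tp]), [0.0], tr, td)[0] \
            == pytest.approx(1.0)

    def test_ampa_peak_time(self):
        assert B.peak_time(0.1, 2.0) == pytest.approx(0.315, abs=0.001)

    def test_peak_matches_numeric_maximization(self):
        tr, td = 2.0, 75.0
        t = np.linspace(0, 60, 60001)
        vals = B.syn_activation(t, [0.0], tr, td)
        assert t[np.argmax(vals)] == pytest.approx(B.peak_time(tr, td),
                                                   abs=1e-2)
        assert vals.max() == pytest.approx(1.0, abs=1e-6)

    def test_unsorted_spikes_rejected(self):
        with pytest.raises(ValueError):
            B.syn_activation(1.0, [2.0, 1.0], 0.1, 2.0)

    def test_bad_time_constants_rejected(self):
        with pytest.raises(ValueError):
            B.syn_activation(1.0, [0.0], 2.0, 0.1)

    @given(st.floats(0.05, 5.0), st.floats(6.0, 100.0))
    @settings(max_examples=25, deadline=None)
    def test_linear_summation(self, tr, td):
        t = np.array([7.3])
        one = B.syn_activation(t, [1.0], tr, td)
        two = B.syn_activation(t, [1.0, 1.0], tr, td)
        assert two[0] == pytest.approx(2 * one[0], rel=1e-9)


class TestNMDAGate:
    def test_passive_identity(self):
        v = np.linspace(-100, 40, 20)
        np.testing.assert_array_equal(B.nmda_gate(v, "passive"), 1.0)

    def test_value_at_zero(self):
        assert B.nmda_gate(0.0, "active") == pytest.approx(1 / (1 + 1 / 3.75))
        assert float(B.nmda_gate(0.0, "active")) == pytest.approx(0.78947,
                                                                  abs=1e-5)

    def test_monotone_and_limits(self):
        v = np.linspace(-150, 150, 400)
        g = B.nmda_gate(v, "active")
        assert np.all(np.diff(g) > 0)
        assert g[0] < 1e-3 and g[-1] > 0.999


class TestGatingRates:
    @pytest.mark.parametrize("ch", ["m", "h", "n", "p", "q"])
    def test_rates_finite_nonnegative(self, ch):
        v = np.linspace(-100, 60, 161)
        a, b = B.gating_rates(v, ch)
        assert np.all(np.isfinite(a)) and np.all(np.isfinite(b))
        assert np.all(a >= 0) and np.all(b >= 0)

    def test_unknown_channel(self):
        with pytest.raises(ValueError):
            B.gating_rates(0.0, "z")

    def test_steady_state_reached(self, leak_only_spec):
        # clamp v and relax m: closed form x(t) = x_inf (1 - exp(-t/tau))
        a, b = B.gating_rates(-40.0, "m")
        tau = 1.0 / (a + b)
        x_inf = a / (a + b)
        dt = 1e-3
        x = 0.0
        for _ in range(int(5 * tau / dt)):
            x = (x + dt * a) / (1 + dt * (a + b))
        assert x == pytest.approx(x_inf * (1 - math.exp(-5.0)), rel=0.01)

    def test_km_peak_time_constant(self):
        v = np.linspace(-100, 40, 1401)
        a, b = B.gating_rates(v, "p")
        tau = 1.0 / (a + b)
        assert tau.max() == pytest.approx(200.0, rel=0.01)

    def test_hcn_activates_with_hyperpolarization(self):
        a1, b1 = B.gating_rates(-100.0, "q")
        a2, b2 = B.gating_rates(-60.0, "q")
        assert a1 / (a1 + b1) > a2 / (a2 + b2)


class TestRHS:
    def test_resting_fixed_point(self, tiny_geom, leak_only_spec):
        lay = B.SynapseLayout(np.array([1]), np.array([True]),
                              np.array([0.0]))
        st0 = B.resting_state(tiny_geom, leak_only_spec, lay)
        d = B.rhs(st0, lay, leak_only_spec, tiny_geom)
        assert np.abs(d["v"]).max() < 1e-3

    def test_reversal_zero_current(self, tiny_geom, leak_only_spec):
        # a synapse at E_E contributes no current: dv/dt equal with w=0 and w>0
        lay0 = B.SynapseLayout(np.array([1]), np.array([True]),
                               np.array([0.0]))
        lay1 = B.SynapseLayout(np.array([1]), np.array([True]),
                               np.array([1e-3]))
        st0 = B.resting_state(tiny_geom, leak_only_spec, lay1)
        st0.v[:] = leak_only_spec.e_e
        st0.s_ad[:] = 1.0   # active synapse
        st1 = st0.copy()
        d0 = B.rhs(st0, lay0, leak_only_spec, tiny_geom)
        d1 = B.rhs(st1, lay1, leak_only_spec, tiny_geom)
        np.testing.assert_allclose(d0["v"], d1["v"], atol=1e-12)

    def test_extended_sag(self, small_geom):
        spec = B.BiophysicsSpec(mode="extended")
        lay = B.SynapseLayout(np.array([1]), np.array([True]),
                              np.array([0.0]))
        rec = B.simulate(small_geom, spec, lay, None, 600.0, i_soma=-0.1,
                         record_dt=0.5)
        v = rec.v_soma
        trough = v.min()
        steady = v[-1]
        sag = steady - trough
        assert 0.3 < sag < 5.0


class TestStep:
    def test_rc_closed_form(self, leak_only_spec):
        cab = M.uniform_cable(1, 10.0, 2.0)
        lay = B.SynapseLayout(np.array([0]), np.array([True]),
                              np.array([0.0]))
        rec = B.simulate(cab, leak_only_spec, lay, None, 60.0, i_soma=0.02,
                         dt=0.025, record_dt=0.1)
        gl_uS = leak_only_spec.g_l * cab.area[0] * 1e3
        vinf = leak_only_spec.e_l + 0.02 / gl_uS
        pred = leak_only_spec.e_l + (vinf - leak_only_spec.e_l) \
            * (1 - np.exp(-rec.t / 10.0))
        err = np.abs(rec.v_soma - pred).max() / abs(vinf - leak_only_spec.e_l)
        assert err < 0.005

    def test_zero_input_stays_at_rest(self, tiny_geom, leak_only_spec):
        lay = B.SynapseLayout(np.array([1]), np.array([True]),
                              np.array([0.0]))
        rec = B.simulate(tiny_geom, leak_only_spec, lay, None, 100.0,
                         record_dt=1.0)
        assert np.abs(rec.v_soma - leak_only_spec.e_l).max() < 1e-6

    def test_dense_reference_matches_core(self, small_geom, active_spec):
        """The dense linear-solve step reproduces the tree-solver exactly."""
        lay = B.place_synapses(small_geom, 10, 4, seed=2)
        trains = B.SpikeTrains([np.array([1.0123 + 0.317 * j])
                                for j in range(lay.n_syn)])
        dt = 0.025
        n_steps = 120
        rec = B.simulate(small_geom, active_spec, lay, trains, n_steps * dt,
                         dt=dt, record_dt=n_steps * dt)
        st = B.resting_state(small_geom, active_spec, lay)
        ev_t, ev_s = trains.events()
        ev_step = np.floor(ev_t / dt).astype(int)
        norms = {
            "a": B.double_exp_gmax(active_spec.tau_ar, active_spec.tau_ad),
            "n": B.double_exp_gmax(active_spec.tau_nr, active_spec.tau_nd),
            "g": B.double_exp_gmax(active_spec.tau_gr, active_spec.tau_gd)}
        for k in range(n_steps):
            for s in ev_s[ev_step == k]:
                s = int(s)
                pos = int(lay.is_exc[:s].sum()) if lay.is_exc[s] \
                    else int((~lay.is_exc[:s]).sum())
                if lay.is_exc[s]:
                    for nm, tau in (("s_ar", active_spec.tau_ar),
                                    ("s_ad", active_spec.tau_ad)):
                        getattr(st, nm)[pos] += math.exp(dt / tau) / norms["a"]
                    for nm, tau in (("s_nr", active_spec.tau_nr),
                                    ("s_nd", active_spec.tau_nd)):
                        getattr(st, nm)[pos] += math.exp(dt / tau) / norms["n"]
                else:
                    for nm, tau in (("s_gr", active_spec.tau_gr),
                                    ("s_gd", active_spec.tau_gd)):
                        getattr(st, nm)[pos] += math.exp(dt / tau) / norms["g"]
            st = B.step(st, dt, lay, active_spec, small_geom)
        np.testing.assert_allclose(st.v, rec.final_state.v, atol=1e-9)

    def test_bad_dt_rejected(self, tiny_geom, leak_only_spec):
        lay = B.SynapseLayout(np.array([1]), np.array([True]),
                              np.array([0.0]))
        st = B.resting_state(tiny_geom, leak_only_spec, lay)
        with pytest.raises(ValueError):
            B.step(st, 0.0, lay, leak_only_spec, tiny_geom)


class TestSimulate:
    def test_determinism(self, small_geom, active_spec, small_layout):
        trains = random_trains(small_layout.n_syn, 200.0, seed=7)
        a = B.simulate(small_geom, active_spec, small_layout, trains, 200.0,
                       record_dt=1.0)
        b = B.simulate(small_geom, active_spec, small_layout, trains, 200.0,
                       record_dt=1.0)
        np.testing.assert_array_equal(a.v_soma, b.v_soma)

    def test_spike_convention(self, small_geom, active_spec):
        lay = B.SynapseLayout(np.array([1]), np.array([True]),
                              np.array([0.0]))
        rec = B.simulate(small_geom, active_spec, lay, None, 300.0,
                         i_soma=0.5)
        assert rec.n_spikes > 1
        np.testing.assert_allclose(rec.spike_times,
                                   rec.cross_times - 2.0)
        assert rec.v_at_spike.shape == (rec.n_spikes, small_geom.n_comp)

    def test_stop_on_spike(self, small_geom, active_spec):
        lay = B.SynapseLayout(np.array([1]), np.array([True]),
                              np.array([0.0]))
        rec = B.simulate(small_geom, active_spec, lay, None, 500.0,
                         i_soma=0.5, stop_on_spike=True)
        assert rec.n_spikes == 1
        assert rec.stopped_early

    def test_adaptation_isi_lengthen(self, small_geom, active_spec):
        lay = B.SynapseLayout(np.array([1]), np.array([True]),
                              np.array([0.0]))
        rec = B.simulate(small_geom, active_spec, lay, None, 600.0,
                         i_soma=0.5)
        isi = np.diff(rec.cross_times)
        assert len(isi) >= 3
        assert isi[-1] > isi[0]

    def test_fi_curve_linearish_above_rheobase(self, small_geom, active_spec):
        lay = B.SynapseLayout(np.array([1]), np.array([True]),
                              np.array([0.0]))
        rates = []
        for i_amp in (0.4, 0.6, 0.8):
            rec = B.simulate(small_geom, active_spec, lay, None, 500.0,
                             i_soma=i_amp)
            rates.append(rec.n_spikes)
        assert rates[0] > 0
        assert rates[0] < rates[1] < rates[2]

    def test_passive_linearity_small_weight(self, small_geom,
                                            leak_only_spec):
        comp = int(np.flatnonzero(small_geom.dendritic_mask())[5])
        tr = B.SpikeTrains([np.array([20.0])])
        amps = []
        for w in (1e-5, 1e-6):
            lay = B.SynapseLayout(np.array([comp]), np.array([True]),
                                  np.array([w]))
            rec = B.simulate(small_geom, leak_only_spec, lay, tr, 100.0,
                             record_dt=0.1)
            amps.append(rec.v_soma.max() - rec.v_soma[0])
        assert amps[0] / amps[1] == pytest.approx(10.0, rel=0.02)

    def test_supralinear_active_sublinear_passive(self, small_geom):
        """Clustered basal E inputs: joint response vs linear sum."""
        branch = small_geom.root_branches(M.DOMAIN_BASAL)[0]
        comps = small_geom.branch_compartments()[branch]
        n_syn = 8
        comp = np.full(n_syn, comps[-1])
        tr_all = B.SpikeTrains([np.array([10.0])] * n_syn)
        ratios = {}
        for mode in ("active", "passive"):
            spec = B.BiophysicsSpec(mode=mode, g_na_soma=0.0, g_k_soma=0.0)
            lay = B.SynapseLayout(comp, np.ones(n_syn, bool),
                                  np.full(n_syn, 1.0e-3))
            joint = B.simulate(small_geom, spec, lay, tr_all, 100.0,
                               record_dt=0.1)
            one = B.SynapseLayout(comp[:1], np.ones(1, bool),
                                  np.array([1.0e-3]))
            single = B.simulate(small_geom, spec, one,
                                B.SpikeTrains([np.array([10.0])]), 100.0,
                                record_dt=0.1)
            pk_joint = joint.v_soma.max() - spec.e_l
            pk_lin = n_syn * (single.v_soma.max() - spec.e_l)
            ratios[mode] = pk_joint / pk_lin
        assert ratios["active"] > 1.05
        assert ratios["passive"] < 1.0

    def test_instability_reported_with_time(self, small_geom, active_spec):
        lay = B.SynapseLayout(np.array([1]), np.array([True]),
                              np.array([0.0]))
        with pytest.raises(B.InstabilityError, match="ms"):
            B.simulate(small_geom, active_spec, lay, None, 50.0,
                       i_soma=1e12)

    def test_point_mode_moves_synapses(self, small_geom):
        spec = B.BiophysicsSpec(mode="point")
        comp = int(np.flatnonzero(small_geom.dendritic_mask())[-1])
        lay = B.SynapseLayout(np.array([comp]), np.array([True]),
                              np.array([2e-3]))
        tr = B.SpikeTrains([np.array([5.0])])
        rec_pt = B.simulate(small_geom, spec, lay, tr, 50.0, record_dt=0.1)
        lay0 = B.SynapseLayout(np.array([0]), np.array([True]),
                               np.array([2e-3]))
        rec_soma = B.simulate(small_geom,
                              B.BiophysicsSpec(mode="active"), lay0, tr,
                              50.0, record_dt=0.1)
        np.testing.assert_allclose(rec_pt.v_soma, rec_soma.v_soma,
                                   atol=1e-9)


class TestPlaceSynapses:
    def test_point_mode(self, small_geom):
        lay = B.place_synapses(small_geom, 20, 5, mode="point")
        assert np.all(lay.comp == 0)

    def test_somatic_inhibition(self, small_geom):
        lay = B.place_synapses(small_geom, 20, 5, mode="somatic_inhibition")
        assert np.all(lay.comp[~lay.is_exc] == 0)
        assert np.all(lay.comp[lay.is_exc] != 0)

    def test_reproducible(self, small_geom):
        a = B.place_synapses(small_geom, 30, 10, seed=5)
        b = B.place_synapses(small_geom, 30, 10, seed=5)
        np.testing.assert_array_equal(a.comp, b.comp)

    def test_area_proportional_sampling(self, small_geom):
        from scipy import stats
        n = 10_000
        lay = B.place_synapses(small_geom, n, 0, seed=11)
        dend = np.flatnonzero(small_geom.dendritic_mask())
        counts = np.bincount(lay.comp, minlength=small_geom.n_comp)[dend]
        expected = n * small_geom.area[dend] / small_geom.area[dend].sum()
        chi2 = ((counts - expected) ** 2 / expected).sum()
        p = 1 - stats.chi2.cdf(chi2, df=len(dend) - 1)
        assert p > 0.01

    def test_negative_counts_rejected(self, small_geom):
        with pytest.raises(ValueError):
            B.place_synapses(small_geom, -1, 0)


class TestSpikeTrains:
    def test_validation(self):
        with pytest.raises(ValueError):
            B.SpikeTrains([np.array([2.0, 1.0])])
        with pytest.raises(ValueError):
            B.SpikeTrains([np.array([-1.0])])

    def test_events_sorted(self):
        tr = B.SpikeTrains([np.array([3.0, 5.0]), np.array([1.0])])
        t, s = tr.events()
        np.testing.assert_array_equal(t, [1.0, 3.0, 5.0])
        np.testing.assert_array_equal(s, [1, 0, 0])

    def test_text_round_trip(self, tmp_path):
        tr = B.SpikeTrains([np.array([1.5, 2.5]), np.empty(0),
                            np.array([0.25])])
        p = tmp_path / "trains.txt"
        tr.save_text(p)
        back = B.SpikeTrains.load_text(p, 3)
        for a, b in zip(tr.times, back.times):
            np.testing.assert_allclose(a, b)


class TestProjections:
    def test_h_matrix_scaling(self, small_geom, active_spec, small_layout):
        he, hi = small_layout.projection_matrices(small_geom, active_spec)
        assert he.shape == (small_geom.n_comp, small_layout.n_e)
        cap = 1e3 * active_spec.c_m * small_geom.area
        e_idx = np.flatnonzero(small_layout.is_exc)
        for k in (0, 3):
            c = small_layout.comp[e_idx[k]]
            assert he[c, k] == pytest.approx(1.0 / cap[c])
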