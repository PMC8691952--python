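import numpy as np
import pytest
from scipy import stats

from dendrite_credit import inputs as I
from dendrite_credit import morphology as M
from dendrite_credit.biophysics import SynapseLayout, place_synapses


class TestSpec:
    def test_defaults(self):
        s = I.InputEnsembleSpec()
        assert s.p_active == pytest.approx(1 / 16)
        assert s.t_on == 100.0 and s.t_off == 500.0

    def test_validation(self):
        with pytest.raises(ValueError):
            I.InputEnsembleSpec(lam_syn=1.0, lam_pop=2.5)
        with pytest.raises(ValueError):
            I.InputEnsembleSpec(k_events=-1)
        with pytest.raises(ValueError):
            I.InputEnsembleSpec(lam_pop=0.0, lam_syn=0.0)

    def test_degenerate_dense_code(self):
        s = I.InputEnsembleSpec(lam_syn=2.5, lam_pop=2.5, n_syn=50)
        assert s.p_active == 1.0
        feat = I.make_feature(s, seed=0)
        assert feat.active.all()

    def test_optimal_burst_preset(self):
        s = I.optimal_burst_spec()
        assert s.k_events == 1 and s.lam_syn == 20.0
        assert s.expected_spikes_per_burst == pytest.approx(8.0)

    def test_burst_width_scaling(self):
        # sigma = sigma0 * expected spikes per burst
        s = I.InputEnsembleSpec(lam_syn=40.0, k_events=2)
        assert s.expected_spikes_per_burst == pytest.approx(8.0)


class TestRate:
    def test_inactive_synapse_is_silent(self):
        s = I.InputEnsembleSpec(n_syn=4)
        pat = I.FeaturePattern(spec=s, indices=np.arange(4),
                               active=np.zeros(4, bool),
                               centers=[np.empty(0)] * 4)
        t = np.linspace(0, 500, 100)
        np.testing.assert_array_equal(pat.rate(0, t), 0.0)

    def test_rate_code_boxcar(self):
        s = I.InputEnsembleSpec(n_syn=1)
        pat = I.FeaturePattern(spec=s, indices=[0], active=[True],
                               centers=[np.empty(0)])
        assert pat.rate(0, np.array([50.0]))[0] == 0.0
        assert pat.rate(0, np.array([300.0]))[0] == s.lam_syn
        assert pat.rate(0, np.array([501.0]))[0] == 0.0

    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_burst_quadrature(self, k):
        """In-window integrated rate equals lam_syn * T regardless of K.

        Bumps are renormalized to the stimulus window, so the expected
        spike count is conserved even for centers near the window edges.
        """
        s = I.InputEnsembleSpec(n_syn=1, k_events=k)
        rng = np.random.default_rng(k)
        centers = np.sort(rng.uniform(s.t_on, s.t_off, k))
        pat = I.FeaturePattern(spec=s, indices=[0], active=[True],
                               centers=[centers])
        t = np.linspace(s.t_on, s.t_off, 400001)
        total = np.trapezoid(pat.rate(0, t), t) / 1000.0  # Hz*ms -> count
        assert total == pytest.approx(s.lam_syn * s.t_stim / 1000.0,
                                      rel=0.001)

    def test_edge_bump_conserves_mass(self):
        s = I.optimal_burst_spec(n_syn=1)
        pat = I.FeaturePattern(spec=s, indices=[0], active=[True],
                               centers=[np.array([s.t_on + 1.0])])
        t = np.linspace(s.t_on, s.t_off, 400001)
        total = np.trapezoid(pat.rate(0, t), t) / 1000.0
        assert total == pytest.approx(8.0, rel=0.001)

    def test_rate_matrix_shape(self):
        s = I.InputEnsembleSpec(n_syn=3)
        pat = I.FeaturePattern(spec=s, indices=np.arange(3),
                               active=np.array([True, False, True]),
                               centers=[np.empty(0)] * 3)
        assert pat.rate_matrix(np.linspace(0, 500, 7)).shape == (3, 7)


class TestMakeFeature:
    def test_reproducible(self):
        s = I.InputEnsembleSpec(n_syn=100, k_events=2)
        a = I.make_feature(s, seed=3)
        b = I.make_feature(s, seed=3)
        np.testing.assert_array_equal(a.active, b.active)
        for ca, cb in zip(a.centers, b.centers):
            np.testing.assert_array_equal(ca, cb)

    def test_active_fraction(self):
        s = I.InputEnsembleSpec(n_syn=4000)
        feat = I.make_feature(s, seed=0)
        n = feat.active.sum()
        mean, sd = 4000 / 16, np.sqrt(4000 * (1 / 16) * (15 / 16))
        assert abs(n - mean) < 4 * sd

    def test_centers_inside_window(self):
        s = I.InputEnsembleSpec(n_syn=200, k_events=3)
        feat = I.make_feature(s, seed=1)
        for j in np.flatnonzero(feat.active):
            c = feat.centers[j]
            assert len(c) == 3
            assert np.all((c >= s.t_on) & (c <= s.t_off))
            assert np.all(np.diff(c) >= 0)


class TestRealizePoisson:
    def test_zero_rate_empty(self):
        s = I.InputEnsembleSpec(n_syn=5, lam_bg=0.0)
        tr = I.realize_poisson([], s, seed=0, background="none")
        assert all(len(t) == 0 for t in tr.times)

    def test_prestim_background_confined(self):
        s = I.InputEnsembleSpec(n_syn=50, lam_bg=20.0)
        tr = I.realize_poisson([], s, seed=1, background="prestim")
        allt = np.concatenate(tr.times)
        assert len(allt) > 0
        assert allt.max() <= s.t_pre

    def test_unknown_background_mode(self):
        s = I.InputEnsembleSpec(n_syn=2)
        with pytest.raises(ValueError):
            I.realize_poisson([], s, seed=0, background="sometimes")

    def test_population_rate_conserved(self):
        """Total stimulus spike count matches N * lam_pop * T."""
        s = I.InputEnsembleSpec(n_syn=200, lam_bg=0.0)
        n_rep = 30
        counts = []
        for r in range(n_rep):
            feat = I.make_feature(s, seed=1000 + r)
            tr = I.realize_poisson([feat], s, seed=2000 + r,
                                   background="none")
            counts.append(sum(len(t) for t in tr.times))
        expected = s.n_syn * s.lam_pop * s.t_stim / 1000.0   # = 200
        se = np.sqrt(expected / n_rep) * np.sqrt(1 + s.lam_syn / s.lam_pop)
        assert abs(np.mean(counts) - expected) < 4 * se

    def test_burst_count_and_timing(self):
        """Single mid-window burst: ~8 spikes, Gaussian-distributed times."""
        s = I.optimal_burst_spec(n_syn=1)
        sigma = s.sigma0 * s.expected_spikes_per_burst     # 20 ms
        pat = I.FeaturePattern(spec=s, indices=[0], active=[True],
                               centers=[np.array([300.0])])
        all_spikes, counts = [], []
        for r in range(300):
            tr = I.realize_poisson([pat], s, seed=r, background="none")
            counts.append(len(tr.times[0]))
            all_spikes.append(tr.times[0])
        mean = np.mean(counts)
        se = np.sqrt(8.0 / 300)
        assert abs(mean - 8.0) < 4 * se
        allt = np.concatenate(all_spikes)
        res = stats.kstest(allt, stats.norm(300.0, sigma).cdf)
        assert res.pvalue > 0.01

    def test_spikes_inside_stimulus_window(self):
        s = I.InputEnsembleSpec(n_syn=100, lam_bg=0.0)
        feat = I.make_feature(s, seed=5)
        tr = I.realize_poisson([feat], s, seed=6, background="none")
        allt = np.concatenate(tr.times)
        assert np.all((allt >= s.t_on) & (allt <= s.t_off))

    def test_determinism(self):
        s = I.InputEnsembleSpec(n_syn=40)
        feat = I.make_feature(s, seed=7)
        a = I.realize_poisson([feat], s, seed=8)
        b = I.realize_poisson([feat], s, seed=8)
        for x, y in zip(a.times, b.times):
            np.testing.assert_array_equal(x, y)


class TestTask:
    def test_nonlinear_2x2_labels(self):
        task = I.make_task(I.InputEnsembleSpec(n_syn=100), 2, True, seed=0)
        np.testing.assert_array_equal(task.labels, np.eye(2, dtype=int))

    def test_halves_disjoint(self):
        task = I.make_task(I.InputEnsembleSpec(n_syn=100), 2, True, seed=0)
        x = set(task.x_features[0].indices.tolist())
        y = set(task.y_features[0].indices.tolist())
        assert not (x & y)
        assert x | y == set(range(100))

    def test_random_labels_nondegenerate(self):
        task = I.make_task(I.InputEnsembleSpec(n_syn=100), 4, seed=2)
        assert task.labels.min() == 0 and task.labels.max() == 1

    def test_n_validation(self):
        with pytest.raises(ValueError):
            I.make_task(I.InputEnsembleSpec(n_syn=100), 0)

    def test_realize_covers_population(self):
        task = I.make_task(I.InputEnsembleSpec(n_syn=60), 2, seed=1)
        tr = task.realize(0, 1, seed=3)
        assert len(tr.times) == 60

    def test_json_round_trip(self, tmp_path):
        task = I.make_task(I.InputEnsembleSpec(n_syn=80, k_events=2), 2,
                           seed=4)
        p = tmp_path / "task.json"
        I.task_to_json(task, p)
        back = I.task_from_json(p)
        assert back.spec == task.spec
        np.testing.assert_array_equal(back.labels, task.labels)
        for fa, fb in zip(task.x_features + task.y_features,
                          back.x_features + back.y_features):
            np.testing.assert_array_equal(fa.active, fb.active)
            for ca, cb in zip(fa.centers, fb.centers):
                np.testing.assert_allclose(ca, cb)


class TestCompressDuration:
    def test_noop_at_default(self):
        task = I.make_task(I.InputEnsembleSpec(n_syn=40, k_events=1), 2,
                           seed=0)
        assert I.compress_duration(task, 400.0) is task

    def test_counts_preserved_and_centers_remapped(self):
        task = I.make_task(I.InputEnsembleSpec(n_syn=40, k_events=1), 2,
                           seed=0)
        new = I.compress_duration(task, 100.0)
        s_old, s_new = task.spec, new.spec
        assert s_new.lam_syn == pytest.approx(4 * s_old.lam_syn)
        assert s_new.lam_syn * s_new.t_stim \
            == pytest.approx(s_old.lam_syn * s_old.t_stim)
        for fo, fn in zip(task.x_features, new.x_features):
            for co, cn in zip(fo.centers, fn.centers):
                np.testing.assert_allclose(
                    cn, s_new.t_on + (co - s_old.t_on) * 0.25)
                if len(cn):
                    assert np.all(cn <= s_new.t_off)

    def test_range_validation(self):
        task = I.make_task(I.InputEnsembleSpec(n_syn=40), 2, seed=0)
        with pytest.raises(ValueError):
            I.compress_duration(task, 10.0)


class TestNoise:
    def test_spec_validation(self):
        with pytest.raises(ValueError):
            I.NoiseSpec(p_mislabel=0.5)
        with pytest.raises(ValueError):
            I.NoiseSpec(shift_mode="roll")

    def test_jitter_bounds_and_zero(self):
        lay = SynapseLayout(np.arange(1, 11), np.ones(10, bool),
                            np.full(10, 1e-3))
        same = I.jitter_weights(lay, 0.0, seed=0)
        np.testing.assert_array_equal(same.weight, lay.weight)
        jit = I.jitter_weights(lay, 0.5, seed=1)
        assert np.all(jit.weight >= 0.5e-3) and np.all(jit.weight <= 1.5e-3)
        assert jit.weight.std() > 0

    def test_mislabel(self):
        labels = np.eye(2, dtype=int)
        np.testing.assert_array_equal(I.mislabel(labels, 0.0, 0), labels)
        rng_hits = sum(np.sum(I.mislabel(labels, 0.2, s) != labels)
                       for s in range(200))
        # 200 draws x 4 entries x p=0.2 -> ~160 flips
        assert 100 < rng_hits < 230

    def test_shift_shared_preserves_relative_timing(self):
        s = I.InputEnsembleSpec(n_syn=20, k_events=2)
        task = I.make_task(s, 2, seed=3)
        shifted = I.shift_bursts(task, 50.0, "shared", seed=9)
        for fo, fn in zip(task.x_features, shifted.x_features):
            deltas = []
            for co, cn in zip(fo.centers, fn.centers):
                d = np.mod(cn - co, s.t_stim)
                deltas.extend(d.tolist())
                assert np.all((cn >= s.t_on) & (cn <= s.t_off))
            if len(deltas) > 1:
                np.testing.assert_allclose(deltas, deltas[0], atol=1e-9)

    def test_apply_noise_dispatch(self):
        lay = SynapseLayout(np.arange(1, 4), np.ones(3, bool),
                            np.full(3, 1e-3))
        noise = I.NoiseSpec(s_jitter=0.0, bg_ratio=2.0)
        assert I.apply_noise(lay, noise, 0) is lay
        task = I.make_task(I.InputEnsembleSpec(n_syn=20), 2, seed=0)
        out = I.apply_noise(task, noise, 0)
        assert out.spec.lam_bg == pytest.approx(2.0 * task.spec.lam_pop)
        with pytest.raises(TypeError):
            I.apply_noise("nope", noise, 0)


class TestBranchSets:
    def test_overlap_zero_identical_full(self):
        rng = np.random.default_rng(0)
        a, b = I._branch_sets(8, 0.0, rng)
        np.testing.assert_array_equal(a, b)
        assert len(a) == 8

    def test_overlap_one_disjoint_halves(self):
        rng = np.random.default_rng(0)
        a, b = I._branch_sets(8, 1.0, rng)
        assert len(a) == len(b) == 4
        assert not (set(a.tolist()) & set(b.tolist()))

    def test_overlap_half_sizes(self):
        rng = np.random.default_rng(0)
        a, b = I._branch_sets(16, 0.5, rng)
        assert len(a) == len(b) == 12
        assert len(set(a.tolist()) & set(b.tolist())) == 8
        assert set(a.tolist()) | set(b.tolist()) == set(range(16))

    def test_bad_overlap_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(M.StructureError):
            I._branch_sets(8, 1.5, rng)


@pytest.fixture(scope="module")
def setup():
    geom = M.synthetic_tree(8, 4, depth=2, seed=0)
    lay = place_synapses(geom, 60, 20, seed=2)
    task = I.make_task(I.InputEnsembleSpec(n_syn=80), 2, True, seed=5)
    return geom, lay, task


class TestStructuredPlacement:
    def test_outputs_valid_and_deterministic(self, setup):
        geom, lay, task = setup
        a = I.structured_placement(geom, task, lay, 0.5, "active", seed=7)
        b = I.structured_placement(geom, task, lay, 0.5, "active", seed=7)
        np.testing.assert_array_equal(a.comp, b.comp)
        assert geom.dendritic_mask()[a.comp].all()
        np.testing.assert_array_equal(a.weight, lay.weight)

    def test_model_validation(self, setup):
        geom, lay, task = setup
        with pytest.raises(ValueError):
            I.structured_placement(geom, task, lay, 0.5, "mixed")

    def test_requires_2x2(self, setup):
        geom, lay, _ = setup
        task4 = I.make_task(I.InputEnsembleSpec(n_syn=80), 3, seed=0)
        with pytest.raises(ValueError):
            I.structured_placement(geom, task4, lay, 0.5)

    def test_needs_enough_root_branches(self, setup):
        _, lay, task = setup
        tiny = M.synthetic_tree(1, 1, depth=1, seed=0)
        with pytest.raises(M.StructureError):
            I.structured_placement(tiny, task, lay, 0.5)

    def test_passive_model_runs(self, setup):
        geom, lay, task = setup
        out = I.structured_placement(geom, task, lay, 1.0, "passive", seed=3)
        assert geom.dendritic_mask()[out.comp].all()
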