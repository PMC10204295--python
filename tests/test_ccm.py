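"""Cross mapping: embedding, weights, skill, convergence, E/tau selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aircausal.ccm import (
    CCM,
    convergence_scan,
    cross_map,
    delay_embed,
    detect_causality,
    neighbor_weights,
    select_E_fnn,
    select_tau_ami,
    skill_significance,
)
from aircausal.simulate import CoupledMapConfig, simulate_coupled_maps


class TestDelayEmbed:
    def test_worked_example(self):
        emb = delay_embed([1, 2, 3, 4, 5, 6], E=2, tau=2)
        assert np.array_equal(emb.vectors, [[3, 1], [4, 2], [5, 3], [6, 4]])
        assert np.array_equal(emb.t_index, [2, 3, 4, 5])

    def test_E1_is_identity(self):
        s = np.arange(10.0)
        emb = delay_embed(s, E=1, tau=3)
        assert np.array_equal(emb.vectors[:, 0], s)

    def test_study_sized_count(self):
        emb = delay_embed(np.random.default_rng(0).normal(size=349), 2, 2)
        assert len(emb) == 347

    @settings(deadline=None, derandomize=True)
    @given(L=st.integers(10, 200), E=st.integers(1, 5), tau=st.integers(1, 4))
    def test_vector_count_property(self, L, E, tau):
        if L <= (E - 1) * tau:
            with pytest.raises(ValueError):
                delay_embed(np.zeros(L), E, tau)
        else:
            emb = delay_embed(np.arange(float(L)), E, tau)
            assert len(emb) == L - (E - 1) * tau
            assert emb.vectors.shape[1] == E

    def test_too_short_raises(self):
        with pytest.raises(ValueError, match="minimum"):
            delay_embed([1.0, 2.0], E=3, tau=2)


class TestNeighborWeights:
    def test_worked_example(self):
        w = neighbor_weights([2.0, 4.0, 6.0])
        assert w == pytest.approx([0.6652, 0.2447, 0.0900], abs=5e-5)

    def test_equal_distances_uniform(self):
        assert neighbor_weights([3.0, 3.0, 3.0]) == pytest.approx([1 / 3] * 3)

    def test_nearest_unnormalised_weight_is_exp_minus_one(self):
        d = np.array([1.5, 4.0, 9.0])
        w = neighbor_weights(d)
        u = np.exp(-d / d[0])
        assert w == pytest.approx(u / u.sum())
        assert u[0] == pytest.approx(np.exp(-1))

    def test_zero_distance_ties_share_mass(self):
        assert neighbor_weights([0.0, 0.0, 3.0]) == pytest.approx([0.5, 0.5, 0.0])

    def test_errors(self):
        with pytest.raises(ValueError):
            neighbor_weights([-1.0, 2.0])
        with pytest.raises(ValueError):
            neighbor_weights([5.0, 2.0, 8.0])

    @settings(deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.01, 100), min_size=3, max_size=8))
    def test_normalisation_property(self, ds):
        w = neighbor_weights(np.sort(ds))
        assert w.sum() == pytest.approx(1.0)
        assert (w >= 0).all()


class TestSkillSignificance:
    def test_null_skill(self):
        t, p = skill_significance(0.0, 50)
        assert t == 0 and p == pytest.approx(1.0)

    def test_worked_example(self):
        t, p = skill_significance(0.6, 102)
        assert t == pytest.approx(7.5, abs=1e-10)
        assert p < 1e-10

    def test_odd_in_rho(self):
        t1, p1 = skill_significance(0.4, 60)
        t2, p2 = skill_significance(-0.4, 60)
        assert t1 == pytest.approx(-t2) and p1 == pytest.approx(p2)

    def test_perfect_skill(self):
        _, p = skill_significance(1.0, 30)
        assert p == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            skill_significance(0.5, 2)
        with pytest.raises(ValueError):
            skill_significance(1.5, 30)


class TestCrossMap:
    def test_self_map_on_deterministic_series(self):
        cfg = CoupledMapConfig(n=700, burn_in=200, seed=3)
        x, _ = simulate_coupled_maps(cfg)
        emb = delay_embed(x, 2, 1)
        res = cross_map(emb, x)
        assert res.rho > 0.99

    def test_independent_noise_target_has_no_skill(self):
        cfg = CoupledMapConfig(n=700, burn_in=200, seed=4)
        x, _ = simulate_coupled_maps(cfg)
        rng = np.random.default_rng(5)
        y = rng.normal(size=len(x))
        res = cross_map(delay_embed(x, 2, 1), y)
        assert abs(res.rho) < 0.15

    def test_constant_target_raises(self):
        x, _ = simulate_coupled_maps(CoupledMapConfig(n=300, burn_in=100, seed=6))
        with pytest.raises(ValueError, match="zero variance"):
            cross_map(delay_embed(x, 2, 1), np.ones(len(x)))

    def test_small_library_raises(self):
        x, _ = simulate_coupled_maps(CoupledMapConfig(n=300, burn_in=100, seed=7))
        emb = delay_embed(x, 2, 2)
        with pytest.raises(ValueError, match="E\\+2"):
            cross_map(emb, x, library=np.arange(3))

    def test_scale_invariance(self, coupled_series):
        x, y = coupled_series
        emb = delay_embed(x, 2, 2)
        base = cross_map(emb, y)
        affine = cross_map(emb, 2.5 * y + 7.0)
        assert affine.rho == pytest.approx(base.rho, abs=1e-12)
        scaled_manifold = cross_map(delay_embed(3.0 * x, 2, 2), y)
        assert scaled_manifold.rho == pytest.approx(base.rho, abs=1e-9)


class TestConvergence:
    def test_full_library_single_rep_reduces_to_cross_map(self, coupled_series):
        x, y = coupled_series
        emb = delay_embed(x, 2, 2)
        n_vec = len(emb)
        curve = convergence_scan(x, y, 2, 2, L_grid=[n_vec], n_reps=1, seed=0)
        direct = cross_map(emb, y)
        assert curve.rho_reps[0, 0] == direct.rho

    def test_skill_rises_with_library_for_true_direction(self, coupled_series):
        x, y = coupled_series
        curve = convergence_scan(x, y, 2, 2, L_grid=[50, 400], n_reps=10,
                                 seed=1)
        assert curve.rho_mean[1] - curve.rho_mean[0] > 0.1

    def test_uncoupled_curve_is_flat(self, uncoupled_series):
        x, y = uncoupled_series
        curve = convergence_scan(x, y, 2, 2, L_grid=[50, 400], n_reps=10,
                                 seed=2)
        assert np.abs(curve.rho_mean).max() < 0.15

    def test_grid_validation(self, coupled_series):
        x, y = coupled_series
        with pytest.raises(ValueError, match="minimum library"):
            convergence_scan(x, y, 2, 2, L_grid=[2, 50], n_reps=1, seed=0)
        with pytest.raises(ValueError, match="usable vectors"):
            convergence_scan(x, y, 2, 2, L_grid=[50, 10_000], n_reps=1, seed=0)


class TestParameterSelection:
    def test_tau_range_contract(self):
        rng = np.random.default_rng(8)
        s = rng.normal(size=400)
        assert 1 <= select_tau_ami(s, max_lag=6) <= 6

    def test_sine_first_minimum_at_quarter_period(self):
        t = np.arange(600)
        s = np.sin(2 * np.pi * t / 12)

        # independent AMI oracle
        def ami(lag, bins=16):
            a, b = s[:-lag], s[lag:]
            j, _, _ = np.histogram2d(a, b, bins=bins)
            p = j / j.sum()
            px = p.sum(1, keepdims=True)
            py = p.sum(0, keepdims=True)
            nz = p > 0
            return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())

        vals = [ami(l) for l in range(1, 9)]
        assert vals[2] < vals[1] and vals[2] < vals[3]  # minimum at lag 3
        assert select_tau_ami(s, max_lag=8) == 3

    def test_iid_noise_falls_back_to_argmin(self):
        rng = np.random.default_rng(9)
        s = rng.normal(size=2000)

        tau = select_tau_ami(s, max_lag=5)
        assert 1 <= tau <= 5

    def test_constant_series_raises(self):
        with pytest.raises(ValueError):
            select_tau_ami(np.ones(100), 5)

    def test_logistic_map_is_low_dimensional(self):
        x, _ = simulate_coupled_maps(CoupledMapConfig(n=700, burn_in=200, seed=5))
        assert select_E_fnn(x, tau=1, E_max=6) <= 2

    def test_E_range_contract_and_noise_hits_ceiling(self):
        rng = np.random.default_rng(10)
        noise = rng.normal(size=500)
        E = select_E_fnn(noise, tau=1, E_max=3)
        assert E == 3  # white noise never unfolds; ceiling with warning

    def test_short_series_raises(self):
        with pytest.raises(ValueError, match="too short"):
            select_E_fnn(np.arange(10.0), tau=2, E_max=8)


class TestDetectCausality:
    GRID = [50, 100, 150, 200, 300, 400, 500, 600]

    def test_one_way_coupling_recovered(self):
        hits_true = hits_false = 0
        n = 5
        for s in range(n):
            cfg = CoupledMapConfig(beta_xy=0.32, beta_yx=0.0, n=1200,
                                   burn_in=200, seed=s)
            x, y = simulate_coupled_maps(cfg)
            v = detect_causality(x, y, E=2, tau=2, L_grid=self.GRID,
                                 n_reps=10, seed=s)
            hits_true += v["y->x"].causal
            hits_false += not v["x->y"].causal
        assert hits_true >= 4 and hits_false >= 4

    def test_independent_series_both_negative(self):
        ok = 0
        n = 5
        for s in range(n):
            x, _ = simulate_coupled_maps(
                CoupledMapConfig(n=1200, burn_in=200, seed=50 + s))
            _, y = simulate_coupled_maps(
                CoupledMapConfig(n=1200, burn_in=200, seed=150 + s))
            v = detect_causality(x, y, E=2, tau=2, L_grid=self.GRID,
                                 n_reps=10, seed=s)
            ok += (not v["y->x"].causal) and (not v["x->y"].causal)
        assert ok >= 4

    def test_identical_series_symmetric_verdicts(self):
        x, _ = simulate_coupled_maps(CoupledMapConfig(n=900, burn_in=200,
                                                      seed=60))
        v = detect_causality(x, x.copy(), E=2, tau=2,
                             L_grid=[50, 150, 300, 500, 690], n_reps=5, seed=0)
        a, b = v["y->x"], v["x->y"]
        # skill saturates near 1 from the smallest library in both
        # directions; the verdict pair is symmetric
        assert a.rho_at_max_L > 0.95 and b.rho_at_max_L > 0.95
        assert a.causal == b.causal
        assert a.significance_pass and b.significance_pass

    def test_rho_bounds_everywhere(self, coupled_series):
        x, y = coupled_series
        model = CCM(x, y, E=2, tau=2)
        res = model.fit(L_grid=[50, 200, 400], n_reps=5, seed=3)
        frame = res.to_frame()
        assert frame["rho"].between(-1, 1).all()
        assert set(frame["direction"]) == {"y->x", "x->y"}
        assert "E=2" in res.summary()


class TestModelObject:
    def test_zscore_and_log1p(self):
        rng = np.random.default_rng(11)
        y = rng.poisson(30, 500).astype(float)
        x = rng.normal(size=500)
        m = CCM(x, y, log1p_y=True)
        assert m.y.mean() == pytest.approx(0.0, abs=1e-12)
        assert m.y.std() == pytest.approx(1.0, abs=1e-12)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError, match="z-scored|zero variance"):
            CCM(np.ones(100), np.arange(100.0))

    def test_select_embedding_updates_model(self, coupled_series):
        x, y = coupled_series
        m = CCM(x, y)
        E, tau = m.select_embedding(max_lag=6, E_max=5)
        assert (m.E, m.tau) == (E, tau)
        assert 1 <= tau <= 6 and 1 <= E <= 5
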