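import json

import numpy as np
import pytest

from ictonet.dynamics import SimulationConfig, default_params, theta_steady_state
from ictonet.ictogenicity import (
    BNIMap,
    IctalClassifierConfig,
    NIDistribution,
    ParameterGrid,
    calibrate_coupling_for_bni,
    compute_bni_map,
    compute_ni,
    default_grid,
    derive_seed,
    escape_time_bni,
    ictal_fraction,
    load_bni_map_h5,
    ni_summary_json,
    ni_to_csv,
    save_bni_map_csv,
    save_bni_map_h5,
)
from ictonet.networks import Network


FAST = {
    "physiological": SimulationConfig(dt=1e-3, t_ref=3.0, t_burn=1.0),
    "theta": SimulationConfig(dt=2e-3, t_ref=8.0, t_burn=1.0),
    "bistable": SimulationConfig(dt=2e-3, t_ref=8.0, t_burn=0.0),
}


class TestParameterGrid:
    def test_standard_windows(self):
        assert default_grid("physiological").p_range == (50.0, 110.0)
        assert default_grid("physiological").alpha_range == (0.0, 1000.0)
        assert default_grid("theta").p_range == (-4.0, -0.1)
        assert default_grid("theta").alpha_range == (0.0, 10.0)
        assert default_grid("bistable").p_range == (-1.0, 0.0)
        assert default_grid("bistable").alpha_range == (0.0, 10.0)
        assert default_grid("theta").resolution == 192

    def test_regular_spacing(self):
        g = ParameterGrid((0.0, 1.0), (0.0, 2.0), resolution=5)
        assert np.allclose(np.diff(g.p_values), 0.25)
        assert g.n_cells == 25

    def test_invalid(self):
        with pytest.raises(ValueError):
            ParameterGrid((1.0, 0.0), (0.0, 1.0))
        with pytest.raises(ValueError):
            ParameterGrid((0.0, 1.0), (0.0, 1.0), resolution=1)
        with pytest.raises(ValueError):
            default_grid("unknown-model")


class TestClassifierConfig:
    def test_defaults_valid(self):
        cl = IctalClassifierConfig()
        assert cl.theta_band == pytest.approx(np.pi / 4)
        assert cl.bistable_escape_radius_sq >= 1.0

    def test_escape_radius_must_dominate_separatrix(self):
        with pytest.raises(ValueError):
            IctalClassifierConfig(bistable_escape_radius_sq=0.5)


class TestDeriveSeed:
    def test_deterministic_and_in_range(self):
        s = derive_seed(1, 2, 3, 4)
        assert s == derive_seed(1, 2, 3, 4)
        assert 0 <= s < 2**31

    def test_sensitive_to_every_argument(self):
        base = derive_seed(1, 2, 3, 4)
        assert base != derive_seed(2, 2, 3, 4)
        assert base != derive_seed(1, 3, 3, 4)
        assert base != derive_seed(1, 2, 4, 4)
        assert base != derive_seed(1, 2, 3, 5)


class TestIctalFraction:
    def test_square_wave_duty_cycle(self):
        # baseline at 0 (median), symmetric +/-10 excursions for half the time
        cl = IctalClassifierConfig(phys_threshold=1.0)
        series = np.zeros((100, 1))
        series[10:35, 0] = 10.0
        series[60:85, 0] = -10.0
        frac = ictal_fraction(series, "physiological", cl)
        assert frac[0] == pytest.approx(0.5)

    def test_theta_at_rest_is_zero(self):
        cl = IctalClassifierConfig()
        ths = theta_steady_state(-1.0)
        series = np.full((50, 2), ths)
        assert np.all(ictal_fraction(series, "theta", cl, ths) == 0.0)

    def test_theta_excursion_span(self):
        cl = IctalClassifierConfig()
        ths = theta_steady_state(-1.0)
        series = np.full((10, 1), ths)
        series[3:7, 0] = ths + np.pi  # out of band for 4 of 10 samples
        assert ictal_fraction(series, "theta", cl, ths)[0] == pytest.approx(0.4)

    def test_wrapped_distance_is_used(self):
        # a full revolution away is the same phase, hence not ictal
        cl = IctalClassifierConfig()
        ths = theta_steady_state(-1.0)
        series = np.full((10, 1), ths + 2 * np.pi)
        assert ictal_fraction(series, "theta", cl, ths)[0] == 0.0

    def test_errors(self):
        cl = IctalClassifierConfig()
        with pytest.raises(ValueError):
            ictal_fraction(np.empty((0, 2)), "theta", cl, -1.0)
        with pytest.raises(ValueError):
            ictal_fraction(np.zeros((5, 2)), "theta", cl)   # no theta_s
        with pytest.raises(ValueError):
            ictal_fraction(np.zeros((5, 2)), "physiological", cl)  # no threshold
        with pytest.raises(ValueError):
            ictal_fraction(np.zeros((5, 2)), "bistable", cl, -1.0)


class TestEscapeTimeBNI:
    def test_censored_when_nothing_escapes(self):
        cl = IctalClassifierConfig()
        bni, times = escape_time_bni(np.zeros((100, 3)), cl, 1.0, 0.01)
        assert bni == 0.0
        assert np.all(times == 1.0)

    def test_immediate_escape(self):
        cl = IctalClassifierConfig()
        bni, _ = escape_time_bni(np.full((100, 2), 2.0), cl, 1.0, 0.01)
        assert bni == pytest.approx(0.99)   # first sample is one step in

    def test_two_node_arithmetic(self):
        cl = IctalClassifierConfig()
        r = np.zeros((100, 2))
        r[24:, 0] = 2.0    # escapes at t = 0.25
        r[74:, 1] = 2.0    # escapes at t = 0.75
        bni, times = escape_time_bni(r, cl, 1.0, 0.01)
        assert times[0] == pytest.approx(0.25)
        assert times[1] == pytest.approx(0.75)
        assert bni == pytest.approx(0.5)

    def test_short_trajectory_rejected(self):
        cl = IctalClassifierConfig()
        with pytest.raises(ValueError, match="shorter"):
            escape_time_bni(np.zeros((10, 1)), cl, 1.0, 0.01)


class TestBNIMap:
    def test_values_bounded_and_deterministic(self, cycle3):
        for model, cfg in FAST.items():
            grid = default_grid(model, resolution=4)
            a = compute_bni_map(cycle3, model, grid, cfg, master_seed=5)
            b = compute_bni_map(cycle3, model, grid, cfg, master_seed=5)
            assert a.bni.shape == (4, 4)
            assert np.all((a.bni >= 0.0) & (a.bni <= 1.0))
            assert np.array_equal(a.bni, b.bni)

    def test_fused_and_stored_engines_agree(self, chain3):
        for model, cfg in FAST.items():
            grid = default_grid(model, resolution=3)
            fused = compute_bni_map(chain3, model, grid, cfg, master_seed=2)
            stored = compute_bni_map(chain3, model, grid, cfg, master_seed=2,
                                     engine="stored")
            assert np.allclose(fused.bni, stored.bni, atol=1e-12)

    def test_theta_deep_subthreshold_column_is_zero_without_noise(self, cycle3):
        grid = ParameterGrid((-4.0, -3.0), (0.0, 0.5), resolution=3)
        params = default_params("theta", sigma_noise=0.0)
        m = compute_bni_map(cycle3, "theta", grid, FAST["theta"],
                            master_seed=1, params=params)
        assert np.all(m.bni == 0.0)

    def test_bistable_never_escapes_without_noise(self):
        single = Network(np.zeros((1, 1), dtype=np.int8))
        grid = ParameterGrid((-1.0, -0.1), (0.0, 10.0), resolution=3)
        params = default_params("bistable", sigma_noise=0.0)
        m = compute_bni_map(single, "bistable", grid, FAST["bistable"],
                            master_seed=1, params=params)
        assert np.all(m.bni == 0.0)

    def test_map_mean_invariant_under_relabeling(self, chain3):
        """Relabeling nodes permutes noise streams but cannot shift the map
        mean beyond Monte-Carlo tolerance."""
        perm = np.array([2, 0, 1])
        relabeled = Network(chain3.adjacency[np.ix_(perm, perm)])
        cfg = SimulationConfig(dt=2e-3, t_ref=8.0, t_burn=1.0)
        grid = default_grid("theta", resolution=8)
        a = compute_bni_map(chain3, "theta", grid, cfg, master_seed=21)
        b = compute_bni_map(relabeled, "theta", grid, cfg, master_seed=21)
        assert abs(a.mean - b.mean) < 0.05

    def test_grid_refinement_converges(self, chain3):
        """Doubling the resolution moves the map mean by no more than the
        across-seed spread (the BNI field is smooth in p and alpha)."""
        cfg = SimulationConfig(dt=2e-3, t_ref=8.0, t_burn=1.0)
        means = {}
        for res in (6, 12):
            grid = default_grid("theta", resolution=res)
            means[res] = np.array([
                compute_bni_map(chain3, "theta", grid, cfg, master_seed=s).mean
                for s in (31, 32, 33, 34)
            ])
        gap = abs(means[6].mean() - means[12].mean())
        sem = np.sqrt(means[6].var(ddof=1) / 4 + means[12].var(ddof=1) / 4)
        assert gap <= 3 * sem + 0.01

    def test_h5_and_csv_roundtrip(self, tmp_path, cycle3):
        m = compute_bni_map(cycle3, "bistable", default_grid("bistable", 3),
                            FAST["bistable"], master_seed=1)
        h5 = tmp_path / "map.h5"
        save_bni_map_h5(m, h5)
        loaded = load_bni_map_h5(h5)
        assert np.array_equal(loaded.bni, m.bni)
        assert loaded.model == "bistable"
        csv_path = tmp_path / "map.csv"
        save_bni_map_csv(m, csv_path)
        rows = csv_path.read_text().strip().splitlines()
        assert rows[0] == "p,alpha,bni"
        assert len(rows) == 1 + m.bni.size


class TestComputeNI:
    def test_master_slave_pair_bistable(self):
        """Removing either node of a mutually-driving pair leaves a stable
        isolated node that never escapes, so both NI approach 1."""
        pair = Network(np.array([[0, 1], [1, 0]], dtype=np.int8))
        grid = ParameterGrid((-1.0, -0.5), (5.0, 10.0), resolution=4)
        cfg = SimulationConfig(dt=2e-3, t_ref=8.0)
        dist = compute_ni(pair, "bistable", grid, cfg, master_seed=2)
        assert dist.mean_bni_full > 0.5
        assert np.all(dist.ni > 0.9)
        assert np.all(dist.ni <= 1.0)
        assert dist.delta_ni >= 0.0

    def test_undefined_when_mean_bni_zero(self, cycle3):
        grid = ParameterGrid((-4.0, -3.0), (0.0, 0.5), resolution=3)
        params = default_params("theta", sigma_noise=0.0)
        with pytest.raises(ValueError, match="NI undefined"):
            compute_ni(cycle3, "theta", grid, FAST["theta"],
                       master_seed=1, params=params)

    def test_tidy_csv_and_json_outputs(self, tmp_path):
        dist = NIDistribution("theta", 42, (0, 1, 2),
                              np.array([0.5, 0.2, -0.1]), 0.4,
                              np.array([0.2, 0.32, 0.44]))
        csv_path = tmp_path / "ni.csv"
        ni_to_csv([dist], csv_path)
        lines = csv_path.read_text().strip().splitlines()
        assert lines[0] == "network_id,model,node,ni"
        assert len(lines) == 4
        json_path = tmp_path / "ni.json"
        ni_summary_json(dist, json_path)
        data = json.loads(json_path.read_text())
        assert data["delta_ni"] == pytest.approx(0.6)
        assert data["ni"]["0"] == pytest.approx(0.5)


class TestCouplingCalibration:
    def test_bisection_on_linear_stub(self, monkeypatch, cycle3):
        import ictonet.ictogenicity as icto

        monkeypatch.setattr(
            icto, "single_point_bni",
            lambda net, model, params, config, classifier: params.alpha / 10.0,
        )
        cfg = SimulationConfig(dt=1e-3, t_ref=1.0)
        alpha = calibrate_coupling_for_bni(
            cycle3, "theta", p=-1.0, config=cfg, target_bni=0.5,
            alpha_bracket=(0.0, 10.0), tol=1e-4)
        assert alpha == pytest.approx(5.0, abs=1e-2)

    def test_subcritical_bracket_error(self, monkeypatch, cycle3):
        import ictonet.ictogenicity as icto

        monkeypatch.setattr(
            icto, "single_point_bni",
            lambda net, model, params, config, classifier: 0.0,
        )
        cfg = SimulationConfig(dt=1e-3, t_ref=1.0)
        with pytest.raises(ValueError, match="straddle"):
            calibrate_coupling_for_bni(cycle3, "theta", p=-1.0, config=cfg,
                                       alpha_bracket=(0.0, 10.0))

    def test_self_consistent_on_theta_complete_digraph(self, complete3):
        cfg = SimulationConfig(dt=2e-3, t_ref=20.0, t_burn=2.0)
        from ictonet.ictogenicity import single_point_bni, resolve_classifier

        tol = 0.05
        alpha = calibrate_coupling_for_bni(
            complete3, "theta", p=-0.2, config=cfg, target_bni=0.5,
            alpha_bracket=(0.0, 10.0), tol=tol, n_reps=4, master_seed=7)
        cl = IctalClassifierConfig()
        params = default_params("theta", p=-0.2, alpha=alpha)
        fresh = np.mean([
            single_point_bni(complete3, "theta", params,
                             cfg.with_seed(1000 + k), cl)
            for k in range(6)
        ])
        assert abs(fresh - 0.5) <= 2 * tol
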