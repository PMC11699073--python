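import copy

import numpy as np
import pandas as pd
import pytest

from shipstrike.engine import (
    SIZE_CLASSES,
    Scenario,
    apportion_risk,
    bootstrap_run,
    sensitivity_sweep,
    simulate_transit,
    simulate_year,
)
from shipstrike.grid_io import (
    DEFAULT_DEPTH_PROFILES,
    DensitySurface,
    GridCell,
    LethalityCoefficients,
    RegionDepthProfile,
    RunConfig,
    ValidationError,
    frame_to_transits,
)

CELL_DEEP = GridCell("deep", 5, 5, mean_depth=60.0, region="CapeCodBay")
CELL_SHALLOW = GridCell("shal", 1, 1, mean_depth=7.0, region="MidAtlantic")


def _transit_row(tid, cell, sc, speed, month=1, year=2021, exempt=False):
    return {
        "transit_id": tid, "cell_id": cell, "month": month, "year": year,
        "category": "x", "size_class": sc, "length_ft": {"SmallMedium": 40.0,
        "Large": 100.0, "OGV": 600.0}[sc], "draft_m": 5.0, "speed_kn": speed,
        "segment_length_m": 8000.0,
        "elapsed_s": 8000.0 / (speed * 0.514444), "exempt": exempt,
    }


def _tiny_scenario(n_w=1.5):
    transits = pd.DataFrame(
        [
            _transit_row("t00", "deep", "OGV", 14.0),
            _transit_row("t01", "deep", "Large", 9.0),
            _transit_row("t02", "shal", "SmallMedium", 20.0),
            _transit_row("t03", "shal", "Large", 12.0),
        ]
    )
    density = [DensitySurface(1, 2021, {"deep": n_w, "shal": n_w})]
    cells = {"deep": CELL_DEEP, "shal": CELL_SHALLOW}
    return Scenario(cells, density, transits, dict(DEFAULT_DEPTH_PROFILES))


class TestSimulateTransit:
    def test_zero_whales_zero_contribution(self, rng):
        t = frame_to_transits(_tiny_scenario().transits)[0]
        assert simulate_transit(t, CELL_DEEP, 0.0, DEFAULT_DEPTH_PROFILES, RunConfig(), rng) == 0.0

    def test_zero_surface_exposure_blocks_strike(self, rng):
        """If the whale is never within the draft depth no strike can occur."""
        profiles = {"CapeCodBay": RegionDepthProfile("CapeCodBay", 0.0, 0.0)}
        t = frame_to_transits(_tiny_scenario().transits)[0]
        total = sum(
            simulate_transit(t, CELL_DEEP, 5.0, profiles, RunConfig(), rng) for _ in range(300)
        )
        assert total == 0.0

    def test_forced_deterministic_path(self, rng):
        """Certain strike + unavoidable cell + certain lethality returns n_w."""
        cfg = RunConfig(
            encounter_radius=1e7,  # clamps strike probability to 1
            lethality_coefficients=LethalityCoefficients(intercept=700.0),
        )
        t = frame_to_transits(_tiny_scenario().transits)[3]  # Large in 7 m water
        for _ in range(20):
            assert simulate_transit(t, CELL_SHALLOW, 2.0, DEFAULT_DEPTH_PROFILES, cfg, rng) == 2.0

    def test_unfiltered_cell_rejected(self, rng):
        bad = GridCell("x", 0, 0, mean_depth=2.0, region="Southeast")
        t = frame_to_transits(_tiny_scenario().transits)[0]
        with pytest.raises(ValidationError):
            simulate_transit(t, bad, 1.0, DEFAULT_DEPTH_PROFILES, RunConfig(), rng)


class TestSimulateYear:
    def test_empty_transits(self):
        sc = _tiny_scenario()
        sc.transits = sc.transits.iloc[0:0]
        out = simulate_year(sc.transits, sc.densities, sc.cells, sc.profiles,
                            RunConfig(), np.random.default_rng(0))
        assert out == {s: 0.0 for s in SIZE_CLASSES}

    def test_scalar_loop_matches_vectorized_engine(self):
        """simulate_transit consumes the same 5-uniform block per transit, so
        a loop over sorted transits reproduces the vectorized path exactly."""
        sc = _tiny_scenario()
        cfg = RunConfig()
        seed = np.random.SeedSequence([cfg.seed, 3])
        vec = simulate_year(sc.transits, sc.densities, sc.cells, sc.profiles, cfg,
                            np.random.default_rng(seed))
        rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
        totals = {s: 0.0 for s in SIZE_CLASSES}
        ordered = sc.transits.sort_values("transit_id")
        lookup = {(s.month, s.year): s.values for s in sc.densities}
        for t in frame_to_transits(ordered):
            n_w = lookup[(t.month, t.year)].get(t.cell_id, 0.0)
            totals[t.size_class.value] += simulate_transit(
                t, sc.cells[t.cell_id], n_w, sc.profiles, cfg, rng
            )
        for s in SIZE_CLASSES:
            assert totals[s] == pytest.approx(vec[s], rel=1e-12)

    def test_density_grid_mismatch_errors(self):
        sc = _tiny_scenario()
        sc.densities = [DensitySurface(1, 2021, {"nowhere": 1.0})]
        with pytest.raises(ValidationError, match="nowhere"):
            simulate_year(sc.transits, sc.densities, sc.cells, sc.profiles,
                          RunConfig(), np.random.default_rng(0))

    def test_doubling_density_doubles_mortality_exactly(self, small_scenario):
        """Contributions are indicator x n_w, so scaling every n_w by 2 at
        matched seeds scales every replicate by exactly 2."""
        cfg = RunConfig(n_iterations=30, seed=5)
        base = bootstrap_run(small_scenario, cfg)
        doubled = copy.copy(small_scenario)
        doubled.densities = [
            DensitySurface(s.month, s.year, {c: 2 * v for c, v in s.values.items()})
            for s in small_scenario.densities
        ]
        res2 = bootstrap_run(doubled, cfg)
        assert np.allclose(
            res2.iteration_totals["mortality"], 2 * base.iteration_totals["mortality"]
        )


class TestBootstrap:
    def test_single_iteration_summary_is_the_replicate(self, small_scenario):
        res = bootstrap_run(small_scenario, RunConfig(n_iterations=1, seed=2))
        for _, row in res.summary.iterrows():
            rep = res.iteration_totals.query("size_class == @row.size_class")["mortality"]
            assert row["mean"] == rep.iloc[0] == row["median"]

    def test_iteration_count_recorded(self, small_scenario, quick_config):
        res = bootstrap_run(small_scenario, quick_config)
        assert len(res.iteration_totals) == quick_config.n_iterations * len(SIZE_CLASSES)

    def test_same_seed_identical_results(self, small_scenario, quick_config):
        a = bootstrap_run(small_scenario, quick_config)
        b = bootstrap_run(small_scenario, quick_config)
        pd.testing.assert_frame_equal(a.iteration_totals, b.iteration_totals)
        pd.testing.assert_frame_equal(a.cell_month_mean, b.cell_month_mean)
        assert a.config_hash == b.config_hash

    def test_conservation_totals_equal_cell_sums(self, small_scenario, quick_config):
        """Class means over iterations equal the summed per-cell-month surface."""
        res = bootstrap_run(small_scenario, quick_config)
        by_class = res.cell_month_mean.groupby("size_class")["mean_mortality"].sum()
        for sc in SIZE_CLASSES:
            mean = res.iteration_totals.query("size_class == @sc")["mortality"].mean()
            assert mean == pytest.approx(by_class.get(sc, 0.0), rel=1e-9, abs=1e-12)

    def test_zero_traffic_zero_mortality(self, small_scenario):
        empty = copy.copy(small_scenario)
        empty.transits = small_scenario.transits.iloc[0:0]
        res = bootstrap_run(empty, RunConfig(n_iterations=5, seed=1))
        assert (res.iteration_totals["mortality"] == 0.0).all()

    def test_write_outputs(self, small_scenario, tmp_path):
        res = bootstrap_run(small_scenario, RunConfig(n_iterations=3, seed=1))
        res.write(tmp_path)
        for name in ("iteration_totals.csv", "cell_month_mean.csv", "summary.csv",
                     "run_metadata.txt"):
            assert (tmp_path / name).exists()


class TestApportionRisk:
    def test_published_style_shares(self):
        shares = apportion_risk({"OGV": 15.96, "Large": 2.47, "SmallMedium": 2.05})
        assert shares["SmallMedium"] == pytest.approx(10.01, abs=0.005)
        assert sum(shares.values()) == pytest.approx(100.0)

    def test_single_class(self):
        assert apportion_risk({"OGV": 3.0, "Large": 0.0})["OGV"] == 100.0

    def test_simple_arithmetic(self):
        shares = apportion_risk({"a": 1.0, "b": 1.0, "c": 2.0})
        assert (shares["a"], shares["b"], shares["c"]) == (25.0, 25.0, 50.0)

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            apportion_risk({"OGV": 0.0})


class TestSensitivity:
    def test_empty_grid_is_baseline_only(self, small_scenario):
        table = sensitivity_sweep(small_scenario, RunConfig(n_iterations=10, seed=3), {})
        assert set(table["parameter"]) == {"baseline"}

    def test_disabling_avoidance_never_reduces_mortality(self, small_scenario):
        cfg = RunConfig(n_iterations=20, seed=3)
        table = sensitivity_sweep(small_scenario, cfg, {"avoidance_enabled": [False]})
        base = table[table["parameter"] == "baseline"].set_index("size_class")["mean"]
        off = table[table["parameter"] == "avoidance_enabled"].set_index("size_class")["mean"]
        assert (off >= base - 1e-12).all()

    def test_faster_descent_weakly_reduces_mortality(self, small_scenario):
        cfg = RunConfig(n_iterations=20, seed=3)
        table = sensitivity_sweep(
            small_scenario, cfg, {"descent_rate_range": [(0.81, 4.0)]}
        )
        base = table[table["parameter"] == "baseline"].set_index("size_class")["mean"]
        fast = table[table["parameter"] == "descent_rate_range"].set_index("size_class")["mean"]
        assert (fast <= base + 1e-12).all()

    def test_unknown_parameter_rejected(self, small_scenario):
        with pytest.raises(KeyError, match="warp_speed"):
            sensitivity_sweep(small_scenario, RunConfig(n_iterations=2), {"warp_speed": [1]})
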