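"""Simulation experiments: line sweeps, grid scans, escape model."""

import numpy as np
import pytest

from blazedtrail import (
    SweepSpec,
    Topology,
    build_escape_line,
    escape_rate_mapping,
    escape_time_profile,
    fit_scaling,
    grid_stretch_scan,
    line_fpt_sweep,
    mean_fpt_exact,
)


class TestLineSweep:
    def test_perfect_advice_perfect_following_medians(self):
        spec = SweepSpec(
            topology=Topology.LINE,
            sizes=(10, 50),
            reliabilities=(1.0,),
            follow_probs=(1.0,),
            reps=20,
            seed=0,
        )
        table = line_fpt_sweep(spec)
        med = dict(zip(table["N"], table["median_hops"]))
        assert med[10] == 9 and med[50] == 49
        assert not table["censored_heavy"].any()

    def test_reliable_advice_gives_linear_passage(self):
        spec = SweepSpec(
            topology=Topology.LINE,
            sizes=(8, 16, 32, 64, 128),
            reliabilities=(1.0, 0.9),
            follow_probs=(0.8,),
            reps=1500,
            seed=1,
        )
        table = line_fpt_sweep(spec)
        for p, block in table.groupby("p"):
            fit = fit_scaling(block["N"], block["median_hops"], "linear")
            assert fit.r_squared > 0.99, f"p={p}: R2={fit.r_squared}"

    def test_wrong_spec_topology_rejected(self):
        with pytest.raises(ValueError):
            line_fpt_sweep(SweepSpec(topology=Topology.GRID))


class TestAllWrongAdviceIsExponential:
    def test_exact_fpt_grows_at_base_nine(self):
        """With every pointer flipped and q=0.8 the mean first passage grows
        exponentially in N with per-step base (1+q)/(1-q) = 9."""
        from blazedtrail import build_line_environment

        sizes = np.arange(4, 15)
        fpts = [
            mean_fpt_exact(build_line_environment(int(n), 0.0, "flip", seed=0), 0, 0.8)
            for n in sizes
        ]
        fit = fit_scaling(sizes, fpts, "exponential")
        assert fit.r_squared > 0.98
        assert np.exp(fit.coefficients["rate"]) == pytest.approx(9.0, rel=0.05)


class TestGridScan:
    def test_perfect_world_has_unit_stretch(self):
        spec = SweepSpec(
            topology=Topology.GRID,
            sizes=(5,),
            reliabilities=(1.0,),
            follow_probs=(1.0,),
            n_envs=3,
            n_sources=5,
            seed=0,
        )
        table = grid_stretch_scan(spec)
        assert table["effective_stretch"].iloc[0] == pytest.approx(1.0)
        assert table["n_censored"].iloc[0] == 0

    def test_reliable_advice_stretch_non_increasing_in_q(self):
        spec = SweepSpec(
            topology=Topology.GRID,
            sizes=(15,),
            reliabilities=(1.0,),
            follow_probs=(0.0, 0.3, 0.6, 0.9, 1.0),
            n_envs=10,
            n_sources=20,
            seed=4,
        )
        table = grid_stretch_scan(spec).sort_values("q")
        values = table["effective_stretch"].to_numpy()
        # allow tiny sampling wiggle on an otherwise monotone curve
        assert np.all(np.diff(values) < 0.05 * values[:-1])

    def test_intermediate_reliability_has_interior_optimum(self):
        # both extremes (pure random walk, pure following) do worse than
        # an intermediate following probability at p = 0.7
        spec = SweepSpec(
            topology=Topology.GRID,
            sizes=(20,),
            reliabilities=(0.7,),
            follow_probs=(0.0, 0.7, 1.0),
            n_envs=30,
            n_sources=10,
            seed=8,
            max_steps=200_000,
        )
        table = grid_stretch_scan(spec)
        s = {round(q, 1): v for q, v in zip(table["q"], table["effective_stretch"])}
        assert s[0.7] < s[0.0] and s[0.7] < s[1.0]


class TestEscapeModel:
    def test_exact_escape_to_distance_two(self):
        table = escape_time_profile(0.8, [2], mode="exact")
        assert table["mean_hops"].iloc[0] == pytest.approx(20.0)

    def test_pure_random_walk_escape(self):
        table = escape_time_profile(0.0, [2], mode="exact")
        assert table["mean_hops"].iloc[0] == pytest.approx(4.0)

    def test_consecutive_distance_ratio_approaches_base_nine(self):
        table = escape_time_profile(0.8, list(range(1, 13)), mode="exact")
        fpt = table["mean_hops"].to_numpy()
        ratios = fpt[1:] / fpt[:-1]
        assert ratios[-1] == pytest.approx(9.0, rel=0.02)

    def test_simulate_matches_exact_on_short_distances(self):
        # mean escape time grows ~9x per unit distance, so sample sizes
        # shrink with d to keep total work bounded
        for d, n_runs in ((2, 20_000), (4, 5_000), (6, 2_000)):
            sim = escape_time_profile(
                0.8, [d], mode="simulate", n_runs=n_runs, max_steps=10**8, seed=3
            )["mean_hops"].iloc[0]
            exact = escape_time_profile(0.8, [d], mode="exact")["mean_hops"].iloc[0]
            # escape times are roughly exponential: SE ~ mean / sqrt(n)
            se = exact / np.sqrt(n_runs)
            assert abs(sim - exact) < 3 * se

    def test_perfect_following_never_escapes(self):
        table = escape_time_profile(1.0, [3], mode="exact")
        assert np.isinf(table["mean_hops"].iloc[0])

    def test_escape_line_advice_points_back(self):
        g = build_escape_line(4)
        assert g.advice[2] == 1 and g.advice[0] == 1 and g.advice[4] == -1


class TestEscapeRateMapping:
    def test_base_nine_at_q_08(self):
        m = escape_rate_mapping(7.0, 0.8)
        assert m["exponential_base_per_step"] == pytest.approx(9.0)

    def test_unbiased_at_q_zero(self):
        assert escape_rate_mapping(5.0, 0.0)["exponential_base_per_step"] == 1.0

    def test_against_advice_turn_rate(self):
        # (1-q)/2 per step of 7 cm: one outward turn per 70 cm
        m = escape_rate_mapping(7.0, 0.8)
        assert 1.0 / m["against_advice_turns_per_cm"] == pytest.approx(70.0)
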