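"""Strike occurrence, targeting, and the CLLR/SSLR risk models."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import flashforest as ff
from flashforest.lightning import mortality_probabilities


def lp(**kw):
    defaults = dict(lam=12.7, a=-3.0, p_direct=0.8, mode="CLLR")
    defaults.update(kw)
    return ff.LightningParams(**defaults)


class TestCllrProbability:
    def test_direct_hit_is_p_direct(self):
        assert ff.cllr_probability(0.0, 15.0, lp(p_direct=0.8)) == 0.8

    def test_reference_decade_of_decay(self):
        # D = 70 cm and r = 45 m make both unit factors 1, so one decade
        assert ff.cllr_probability(45.0, 70.0, lp(a=-1.0, p_direct=0.8)) == pytest.approx(0.08)

    def test_hand_evaluated_point(self):
        # exponent = -3 * (70/35) * (22.5/45) = -3
        assert ff.cllr_probability(22.5, 35.0, lp(a=-3.0, p_direct=0.8)) == pytest.approx(8e-4)

    def test_rejects_nonpositive_dbh(self):
        with pytest.raises(ValueError):
            ff.cllr_probability(1.0, 0.0, lp())

    @given(
        r=st.floats(0.0, 50.0),
        dbh=st.floats(1.0, 200.0),
        a=st.floats(-7.0, -1.0),
        p_direct=st.floats(0.0, 1.0),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_bounds(self, r, dbh, a, p_direct):
        p = ff.cllr_probability(r, dbh, lp(a=a, p_direct=p_direct))
        assert 0.0 <= p <= p_direct

    def test_monotone_in_distance_and_dbh(self):
        rs = np.linspace(0, 40, 30)
        ds = np.linspace(5, 150, 30)
        for a in (-1.0, -3.0, -7.0):
            params = lp(a=a)
            by_r = ff.cllr_probability(rs, 50.0, params)
            assert (np.diff(by_r) <= 1e-15).all()
            by_d = ff.cllr_probability(10.0, ds, params)
            assert (np.diff(by_d) >= -1e-15).all()


class TestSslrProbability:
    def test_zero_shift_is_identity(self):
        for p in (0.01, 0.25, 0.5, 0.99):
            assert ff.sslr_probability(p, 0.0) == p

    def test_hand_odds_arithmetic(self):
        # odds 1/3 shifted one factor of 3 up gives even odds
        assert ff.sslr_probability(0.25, np.log10(3.0)) == pytest.approx(0.5)

    def test_strong_tolerance_limit(self):
        assert ff.sslr_probability(0.5, -300.0) == pytest.approx(0.0, abs=1e-12)
        assert ff.sslr_probability(0.5, 300.0) == pytest.approx(1.0)

    def test_boundaries_preserved(self):
        assert ff.sslr_probability(0.0, 5.0) == 0.0
        assert ff.sslr_probability(1.0, -5.0) == 1.0

    @given(p=st.floats(1e-6, 1.0 - 1e-6), d1=st.floats(-5, 5), d2=st.floats(-5, 5))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_monotone_in_shift(self, p, d1, d2):
        lo, hi = sorted((d1, d2))
        assert ff.sslr_probability(p, lo) <= ff.sslr_probability(p, hi) + 1e-12


class TestScalingFactor:
    def test_neutral(self):
        assert ff.scaling_factor(0.0) == 0.5

    def test_hand_value(self):
        assert ff.scaling_factor(np.log(3.0)) == pytest.approx(0.75)

    def test_limits(self):
        assert ff.scaling_factor(80.0) == pytest.approx(1.0)
        assert ff.scaling_factor(-80.0) == pytest.approx(0.0, abs=1e-12)


class TestSampleStrikes:
    def test_unit_conversion(self):
        assert lp(lam=12.0).monthly_voxel_probability == pytest.approx(1.0e-6)

    def test_lam_zero_never_strikes(self, small_grid, rng):
        assert ff.sample_strikes(small_grid, lp(lam=0.0), rng) == []

    def test_absurd_lam_rejected(self, small_grid, rng):
        with pytest.raises(ValueError):
            ff.sample_strikes(small_grid, lp(lam=2.0e13), rng)

    def test_long_run_rate_recovers_lambda(self, rng):
        # 200 x 200 m = 0.04 km^2; expected strikes/yr = lam * area
        g = ff.build_grid(200, 200, 50)
        params = lp(lam=12.7)
        years = 2000
        total = sum(
            len(ff.sample_strikes(g, params, rng)) for _ in range(years * 12)
        )
        expected = 12.7 * 0.04 * years
        assert abs(total - expected) <= 3.0 * np.sqrt(expected)


class TestSelectTarget:
    def test_treeless_region_returns_none(self, small_grid):
        assert ff.select_target(small_grid, (5, 5), lp()) is None

    def test_single_tree_is_target_regardless_of_height(self, small_grid):
        slot = small_grid.add_tree(0, 6, 6, height=2.0)
        assert ff.select_target(small_grid, (5, 5), lp()) == slot

    def test_tallest_wins_and_ties_break_lexicographically(self, small_grid):
        s1 = small_grid.add_tree(0, 4, 9, height=30.0)
        s2 = small_grid.add_tree(0, 4, 2, height=30.0)
        small_grid.add_tree(0, 5, 5, height=29.0)
        # brute-force oracle over every tree in range
        best = min(
            [(4, 2, s2), (4, 9, s1)], key=lambda t: (t[0], t[1])
        )[2]
        assert ff.select_target(small_grid, (5, 5), lp()) == best

    def test_search_radius_respected(self):
        g = ff.build_grid(60, 60, 50)
        g.add_tree(0, 0, 0, height=40.0)
        assert ff.select_target(g, (30, 30), lp()) is None


class TestApplyStrike:
    def test_treeless_neighborhood_no_kills(self, small_grid, rng):
        ev = ff.apply_strike(small_grid, (5, 5), lp(), rng)
        assert ev.target_slot is None and ev.killed_slots == []

    def test_certain_direct_hit(self, small_grid, rng):
        slot = small_grid.add_tree(0, 5, 5, height=20.0, dbh=40.0)
        ev = ff.apply_strike(small_grid, (5, 5), lp(p_direct=1.0), rng)
        assert ev.target_slot == slot
        assert slot in ev.killed_slots
        assert not small_grid.alive[slot]

    def test_mean_kills_match_analytic_expectation(self, rng):
        # fixed stand; compare Monte-Carlo kills to the sum of per-tree
        # mortality probabilities
        g = ff.build_grid(40, 40, 50)
        positions = [(20, 20, 35.0, 80.0), (22, 20, 25.0, 30.0), (28, 24, 20.0, 15.0),
                     (12, 16, 18.0, 12.0), (20, 28, 22.0, 25.0)]
        for x, y, h, d in positions:
            g.add_tree(0, x, y, height=h, dbh=d)
        params = lp(a=-2.0, p_direct=0.9)
        target = ff.select_target(g, (20, 20), params)
        assert target == g.occ[20, 20]
        r = g.distance(20, 20, g.x[g.living_indices()], g.y[g.living_indices()])
        probs = ff.cllr_probability(r, g.dbh[g.living_indices()], params)
        expect = probs.sum()
        n_rep = 10_000
        kills = 0
        for _ in range(n_rep):
            ev = ff.apply_strike(g, (20, 20), params, rng, remove=False)
            kills += len(ev.killed_slots)
        se = np.sqrt((probs * (1 - probs)).sum() / n_rep)
        assert abs(kills / n_rep - expect) <= 3.0 * se

    def test_sslr_with_zero_deltas_reproduces_cllr(self, rng):
        g1 = ff.build_grid(30, 30, 50)
        g2 = ff.build_grid(30, 30, 50)
        for g in (g1, g2):
            state = np.random.default_rng(7)
            for _ in range(40):
                x, y = state.integers(0, 30, 2)
                if g.occ[x, y] == -1:
                    g.add_tree(0, int(x), int(y), height=float(state.uniform(5, 40)),
                               dbh=float(state.uniform(5, 90)))
        deltas = np.zeros(1)
        r1 = np.random.default_rng(99)
        r2 = np.random.default_rng(99)
        for voxel in [(3, 3), (15, 15), (20, 8)]:
            e1 = ff.apply_strike(g1, voxel, lp(mode="CLLR"), r1, species_delta=deltas)
            e2 = ff.apply_strike(g2, voxel, lp(mode="SSLR"), r2, species_delta=deltas)
            assert e1.killed_slots == e2.killed_slots

    def test_dispatch_uses_delta(self):
        params = lp(mode="SSLR")
        p_neutral = mortality_probabilities(
            np.array([10.0]), np.array([50.0]), np.array([0.0]), params
        )
        p_tolerant = mortality_probabilities(
            np.array([10.0]), np.array([50.0]), np.array([-2.0]), params
        )
        assert p_tolerant[0] < p_neutral[0]
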