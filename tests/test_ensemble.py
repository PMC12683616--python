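"""Sobol' sampling, the allocation transform, manifests and summaries."""

import numpy as np
import pandas as pd
import pytest

import flashforest as ff
from flashforest.ensemble import run_seed


class TestSobolSample:
    def test_values_within_ranges(self):
        ranges = ff.ParamRanges()
        for ps in ff.sobol_sample(64, ranges):
            for name in ("phi", "m0", "f_below", "theta", "lam", "d"):
                lo, hi = getattr(ranges, name)
                assert lo <= getattr(ps, name) <= hi

    def test_prefix_property(self):
        short = ff.sobol_sample(20)
        long = ff.sobol_sample(1000)
        for a, b in zip(short, long[:20]):
            assert a.to_dict() == b.to_dict()

    def test_rejects_nonpositive_n(self):
        with pytest.raises(ValueError):
            ff.sobol_sample(0)

    def test_default_ranges_are_the_uncertainty_table(self):
        r = ff.ParamRanges()
        assert r.phi == (0.04, 0.09)
        assert r.m0 == (0.0, 0.03)
        assert r.f_below == (0.1, 0.5)
        assert r.theta == (np.pi / 12, 5 * np.pi / 12)
        assert r.lam == (10.9, 14.5)
        assert r.d == (0.0, 1.0)


class TestAllocationTransform:
    def test_symmetric_angle_splits_evenly(self):
        f_wood, f_canopy = ff.allocation_from_cylindrical(0.5, np.pi / 4)
        assert f_wood == pytest.approx(0.25)
        assert f_canopy == pytest.approx(0.25)

    def test_sum_constraint_exact(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            fb = float(rng.uniform(0, 0.99))
            th = float(rng.uniform(0.01, np.pi / 2 - 0.01))
            fw, fc = ff.allocation_from_cylindrical(fb, th)
            assert fw + fc + fb == pytest.approx(1.0, abs=1e-15)

    def test_tangent_ratio(self):
        fw, fc = ff.allocation_from_cylindrical(0.1, np.pi / 3)
        assert fc / fw == pytest.approx(np.sqrt(3.0))

    @pytest.mark.parametrize("theta", [0.0, np.pi / 2])
    def test_degenerate_angles_rejected(self, theta):
        with pytest.raises(ValueError):
            ff.allocation_from_cylindrical(0.3, theta)


class TestManifest:
    def test_full_sweep_row_count(self):
        paramsets = ff.sobol_sample(1000)
        manifest = ff.lambda_sweep_manifest(ff.SWEEP_FREQUENCIES, paramsets)
        assert len(manifest) == 15_000

    def test_single_cell(self):
        manifest = ff.lambda_sweep_manifest([12.0], ff.sobol_sample(1))
        assert len(manifest) == 1

    def test_same_paramsets_at_every_frequency(self):
        manifest = ff.lambda_sweep_manifest([9.0, 16.0, 23.0], ff.sobol_sample(10))
        groups = {
            lam: sorted(g["param_index"].tolist())
            for lam, g in manifest.groupby("lam")
        }
        assert groups[9.0] == groups[16.0] == groups[23.0]

    def test_seeds_are_deterministic_and_small(self):
        m1 = ff.lambda_sweep_manifest([9.0], ff.sobol_sample(5))
        m2 = ff.lambda_sweep_manifest([9.0], ff.sobol_sample(5))
        assert (m1["seed"] == m2["seed"]).all()
        assert (m1["seed"] < 2**31).all()
        assert run_seed("x", 9.0, 0) != run_seed("x", 10.0, 0)


class TestFilterConsistent:
    def _outputs(self, metrics_list):
        outs = []
        for m in metrics_list:
            outs.append(
                ff.RunOutputs(
                    agb=m[0], gpp=m[1], n10=m[2], n30=m[2], n60=m[2],
                    strikes=0, lightning_kills=0, kills_per_strike=0.0,
                    species_agb=pd.Series(dtype=float), annual=pd.DataFrame(),
                )
            )
        return outs

    def test_infinite_intervals_keep_all(self):
        outs = self._outputs([(100, 30, 50), (900, 2, 7)])
        ci = {k: (-np.inf, np.inf) for k in ("agb", "gpp", "n10", "n60")}
        assert ff.filter_consistent(outs, ci) == [0, 1]

    def test_disjoint_interval_keeps_none(self):
        outs = self._outputs([(100, 30, 50)])
        ci = {"agb": (0, 1), "gpp": (0, np.inf), "n10": (0, np.inf), "n60": (0, np.inf)}
        assert ff.filter_consistent(outs, ci) == []

    def test_membership_matches_hand_check(self):
        outs = self._outputs([(250, 30, 40), (500, 30, 40), (250, 90, 40)])
        ci = {"agb": (200, 300), "gpp": (20, 40), "n10": (0, 100), "n60": (0, 100)}
        assert ff.filter_consistent(outs, ci) == [0]

    def test_idempotent(self):
        outs = self._outputs([(250, 30, 40), (500, 30, 40)])
        ci = {"agb": (200, 300), "gpp": (20, 40), "n10": (0, 100), "n60": (0, 100)}
        keep = ff.filter_consistent(outs, ci)
        again = ff.filter_consistent([outs[i] for i in keep], ci)
        assert again == list(range(len(keep)))

    def test_missing_interval_rejected(self):
        with pytest.raises(ValueError):
            ff.filter_consistent([], {"agb": (0, 1)})


class TestToleranceBinning:
    def test_all_neutral(self):
        vals = pd.Series({"a": 10.0, "b": 5.0})
        out = ff.tolerance_binning(vals, {"a": 0.0, "b": 0.0})
        assert out["neutral"] == 15.0
        assert out["tolerant"] == 0.0 and out["intolerant"] == 0.0

    def test_partition_conserves_total(self):
        rng = np.random.default_rng(1)
        vals = pd.Series(rng.uniform(0, 10, 12), index=[f"s{i}" for i in range(12)])
        deltas = pd.Series(rng.normal(0, 2, 12), index=vals.index)
        out = ff.tolerance_binning(vals, deltas)
        assert out.sum() == pytest.approx(vals.sum())

    def test_hand_binning(self):
        vals = pd.Series({"a": 10.0, "b": 5.0, "c": 3.0})
        out = ff.tolerance_binning(vals, {"a": -2.0, "b": 0.0, "c": 1.0})
        assert out["tolerant"] == 10.0
        assert out["neutral"] == 5.0
        assert out["intolerant"] == 3.0


class TestAgbDeltaSummary:
    def _sweep_frame(self, lo_vals, hi_vals):
        rows = []
        for lam, vals in ((9.0, lo_vals), (23.0, hi_vals)):
            for i, v in enumerate(vals):
                rows.append({"lam": lam, "param_index": i,
                             "agb:t": v[0], "agb:n": v[1], "agb:i": v[2]})
        return pd.DataFrame(rows)

    def test_identical_outputs_give_degenerate_cdf(self):
        sweep = self._sweep_frame([(5, 5, 5)] * 3, [(5, 5, 5)] * 3)
        out = ff.agb_delta_summary(sweep, {"t": -1.0, "n": 0.0, "i": 1.0}, 9.0, 23.0)
        assert all(v == 0.0 for v in out["diffs"]["total"])
        assert out["fraction_declining"]["total"] == 0.0

    def test_cdf_is_nondecreasing_with_unit_range(self):
        rng = np.random.default_rng(5)
        lo = [(a, b, c) for a, b, c in rng.uniform(0, 10, (8, 3))]
        hi = [(a, b, c) for a, b, c in rng.uniform(0, 10, (8, 3))]
        sweep = self._sweep_frame(lo, hi)
        out = ff.agb_delta_summary(sweep, {"t": -1.0, "n": 0.0, "i": 1.0}, 9.0, 23.0)
        p = out["cdf"]["total"]["p"]
        assert (np.diff(p) >= 0).all()
        assert p[-1] == 1.0

    def test_fraction_declining_matches_count(self):
        lo = [(10, 10, 10), (10, 10, 10), (10, 10, 10)]
        hi = [(12, 8, 9), (11, 12, 8), (9, 9, 12)]
        sweep = self._sweep_frame(lo, hi)
        out = ff.agb_delta_summary(sweep, {"t": -1.0, "n": 0.0, "i": 1.0}, 9.0, 23.0)
        assert out["fraction_declining"]["tolerant"] == pytest.approx(1 / 3)
        assert out["fraction_declining"]["neutral"] == pytest.approx(2 / 3)
        assert out["fraction_declining"]["intolerant"] == pytest.approx(2 / 3)

    def test_mismatched_paramsets_rejected(self):
        sweep = self._sweep_frame([(1, 1, 1)], [(1, 1, 1), (2, 2, 2)])
        with pytest.raises(ValueError):
            ff.agb_delta_summary(sweep, {"t": 0.0, "n": 0.0, "i": 0.0}, 9.0, 23.0)


class TestTransientLambda:
    def test_constant_schedule(self):
        sched = ff.transient_lambda(12.0, 12.0, 10.0, 20.0)
        assert sched(0) == 12.0 and sched(400) == 12.0

    def test_midpoint_linearity(self):
        sched = ff.transient_lambda(9.0, 23.0, 100.0, 200.0)
        assert sched(150 * 12) == pytest.approx(16.0)
        assert sched(0) == 9.0
        assert sched(300 * 12) == 23.0

    def test_monthly_sum_matches_trapezoid_integral(self):
        lam0, lam1, t0, t1 = 9.0, 23.0, 50.0, 250.0
        sched = ff.transient_lambda(lam0, lam1, t0, t1)
        months = np.arange(300 * 12)
        monthly_sum = sum(sched(m) for m in months) / 12.0
        exact = lam0 * t0 + 0.5 * (lam0 + lam1) * (t1 - t0) + lam1 * (300 - t1)
        assert abs(monthly_sum - exact) / exact < 1e-3

    def test_invalid_schedules_rejected(self):
        with pytest.raises(ValueError):
            ff.transient_lambda(9.0, 23.0, 20.0, 10.0)
        with pytest.raises(ValueError):
            ff.transient_lambda(-1.0, 23.0, 0.0, 10.0)
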