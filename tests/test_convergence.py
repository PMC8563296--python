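import numpy as np
import pytest

from socmicro.abundance import SampleRecord
from socmicro.convergence import (
    DyadSeries,
    bootstrap_mean_ci,
    fit_interaction_model,
    per_dyad_directions,
    permute_time_within_dyad,
    select_premerge_pairs,
)
from socmicro.dyad import SimilarityMatrix

from _oracles import ols_t_oracle


def series(dyad, kind, times, sims):
    return DyadSeries(dyad=dyad, dyad_type=kind, reference_sample="ref",
                      times=np.asarray(times, float),
                      sims=np.asarray(sims, float))


def linear_series(n_intro=4, n_same=4, slope_intro=1.0, slope_same=-1.0,
                  intercept=0.5, times=(0.0, 1.0, 2.0), noise=None, rng=None):
    out = []
    for d in range(n_intro):
        s = [intercept + slope_intro * t for t in times]
        if noise:
            s = [v + rng.normal(0, noise) for v in s]
        out.append(series(("a", f"i{d}"), "introduced", times, s))
    for d in range(n_same):
        s = [intercept + slope_same * t for t in times]
        if noise:
            s = [v + rng.normal(0, noise) for v in s]
        out.append(series(("a", f"s{d}"), "same_roost", times, s))
    return out


class TestDyadSeries:
    def test_times_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            series(("a", "b"), "introduced", [0, 0], [0.5, 0.5])

    def test_negative_times_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            series(("a", "b"), "introduced", [-1, 1], [0.5, 0.5])


class TestSelectPremergePairs:
    @staticmethod
    def _metadata():
        # 5 reference bats (pre-merge only) x 2 partner bats (pre + post)
        recs = []
        for i in range(5):
            colony = "A" if i < 3 else "B"
            recs.append(SampleRecord(f"r{i}", f"ref{i}", colony, 0,
                                     "faecal", "pre_merge"))
        for j, colony in enumerate(["A", "B"]):
            for day, phase in ((5, "pre_merge"), (20, "post_merge"),
                               (40, "post_merge")):
                recs.append(SampleRecord(f"p{j}d{day}", f"par{j}", colony,
                                         day, "faecal", phase))
        return recs

    @staticmethod
    def _sim(recs, rng):
        n = len(recs)
        vals = rng.uniform(0.3, 0.9, size=(n, n))
        vals = (vals + vals.T) / 2
        np.fill_diagonal(vals, 1.0)
        return SimilarityMatrix([r.sample_id for r in recs], vals)

    def test_enumerates_all_qualifying_pairs(self, rng):
        recs = self._metadata()
        out = select_premerge_pairs(recs, self._sim(recs, rng))
        # 5 refs x 2 partners + 2 partners as refs of each other
        assert len(out) == 12
        restricted = select_premerge_pairs(
            recs, self._sim(recs, rng),
            reference_bats=[f"ref{i}" for i in range(5)],
        )
        assert len(restricted) == 10

    def test_dyad_typing_by_colony(self, rng):
        recs = self._metadata()
        out = select_premerge_pairs(recs, self._sim(recs, rng))
        by_dyad = {s.dyad: s.dyad_type for s in out}
        assert by_dyad[("ref0", "par0")] == "same_roost"  # both colony A
        assert by_dyad[("ref0", "par1")] == "introduced"

    def test_partner_without_post_merge_excluded(self, rng):
        recs = self._metadata()
        recs = [r for r in recs if not (r.bat_id == "par1"
                                        and r.phase == "post_merge")]
        out = select_premerge_pairs(recs, self._sim(recs, rng))
        assert not any(s.dyad[1] == "par1" for s in out)

    def test_earliest_premerge_sample_is_the_reference(self, rng):
        recs = self._metadata()
        recs.append(SampleRecord("r0b", "ref0", "A", 3, "faecal",
                                 "pre_merge"))
        out = select_premerge_pairs(recs, self._sim(recs, rng))
        refs = {s.dyad[0]: s.reference_sample for s in out}
        assert refs["ref0"] == "r0"


class TestInteractionModel:
    def test_noise_free_interaction_is_slope_difference(self):
        fit = fit_interaction_model(linear_series(), scale_time=False)
        assert fit.coef["time"] == pytest.approx(1.0)
        assert fit.coef["interaction"] == pytest.approx(-2.0)
        assert fit.slopes["introduced"] == pytest.approx(1.0)
        assert fit.slopes["same_roost"] == pytest.approx(-1.0)

    def test_flat_similarity_gives_zero_slopes(self):
        fit = fit_interaction_model(
            linear_series(slope_intro=0.0, slope_same=0.0))
        assert fit.coef["interaction"] == pytest.approx(0.0, abs=1e-12)
        assert fit.slopes["introduced"] == pytest.approx(0.0, abs=1e-12)

    def test_interaction_equals_per_type_slope_difference(self, rng):
        out = linear_series(noise=0.05, rng=rng)
        fit = fit_interaction_model(out)
        assert fit.coef["interaction"] == pytest.approx(
            fit.slopes["same_roost"] - fit.slopes["introduced"]
        )

    def test_matches_normal_equations_oracle(self, rng):
        out = linear_series(noise=0.1, rng=rng, times=(0, 1, 3, 7))
        fit = fit_interaction_model(out)
        times = np.concatenate([s.times for s in out])
        sims = np.concatenate([s.sims for s in out])
        group = np.concatenate([
            np.full(s.n_points, float(s.dyad_type == "same_roost"))
            for s in out
        ])
        ts = (times - times.mean()) / times.std(ddof=1)
        X = np.column_stack([np.ones_like(ts), ts, group, ts * group])
        beta, t = ols_t_oracle(sims, X)
        assert fit.coef["interaction"] == pytest.approx(beta[3], abs=1e-10)
        assert fit.tstat["interaction"] == pytest.approx(t[3], abs=1e-8)

    def test_requires_both_dyad_types(self):
        only = linear_series(n_same=0)
        with pytest.raises(ValueError, match="both dyad types"):
            fit_interaction_model(only)

    def test_single_time_per_type_rejected(self):
        bad = (
            [series(("a", f"i{d}"), "introduced", [1.0], [0.5])
             for d in range(2)]
            + linear_series(n_intro=0)
        )
        with pytest.raises(ValueError, match="single time"):
            fit_interaction_model(bad)


class TestPermutationTest:
    def test_degenerate_flat_data_gives_p_one(self):
        out = linear_series(slope_intro=0.0, slope_same=0.0,
                            times=(0.0, 10.0))
        res = permute_time_within_dyad(out, n_permutations=50, seed=3)
        assert res.statistic == 0.0
        assert res.pvalue == 1.0

    def test_strong_interaction_gives_minimum_p(self, rng):
        out = linear_series(n_intro=8, n_same=8, noise=0.01, rng=rng,
                            times=(0, 5, 10, 20))
        res = permute_time_within_dyad(out, n_permutations=199, seed=3)
        assert res.pvalue == pytest.approx(1 / 200)
        assert res.interaction < 0

    def test_single_point_dyads_excluded_with_warning(self, caplog):
        out = linear_series() + [
            series(("a", "lone"), "introduced", [4.0], [0.7])
        ]
        with caplog.at_level("WARNING"):
            res = permute_time_within_dyad(out, n_permutations=20, seed=0)
        assert res.n_dyads_excluded == 1
        assert "single-point" in caplog.text

    def test_invariant_to_affine_time_rescaling(self, rng):
        out = linear_series(noise=0.05, rng=rng, times=(0, 2, 5))
        res1 = permute_time_within_dyad(out, n_permutations=100, seed=9)
        rescaled = [
            series(s.dyad, s.dyad_type, 3.0 * s.times + 7.0, s.sims)
            for s in out
        ]
        res2 = permute_time_within_dyad(rescaled, n_permutations=100, seed=9)
        assert res1.pvalue == res2.pvalue
        assert res1.statistic == pytest.approx(res2.statistic)

    def test_seed_determinism(self, rng):
        out = linear_series(noise=0.2, rng=rng)
        a = permute_time_within_dyad(out, n_permutations=100, seed=5)
        b = permute_time_within_dyad(out, n_permutations=100, seed=5)
        assert a.pvalue == b.pvalue


class TestPerDyadDirections:
    def test_all_consistent_when_built_that_way(self):
        res = per_dyad_directions(linear_series())
        assert res.fraction_consistent == 1.0
        assert not res.ties

    def test_flat_dyad_counts_as_tie_and_inconsistent(self):
        out = linear_series(n_intro=1, n_same=1)
        out.append(series(("a", "flat"), "introduced", [0, 1], [0.5, 0.5]))
        res = per_dyad_directions(out)
        assert ("a", "flat") in res.ties
        assert res.consistent[("a", "flat")] is False
        assert res.fraction_consistent == pytest.approx(2 / 3)

    def test_random_walk_null_near_half(self):
        rng = np.random.default_rng(77)
        out = []
        for d in range(200):
            steps = rng.normal(0, 0.05, size=3)
            vals = 0.5 + np.cumsum(steps)
            kind = "introduced" if d % 2 else "same_roost"
            out.append(series(("a", f"d{d}"), kind, [0, 1, 2], vals))
        res = per_dyad_directions(out)
        assert 0.4 < res.fraction_consistent < 0.6


class TestBootstrap:
    def test_constant_values_give_degenerate_interval(self):
        ci = bootstrap_mean_ci([3.0, 3.0, 3.0], n_boot=200, seed=1)
        assert ci.lower == ci.upper == ci.mean == 3.0

    def test_endpoints_are_percentiles_of_bootstrap_means(self, rng):
        vals = rng.normal(size=30)
        ci = bootstrap_mean_ci(vals, n_boot=1000, seed=12)
        r2 = np.random.default_rng(12)
        idx = r2.integers(0, 30, size=(1000, 30))
        means = vals[idx].mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
        assert ci.lower == pytest.approx(lo)
        assert ci.upper == pytest.approx(hi)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            bootstrap_mean_ci([1.0])
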