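"""Sweep calling: quantile thresholds, >=2-metric intersection on hand
toys, genotype gradients, and the interval Fisher/permutation machinery."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import hypergeom

from ponypop.core import interval_jaccard
from ponypop.simulate import default_sweep_fixture
from ponypop.sweeps import (
    call_candidates,
    genotype_gradient,
    interval_fisher,
    merge_close_snps,
    quantile_cut,
    shuffle_overlap_null,
)
from ponypop.winstats import window_table
from ponypop.xpehh import panels_from_genotypes, window_average, xpehh_scores
from tests.conftest import make_gm


class TestQuantileCut:
    def test_top_one_percent_of_hundred_is_maximum(self):
        rng = np.random.default_rng(0)
        v = rng.permutation(100).astype(float)
        thr, flags = quantile_cut(v, q=0.01, tail="upper")
        assert flags.sum() == 1
        assert v[flags][0] == v.max()

    def test_all_equal_flags_nothing(self):
        thr, flags = quantile_cut(np.full(50, 3.0), q=0.1, tail="upper")
        assert thr == 3.0 and flags.sum() == 0

    def test_q_one_flags_all_defined(self):
        v = np.array([1.0, np.nan, 2.0, 3.0])
        _, flags = quantile_cut(v, q=1.0)
        assert flags.sum() == 3 and not flags[1]

    def test_lower_tail(self):
        v = np.arange(100.0)
        _, flags = quantile_cut(v, q=0.01, tail="lower")
        assert flags.sum() == 1 and flags[0]

    def test_all_nan_is_error(self):
        with pytest.raises(ValueError):
            quantile_cut(np.full(5, np.nan))


def toy_windows():
    """10 windows with flat backgrounds; planted extremes pin the flags."""
    base = pd.DataFrame(
        {
            "chrom": "1",
            "start": np.arange(10) * 10_000,
            "end": (np.arange(10) + 1) * 10_000,
            "fst": np.full(10, 0.02),
            "pi_ratio": np.full(10, 1.0),
            "mean_xpehh": np.zeros(10),
        }
    )
    base.loc[3, "fst"] = 0.9  # fst flag at window 3
    base.loc[3, "pi_ratio"] = 0.01  # pi flag at window 3
    base.loc[7, "mean_xpehh"] = 5.0  # xpehh flag at window 7 (single-metric)
    return base


class TestCallCandidates:
    def test_two_metric_window_is_candidate_single_metric_is_not(self):
        cand = call_candidates(toy_windows(), q=0.1)
        assert len(cand) == 1
        assert cand["start"].iloc[0] == 30_000 and cand["end"].iloc[0] == 40_000
        assert cand["metrics"].iloc[0] == "fst,pi_ratio"
        assert cand["n_metrics"].iloc[0] == 2

    def test_three_metric_support(self):
        t = toy_windows()
        t.loc[3, "mean_xpehh"] = 6.0
        cand = call_candidates(t, q=0.1)
        assert cand["n_metrics"].iloc[0] == 3

    def test_adjacent_flagged_windows_merge(self):
        t = toy_windows()
        t.loc[4, "fst"] = 0.8
        t.loc[4, "pi_ratio"] = 0.02
        t.loc[7, "mean_xpehh"] = 0.0  # no single-metric distraction
        cand = call_candidates(t, q=0.2)
        assert len(cand) == 1
        assert (cand["start"].iloc[0], cand["end"].iloc[0]) == (30_000, 50_000)

    def test_supports_consistent_with_raw_tracks(self, sweep_fixture):
        gm, meta, sweep = sweep_fixture
        pony = gm.take_samples(meta.samples_in("pony"))
        horse = gm.take_samples(meta.samples_in("horse"))
        wt = window_table(pony, horse)
        q, r = panels_from_genotypes(gm, meta, ["pony"], ["horse"])
        wa = window_average(xpehh_scores(q, r))
        wt = wt.merge(
            wa[["chrom", "start", "end", "mean_xpehh"]],
            on=["chrom", "start", "end"],
            how="left",
        )
        cand = call_candidates(wt, q=0.01)
        assert len(cand) >= 1
        tails = {"fst": "upper", "pi_ratio": "lower", "mean_xpehh": "upper"}
        for _, c in cand.iterrows():
            for metric in c["metrics"].split(","):
                thr, flags = quantile_cut(
                    wt[metric].to_numpy(float), q=0.01, tail=tails[metric]
                )
                flagged = wt[flags]
                overlap = flagged[
                    (flagged.chrom == c.chrom)
                    & (flagged.start < c.end)
                    & (flagged.end > c.start)
                ]
                assert len(overlap) > 0

    def test_recovers_implanted_sweep(self, sweep_fixture):
        gm, meta, sweep = sweep_fixture
        pony = gm.take_samples(meta.samples_in("pony"))
        horse = gm.take_samples(meta.samples_in("horse"))
        wt = window_table(pony, horse)
        q, r = panels_from_genotypes(gm, meta, ["pony"], ["horse"])
        wa = window_average(xpehh_scores(q, r))
        wt = wt.merge(
            wa[["chrom", "start", "end", "mean_xpehh"]],
            on=["chrom", "start", "end"],
            how="left",
        )
        cand = call_candidates(wt, q=0.01)
        jac = interval_jaccard(
            cand[["start", "end"]].to_numpy(), np.array([[sweep.start, sweep.end]])
        )
        assert jac >= 0.5


class TestMergeCloseSnps:
    def test_snps_within_100bp_merge(self):
        iv = merge_close_snps(np.array([1000, 1050, 1200, 5000]), max_gap=100)
        assert len(iv) == 3
        assert iv[0].tolist() == [999, 1050]

    def test_far_snps_stay_single(self):
        iv = merge_close_snps(np.array([1000, 2000]), max_gap=100)
        assert len(iv) == 2


class TestGenotypeGradient:
    @staticmethod
    def gradient_fixture(seed=0):
        rng = np.random.default_rng(seed)
        freqs = {"h1": 0.9, "h2": 0.6, "h3": 0.3, "h4": 0.1}
        rows, meta_rows = [], []
        for grp, p in freqs.items():
            for i in range(15):
                rows.append(rng.binomial(2, p, 10).astype(np.int8))
                meta_rows.append(
                    {
                        "sample": f"{grp}_{i}",
                        "breed": "b",
                        "region": "r",
                        "height_class": grp,
                        "sex": "female",
                        "yakutia_adjacent": False,
                    }
                )
        from ponypop.core import SampleMeta

        gm = make_gm(
            np.vstack(rows),
            positions=np.arange(1, 11) * 100,
            samples=[m["sample"] for m in meta_rows],
        )
        return gm, SampleMeta(pd.DataFrame(meta_rows))

    def test_single_group_frequencies_normalized_flag_undefined(self):
        gm, meta = self.gradient_fixture()
        table, flag = genotype_gradient(gm, "1", 0, 2000, meta, ["h1"])
        assert flag is None
        s = table[[f"freq_geno_{c}" for c in (0, 1, 2)]].sum(axis=1)
        assert np.allclose(s, 1.0)

    def test_planted_gradient_is_monotone(self):
        gm, meta = self.gradient_fixture()
        table, flag = genotype_gradient(gm, "1", 0, 2000, meta, ["h1", "h2", "h3", "h4"])
        assert flag is True
        assert table["alt_allele_freq"].is_monotonic_decreasing

    def test_label_permutations_break_monotonicity(self):
        import itertools

        gm, meta = self.gradient_fixture()
        broken = 0
        orders = list(itertools.permutations(["h1", "h2", "h3", "h4"]))
        for order in orders:
            _, flag = genotype_gradient(gm, "1", 0, 2000, meta, list(order))
            broken += not flag
        # only the identity and full reversal preserve monotonicity
        assert broken == len(orders) - 2

    def test_empty_region_is_error(self):
        gm, meta = self.gradient_fixture()
        with pytest.raises(ValueError):
            genotype_gradient(gm, "1", 500_000, 600_000, meta, ["h1"])


class TestIntervalFisher:
    GENOME = {"1": 10_000}

    def test_hand_built_table(self):
        a = [("1", 0, 100), ("1", 500, 600)]
        b = [("1", 50, 150), ("1", 900, 950)]
        res = interval_fisher(a, b, self.GENOME)
        assert (res.n11, res.n12, res.n21) == (1, 1, 1)
        # n22 = round(10000 / (100 + 75)) - 3 = 57 - 3 = 54
        assert res.n22 == 54
        # two-sided hypergeometric oracle on the fixed-margin table
        M = 1 + 1 + 1 + 54
        n_row = 2
        n_col = 2
        pmf = [hypergeom.pmf(k, M, n_row, n_col) for k in range(3)]
        p_obs = pmf[1]
        expect = sum(p for p in pmf if p <= p_obs * (1 + 1e-9))
        assert res.fisher_p == pytest.approx(expect, rel=1e-9)

    def test_identical_sets_maximal_odds_ratio(self):
        a = [("1", 0, 100), ("1", 500, 600)]
        res = interval_fisher(a, list(a), self.GENOME)
        assert res.n12 == 0 and res.n21 == 0
        assert res.odds_ratio > 100  # Haldane-corrected, zero off-cells

    def test_swapping_sets_preserves_p(self):
        a = [("1", 0, 100), ("1", 500, 600), ("1", 4000, 4100)]
        b = [("1", 50, 150), ("1", 900, 950)]
        r1 = interval_fisher(a, b, self.GENOME)
        r2 = interval_fisher(b, a, self.GENOME)
        assert r1.fisher_p == pytest.approx(r2.fisher_p, rel=1e-12)

    def test_empty_set_is_error(self):
        with pytest.raises(ValueError):
            interval_fisher([], [("1", 0, 10)], self.GENOME)


class TestShuffleNull:
    GENOME = {"1": 1_000_000, "2": 500_000}

    @staticmethod
    def rand_set(seed, genome, n=8, ln=5000):
        rng = np.random.default_rng(seed)
        out = []
        for chrom, L in genome.items():
            starts = np.sort(rng.choice(L - ln, n, replace=False))
            out += [(chrom, int(s), int(s + ln)) for s in starts]
        return out

    def test_shuffle_preserves_lengths_and_counts(self):
        a = self.rand_set(1, self.GENOME)
        b = self.rand_set(2, self.GENOME)
        res = shuffle_overlap_null(a, b, self.GENOME, n_shuffles=20, seed=5)
        assert len(res.null_odds_ratios) == 20
        from ponypop.sweeps import _as_interval_dict, _shuffle_intervals

        ad = _as_interval_dict(a)
        rng = np.random.default_rng(5)
        for _ in range(10):
            sh = _shuffle_intervals(ad, self.GENOME, rng)
            for chrom in ad:
                assert len(sh[chrom]) == len(ad[chrom])
                assert sorted((sh[chrom][:, 1] - sh[chrom][:, 0]).tolist()) == sorted(
                    (ad[chrom][:, 1] - ad[chrom][:, 0]).tolist()
                )
                iv = sh[chrom][np.argsort(sh[chrom][:, 0])]
                assert np.all(iv[1:, 0] >= iv[:-1, 1])  # non-overlapping
                assert iv[0, 0] >= 0 and iv[-1, 1] <= self.GENOME[chrom]

    def test_identical_sets_attain_lower_bound_p(self):
        a = self.rand_set(3, self.GENOME)
        res = shuffle_overlap_null(a, list(a), self.GENOME, n_shuffles=99, seed=6)
        assert res.empirical_p == pytest.approx(1 / 100)

    def test_fixed_seed_reproducible_null(self):
        a = self.rand_set(4, self.GENOME)
        b = self.rand_set(5, self.GENOME)
        r1 = shuffle_overlap_null(a, b, self.GENOME, n_shuffles=50, seed=9)
        r2 = shuffle_overlap_null(a, b, self.GENOME, n_shuffles=50, seed=9)
        assert np.array_equal(r1.null_odds_ratios, r2.null_odds_ratios)

    def test_infeasible_placement_is_error(self):
        a = [("1", 0, 900_000), ("1", 900_000, 1_000_000)]
        b = [("1", 0, 1000)]
        genome = {"1": 500_000}
        with pytest.raises(ValueError):
            shuffle_overlap_null(a, b, genome, n_shuffles=2, seed=0)
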