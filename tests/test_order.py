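import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from searchbench.order import (arbitrary_rank_baseline, arbitrary_ranks,
                               build_order_dataset, color_match_by_order,
                               compare_size_vs_arbitrary,
                               order_feature_correlation, rank_within_trial,
                               williams_test)


def make_scored(cells):
    """Build a scored table from {(pid, tid): [(role, instance_id, area,
    order_index, color_match), ...]}."""
    rows = []
    for (pid, tid), objs in cells.items():
        n_targets = sum(1 for role, *_ in objs if role in ("TP", "FN"))
        for role, iid, area, k, cm in objs:
            side = math.sqrt(area) if area else np.nan
            rows.append({
                "participant_id": pid, "trial_id": tid, "role": role,
                "instance_id": iid, "x": 0.0, "y": 0.0,
                "t": float(k) if k else np.nan, "order_index": k,
                "cx": 0.0, "cy": 0.0, "width": side, "height": side,
                "area": area, "distance": 0.0, "n_targets": n_targets,
                "clarity": 3, "color_match": cm, "threshold": 66.0,
            })
    return pd.DataFrame(rows)


class TestRanks:
    def test_descending_ranks(self):
        assert list(rank_within_trial([100, 50, 75])) == [1, 3, 2]

    def test_ties_get_average_rank(self):
        assert list(rank_within_trial([50, 50])) == [1.5, 1.5]

    def test_single_value(self):
        assert list(rank_within_trial([7.0])) == [1.0]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_within_trial([])

    def test_arbitrary_ranks_are_permutations_and_reproducible(self):
        trials = {"t1": [f"i{k}" for k in range(6)], "t2": ["j0", "j1"]}
        a = arbitrary_ranks(trials, np.random.default_rng(3))
        b = arbitrary_ranks(trials, np.random.default_rng(3))
        assert a == b
        assert sorted(a[f"i{k}"] for k in range(6)) == [1, 2, 3, 4, 5, 6]

    def test_arbitrary_ranks_uniform_over_draws(self):
        """Each rank is equally likely for a given instance (chi-square)."""
        trials = {"t": ["a", "b", "c", "d"]}
        rng = np.random.default_rng(9)
        hits = np.zeros(4)
        n_draws = 4000
        for _ in range(n_draws):
            hits[int(arbitrary_ranks(trials, rng)["a"]) - 1] += 1
        assert stats.chisquare(hits).pvalue > 1e-3


class TestBuildOrderDataset:
    def test_single_tp_cell_excluded(self):
        sc = make_scored({("p", "t"): [("TP", "t:0", 100, 1, 0),
                                       ("FN", "t:1", 50, None, 0)]})
        assert build_order_dataset(sc).empty

    def test_truncation_at_max_order(self):
        objs = [("TP", f"t:{k}", 100 + k, k + 1, 0) for k in range(12)]
        sc = make_scored({("p", "t"): objs})
        rec = build_order_dataset(sc, max_order=10)
        assert len(rec) == 10
        assert rec["order"].max() == 10

    def test_interleaved_fp_does_not_advance_tp_order(self):
        sc = make_scored({("p", "t"): [
            ("TP", "t:0", 100, 1, 0),
            ("FP", None, None, 2, None),
            ("TP", "t:1", 50, 3, 0),
        ]})
        rec = build_order_dataset(sc).sort_values("order")
        assert list(rec["order"]) == [1, 2]
        assert list(rec["raw_order"]) == [1, 3]

    def test_record_count_is_sum_of_capped_tp_counts(self, exp2_scored):
        _, sc = exp2_scored
        rec = build_order_dataset(sc)
        expected = 0
        for _, grp in sc[sc.role == "TP"].groupby(
                ["participant_id", "trial_id"]):
            if len(grp) >= 2:
                expected += min(len(grp), 10)
        assert len(rec) == expected

    def test_size_rank_over_all_trial_instances(self):
        sc = make_scored({("p", "t"): [
            ("TP", "t:0", 400, 1, 0),   # 2nd largest of three
            ("TP", "t:1", 100, 2, 0),   # smallest
            ("FN", "t:2", 900, None, 0),
        ]})
        rec = build_order_dataset(sc).set_index("instance_id")
        assert rec.loc["t:0", "size_rank"] == 2.0
        assert rec.loc["t:1", "size_rank"] == 3.0


class TestOrderCorrelation:
    def _records(self, reverse=False):
        cells = {}
        for t in range(6):
            n = 4 + (t % 3)
            objs = []
            for k in range(1, n + 1):
                area = (1000 - 100 * k) if not reverse else (100 * k)
                objs.append(("TP", f"t{t}:{k}", float(area), k, 0))
            cells[("p", f"t{t}")] = objs
        return build_order_dataset(make_scored(cells))

    def test_perfect_agreement(self):
        rec = self._records()
        r, _ = order_feature_correlation(rec, "size_rank")
        assert r == pytest.approx(1.0)

    def test_perfect_reversal(self):
        rec = self._records(reverse=True)
        # within each trial size rank runs opposite to order
        r_within = [stats.spearmanr(g["order"], g["size_rank"]).statistic
                    for _, g in rec.groupby("trial_id")]
        assert all(r == pytest.approx(-1.0) for r in r_within)

    def test_constant_feature_flagged(self):
        rec = self._records()
        rec["size_rank"] = 1.0
        with pytest.raises(ValueError, match="constant"):
            order_feature_correlation(rec, "size_rank")

    def test_too_few_records_rejected(self):
        rec = self._records().head(3)
        with pytest.raises(ValueError):
            order_feature_correlation(rec, "size_rank")


class TestWilliams:
    def test_zero_when_correlations_equal(self):
        res = williams_test(0.4, 0.4, 0.1, 50)
        assert res.t == 0.0
        assert res.p == pytest.approx(1.0)
        assert res.df == 47

    def test_antisymmetric_in_swapped_correlations(self):
        a = williams_test(0.5, 0.3, 0.2, 50)
        b = williams_test(0.3, 0.5, 0.2, 50)
        assert a.t == pytest.approx(-b.t)
        assert a.p == pytest.approx(b.p)

    def test_against_step_by_step_evaluation(self):
        """Independent hand evaluation of the Williams (1959) formula."""
        r12, r13, r23, n = 0.5, 0.3, 0.2, 50
        K = 1 - r12**2 - r13**2 - r23**2 + 2 * r12 * r13 * r23  # 0.68
        assert K == pytest.approx(0.68)
        rbar = 0.4
        denom = 2 * K * (n - 1) / (n - 3) + rbar**2 * (1 - r23) ** 3
        expected_t = (r12 - r13) * math.sqrt((n - 1) * (1 + r23) / denom)
        assert expected_t == pytest.approx(1.252287, abs=1e-5)
        res = williams_test(r12, r13, r23, n)
        assert res.t == pytest.approx(expected_t)
        assert res.p == pytest.approx(2 * stats.t.sf(expected_t, 47))

    @pytest.mark.parametrize("kwargs", [
        dict(r12=0.5, r13=0.3, r23=0.2, n=3),
        dict(r12=1.0, r13=0.3, r23=0.2, n=50),
        dict(r12=0.5, r13=0.3, r23=-1.0, n=50),
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            williams_test(**kwargs)


class TestArbitraryBaseline:
    def _fixture(self):
        """20 trials, sizes 2..9 cycling, every instance selected, so the
        expected pooled correlation is exactly computable."""
        rng = np.random.default_rng(77)
        cells = {}
        for t in range(20):
            n = 2 + (t % 8)
            objs = [("TP", f"t{t:02d}:{k}", float(rng.uniform(100, 10000)),
                     k, 0) for k in range(1, n + 1)]
            cells[("p", f"t{t:02d}")] = objs
        sc = make_scored(cells)
        return sc, build_order_dataset(sc)

    @staticmethod
    def _expected_correlation(records):
        """Exact expectation of Spearman(order, arbitrary rank).

        With every instance selected, each trial contributes the full rank
        set 1..n_i in a uniform random permutation, so the pooled multiset of
        arbitrary ranks is fixed and the correlation is linear in the
        per-record expectations: E[pooled midrank of record in trial i] is
        the average pooled midrank of the values 1..n_i.
        """
        pooled_vals = records.groupby("trial_id")["order"].max().map(
            lambda n: list(range(1, int(n) + 1)))
        all_vals = np.concatenate(pooled_vals.to_list()).astype(float)
        pooled_midrank = {}
        ranks = stats.rankdata(all_vals, method="average")
        for v, r in zip(all_vals, ranks):
            pooled_midrank[v] = r
        order_rank = stats.rankdata(records["order"], method="average")
        mean_mid_by_trial = {
            tid: np.mean([pooled_midrank[v] for v in vals])
            for tid, vals in pooled_vals.items()}
        e_arb = records["trial_id"].map(mean_mid_by_trial).to_numpy()
        e_num = np.mean(order_rank * e_arb) - order_rank.mean() * ranks.mean()
        sd_arb = ranks.std()
        sd_ord = order_rank.std()
        return e_num / (sd_arb * sd_ord)

    def test_baseline_mean_matches_enumeration_oracle(self):
        sc, rec = self._fixture()
        expected = self._expected_correlation(rec)
        assert expected > 0.2  # composition alone induces a positive baseline
        base = arbitrary_rank_baseline(rec, sc, np.random.default_rng(101),
                                       n_reps=100)
        mc_err = base["sd"] / math.sqrt(base["n_reps"])
        assert abs(base["mean"] - expected) < 4 * mc_err + 1e-9

    def test_comparison_on_simulated_cohort(self, exp2_scored):
        _, sc = exp2_scored
        rec = build_order_dataset(sc)
        res = compare_size_vs_arbitrary(rec, sc, np.random.default_rng(8))
        assert res.df == len(rec) - 3
        # size salience in the generator puts size above the arbitrary baseline
        assert res.r12 > res.r13
        assert res.t > 0


class TestColorByOrder:
    def test_all_matched(self):
        cells = {("p", "t"): [("TP", f"t:{k}", 100.0 * k, k, 1)
                              for k in range(1, 5)]}
        rec = build_order_dataset(make_scored(cells))
        out = color_match_by_order(rec)
        assert (out["per_order"]["frac_color_match"] == 1.0).all()
        assert math.isnan(out["order_match_spearman_r"])

    def test_match_only_first(self):
        cells = {(f"p{j}", f"t{j}"): [
            ("TP", f"t{j}:{k}", 100.0 * k, k, int(k == 1))
            for k in range(1, 4)] for j in range(4)}
        rec = build_order_dataset(make_scored(cells))
        out = color_match_by_order(rec)
        per = out["per_order"].set_index("order")
        assert per.loc[1, "frac_color_match"] == 1.0
        assert (per.loc[2:, "frac_color_match"] == 0.0).all()
        assert out["order_match_spearman_r"] < 0

    def test_simulated_color_salience_negative_correlation(self, exp2_scored):
        _, sc = exp2_scored
        rec = build_order_dataset(sc)
        out = color_match_by_order(rec)
        assert out["order_match_spearman_r"] < 0
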