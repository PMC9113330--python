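from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from stablephos import (
    Partition,
    SiteId,
    StabilityFeatures,
    StabilityResult,
    concordance,
    group_change_comparison,
    rank_groups,
    subset_and_cluster,
)

from conftest import make_table


def _result(i: int, p: float, is_sps: bool) -> StabilityResult:
    site = SiteId(f"G{i}", "S", 1)
    feats = StabilityFeatures(site=site, recurrence=5, phospho_change=0.5, n_contributing=5)
    return StabilityResult(
        site=site, features=feats, p_recurrence=p, p_change=p, p_combined=p, is_sps=is_sps
    )


class TestConcordance:
    def test_identical_partitions_score_one_everywhere(self):
        p = Partition({"a": 1, "b": 1, "c": 2, "d": 3})
        q = Partition({"a": "x", "b": "x", "c": "y", "d": "z"})  # same partition, new labels
        rep = concordance(q, p)
        assert rep.as_dict() == {"ari": 1.0, "fmi": 1.0, "nmi": 1.0, "purity": 1.0, "jaccard": 1.0}

    def test_crossed_partition_hand_enumerated(self):
        # truth {a,b | c,d} vs clustering {a,c | b,d}: over the 6 sample pairs
        # TP=0, FP=2, FN=2 -> Jaccard 0, and ARI = -0.5 by the adjusted formula
        truth = Partition({"a": 1, "b": 1, "c": 2, "d": 2})
        clust = Partition({"a": 1, "b": 2, "c": 1, "d": 2})
        rep = concordance(clust, truth)
        assert rep.ari == pytest.approx(-0.5)
        assert rep.jaccard == 0.0
        assert rep.fmi == 0.0
        assert rep.nmi == pytest.approx(0.0, abs=1e-12)
        assert rep.purity == pytest.approx(0.5)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        samples = [f"s{i}" for i in range(30)]
        t = {s: int(x) for s, x in zip(samples, rng.integers(0, 4, 30))}
        c = {s: int(x) for s, x in zip(samples, rng.integers(0, 3, 30))}
        relabeled = {s: f"cluster_{v}" for s, v in c.items()}
        r1 = concordance(Partition(c), Partition(t))
        r2 = concordance(Partition(relabeled), Partition(t))
        assert r1.as_dict() == pytest.approx(r2.as_dict())

    def test_sample_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            concordance(Partition({"a": 1}), Partition({"b": 1}))

    def test_purity_monotone_under_refinement(self):
        truth = Partition({s: s[0] for s in ["a1", "a2", "b1", "b2", "b3", "c1"]})
        coarse = Partition({"a1": 1, "a2": 1, "b1": 1, "b2": 2, "b3": 2, "c1": 2})
        refined = Partition({"a1": 1, "a2": 3, "b1": 1, "b2": 2, "b3": 4, "c1": 2})
        singletons = Partition({s: i for i, s in enumerate(truth.labels)})
        p_coarse = concordance(coarse, truth).purity
        p_refined = concordance(refined, truth).purity
        assert p_coarse <= p_refined <= concordance(singletons, truth).purity == 1.0

    def test_agrees_with_sklearn_on_random_partitions(self):
        from sklearn.metrics import (
            adjusted_rand_score,
            fowlkes_mallows_score,
            normalized_mutual_info_score,
        )

        rng = np.random.default_rng(4)
        samples = [f"s{i}" for i in range(40)]
        for _ in range(50):
            t = rng.integers(0, 5, 40)
            c = rng.integers(0, 4, 40)
            rep = concordance(
                Partition(dict(zip(samples, (int(x) for x in c)))),
                Partition(dict(zip(samples, (int(x) for x in t)))),
            )
            tt = [t[samples.index(s)] for s in sorted(samples)]
            cc = [c[samples.index(s)] for s in sorted(samples)]
            assert rep.ari == pytest.approx(adjusted_rand_score(tt, cc), abs=1e-10)
            assert rep.fmi == pytest.approx(fowlkes_mallows_score(tt, cc), abs=1e-10)
            assert rep.nmi == pytest.approx(
                normalized_mutual_info_score(tt, cc, average_method="arithmetic"), abs=1e-8
            )


class TestRankGroups:
    def test_mid_window_centering_hand_enumerated(self):
        # 9 ranked sites, 3 SPSs, n=3: mid = ranks 4-6, bottom = ranks 7-9
        results = [_result(i, p=(i + 1) / 100.0, is_sps=i < 3) for i in range(9)]
        sps, mid, bottom, non_sps = rank_groups(results, n=3)
        assert sps == {r.site for r in results[:3]}
        assert mid == {r.site for r in results[3:6]}
        assert bottom == {r.site for r in results[6:9]}
        assert non_sps == {r.site for r in results[3:]}
        assert sps & bottom == set()

    def test_group_size_limit(self):
        results = [_result(i, p=(i + 1) / 100.0, is_sps=i < 3) for i in range(9)]
        with pytest.raises(ValueError, match="too large"):
            rank_groups(results, n=4)
        with pytest.raises(ValueError, match="too large"):
            rank_groups(results, n=9)

    def test_sorting_is_internal(self):
        results = [_result(i, p=(i + 1) / 100.0, is_sps=i < 3) for i in range(9)]
        shuffled = [results[i] for i in [4, 0, 8, 2, 6, 1, 5, 3, 7]]
        assert rank_groups(shuffled, n=3) == rank_groups(results, n=3)


class TestGroupChangeComparison:
    def _groups_and_table(self, rng, shift_sps=0.0):
        sites = {g: [SiteId(f"{g.upper()}{i}", "S", 1) for i in range(10)] for g in ("s", "m", "b", "n")}
        rows = {}
        for g, ss in sites.items():
            loc = shift_sps if g == "s" else 1.0
            for s in ss:
                rows[str(s)] = list(rng.normal(loc, 0.2, size=3))
        table = make_table("eval", rows, ["x", "y", "z"])
        groups = (set(sites["s"]), set(sites["m"]), set(sites["b"]), set(sites["n"]))
        return groups, table

    def test_null_one_sided_p_is_central(self):
        rng = np.random.default_rng(8)
        groups, table = self._groups_and_table(rng, shift_sps=1.0)  # identical distributions
        comp = group_change_comparison(groups, table)
        assert 0.05 < comp.p_less["mid"] < 0.95

    def test_shifted_sps_group_detected(self):
        rng = np.random.default_rng(9)
        groups, table = self._groups_and_table(rng, shift_sps=0.1)
        comp = group_change_comparison(groups, table)
        assert comp.medians["sps"] < comp.medians["mid"]
        assert comp.p_less["mid"] < 1e-3

    def test_insufficient_overlap_names_group(self):
        rng = np.random.default_rng(10)
        groups, table = self._groups_and_table(rng)
        groups = (set(list(groups[0])[:2]), groups[1], groups[2], groups[3])
        with pytest.raises(ValueError, match="sps"):
            group_change_comparison(groups, table)

    def test_ranksum_p_matches_permutation_oracle(self):
        from scipy.stats import mannwhitneyu

        rng = np.random.default_rng(12)
        x = rng.normal(0.0, 1.0, 10)
        y = rng.normal(0.8, 1.0, 10)
        p_exact = mannwhitneyu(x, y, alternative="less").pvalue
        pooled = np.concatenate([x, y])
        u_obs = mannwhitneyu(x, y, alternative="less").statistic
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            perm = rng.permutation(pooled)
            u = mannwhitneyu(perm[:10], perm[10:], alternative="less").statistic
            if u <= u_obs:
                count += 1
        p_perm = (count + 1) / (n_perm + 1)
        mc_err = 4 * math.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_exact - p_perm) < max(mc_err, 0.01)


class TestSubsetAndCluster:
    def test_separable_duplicated_groups_recovered(self):
        rng = np.random.default_rng(1)
        sites = [f"P{i}_S1" for i in range(20)]
        profile_a = rng.normal(0, 0.05, size=(20, 3))
        profile_b = profile_a + 5.0
        rows = {s: list(profile_a[i]) + list(profile_b[i]) for i, s in enumerate(sites)}
        table = make_table("e", rows, ["a1", "a2", "a3", "b1", "b2", "b3"])
        part = subset_and_cluster(table, table.site_set, k=2)
        truth = Partition({c: c[0] for c in table.conditions})
        assert concordance(part, truth).ari == 1.0

    def test_missing_values_handled_by_pairwise_complete_distance(self):
        rng = np.random.default_rng(6)
        rows = {
            f"P{i}_S1": [float(v) if rng.random() > 0.2 else None for v in rng.normal(size=4)]
            for i in range(30)
        }
        rows["P0_S1"] = [1.0, 1.0, 1.0, 1.0]  # guarantee shared observations
        table = make_table("e", rows, ["w", "x", "y", "z"])
        part = subset_and_cluster(table, table.site_set, k=2)
        assert set(part.labels) == set(table.conditions)
        assert len(set(part.labels.values())) == 2

    def test_deterministic(self, eval_data):
        table, _ = eval_data
        p1 = subset_and_cluster(table, table.site_set, k=4, seed=0)
        p2 = subset_and_cluster(table, table.site_set, k=4, seed=99)
        assert p1.labels == p2.labels  # no randomness involved

    def test_insufficient_sites_errors(self, eval_data):
        table, _ = eval_data
        with pytest.raises(ValueError, match="site"):
            subset_and_cluster(table, {SiteId("NOPE", "S", 1)}, k=2)
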