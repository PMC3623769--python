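import numpy as np
import pytest
from scipy import stats as sps

from ystrpopgen.amova import (
    amova_one_factor,
    amova_two_factor,
    matched_subsample_amova,
)


def pairwise_ssd_oracle(x, labels):
    """Independent one-factor AMOVA oracle computed literally from pairwise
    squared distances: SSD(T) = (1/2n) sum_ij d2, SSD within per group, then
    the unequal-n variance-component equations."""
    x = np.asarray(x, float)
    labels = np.asarray(labels)
    n = len(x)
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    ssd_t = d2.sum() / (2 * n)
    groups = sorted(set(labels.tolist()))
    ssd_w = 0.0
    sizes = []
    for g in groups:
        idx = np.flatnonzero(labels == g)
        sizes.append(len(idx))
        ssd_w += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    G = len(groups)
    sigma_w = ssd_w / (n - G)
    nprime = (n - sum(s * s for s in sizes) / n) / (G - 1)
    sigma_a = ((ssd_t - ssd_w) / (G - 1) - sigma_w) / nprime
    return sigma_a, sigma_w


class TestOneFactor:
    def test_spec_toy_matches_pairwise_oracle(self, make_table):
        t = make_table({"A": [10, 10, 12], "B": [12, 14, 14]})
        res = amova_one_factor(
            t, {r.sample_id: r.site_id for r in t.records}, ("M1",), permutations=0
        )
        sa, sw = pairwise_ssd_oracle([[v] for v in [10, 10, 12, 12, 14, 14]], [0, 0, 0, 1, 1, 1])
        assert res.components["among"] == pytest.approx(sa)
        assert res.components["within"] == pytest.approx(sw)
        assert sum(res.percentages.values()) == pytest.approx(100.0)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_small_instances_match_oracle(self, make_table, seed):
        rng = np.random.default_rng(seed)
        sizes = rng.integers(1, 4, size=3)
        while sizes.sum() < 4:
            sizes = rng.integers(1, 4, size=3)
        vals = {f"S{i}": list(rng.integers(8, 20, size=k)) for i, k in enumerate(sizes)}
        t = make_table(vals)
        res = amova_one_factor(
            t, {r.sample_id: r.site_id for r in t.records}, ("M1",), permutations=0
        )
        x, lab = [], []
        for i, k in enumerate(sizes):
            x += [[v] for v in vals[f"S{i}"]]
            lab += [i] * k
        sa, sw = pairwise_ssd_oracle(x, lab)
        assert res.components["among"] == pytest.approx(sa)
        assert res.components["within"] == pytest.approx(sw)

    def test_each_distinct_value_its_own_group_is_all_among(self, make_table):
        t = make_table({"A": [10] * 3, "B": [14] * 3, "C": [20] * 3})
        res = amova_one_factor(
            t, {r.sample_id: r.site_id for r in t.records}, ("M1",), permutations=499, seed=0
        )
        assert res.percentages["among"] == pytest.approx(100.0)
        # only 6 of the 9!/(3!)^3 label arrangements separate perfectly
        assert res.p_values["Phi_ST"] <= 0.02

    def test_single_group_zero_among(self, make_table):
        t = make_table({"A": [10, 12], "B": [11, 13]})
        grouping = {r.sample_id: "all" for r in t.records}
        with pytest.raises(ValueError):
            amova_one_factor(t, grouping, ("M1",), permutations=0)

    def test_zero_variance_flagged_not_crashing(self, make_table):
        t = make_table({"A": [10, 10], "B": [10, 10]})
        res = amova_one_factor(
            t, {r.sample_id: r.site_id for r in t.records}, ("M1",), permutations=0
        )
        assert res.degenerate and res.percentages is None

    def test_shift_and_marker_relabel_invariance(self, make_table):
        rng = np.random.default_rng(3)
        a = list(rng.integers(10, 18, size=5))
        b = list(rng.integers(10, 18, size=6))
        t1 = make_table({"A": a, "B": b})
        t2 = make_table({"A": [v + 9 for v in a], "B": [v + 9 for v in b]})
        g = lambda t: {r.sample_id: r.site_id for r in t.records}
        r1 = amova_one_factor(t1, g(t1), ("M1",), permutations=0)
        r2 = amova_one_factor(t2, g(t2), ("M1",), permutations=0)
        assert r1.components == pytest.approx(r2.components)

    def test_permutation_p_uniform_under_null(self, make_table):
        """Under exchangeable labels the permutation p-value is uniform on
        {1/(R+1), ..., 1}; checked by a KS test over null datasets."""
        rng = np.random.default_rng(7)
        pvals = []
        for rep in range(300):
            pool = rng.integers(10, 40, size=12)
            t = make_table({"A": list(pool[:6]), "B": list(pool[6:])})
            res = amova_one_factor(
                t,
                {r.sample_id: r.site_id for r in t.records},
                ("M1",),
                permutations=99,
                seed=int(rng.integers(2**31)),
            )
            pvals.append(res.p_values["Phi_ST"])
        assert sps.kstest(pvals, "uniform").pvalue > 0.01


class TestTwoFactor:
    def _nested_table(self, make_table, seed=0, shift=(0, 2)):
        rng = np.random.default_rng(seed)
        groups, cluster_of = {}, {}
        for s in range(4):
            c = f"A{s // 2 + 1}"
            cluster_of[f"S{s}"] = c
            groups[f"S{s}"] = list(rng.integers(10, 15, size=3) + shift[s // 2])
        return make_table(groups, cluster_of=cluster_of), cluster_of

    def test_matches_pairwise_nested_oracle(self, make_table):
        t, cluster_of = self._nested_table(make_table)
        site_g = {r.sample_id: r.site_id for r in t.records}
        clus_g = {r.sample_id: cluster_of[r.site_id] for r in t.records}
        res = amova_two_factor(t, site_g, clus_g, ("M1",), permutations=0)

        # oracle straight from pairwise squared distances and the nested
        # expected-mean-square equations
        x = np.array([[float(r.str_profile["M1"])] for r in t.records])
        site = np.array([int(r.site_id[1]) for r in t.records])
        clus = site // 2
        n = len(x)
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)

        def ssd(idx):
            return d2[np.ix_(idx, idx)].sum() / (2 * len(idx))

        ssd_t = ssd(np.arange(n))
        ssd_wp = sum(ssd(np.flatnonzero(site == s)) for s in set(site))
        ssd_wg = sum(ssd(np.flatnonzero(clus == c)) for c in set(clus))
        P, G = len(set(site)), len(set(clus))
        sc = ssd_wp / (n - P)
        np_sizes = np.bincount(site)
        ng_sizes = np.bincount(clus)
        s_np2_ng = sum(
            (np_sizes[[s for s in set(site) if s // 2 == c]] ** 2).sum() / ng_sizes[c]
            for c in set(clus)
        )
        n1 = (n - s_np2_ng) / (P - G)
        n2 = (s_np2_ng - (np_sizes**2).sum() / n) / (G - 1)
        n3 = (n - (ng_sizes**2).sum() / n) / (G - 1)
        sb = ((ssd_wg - ssd_wp) / (P - G) - sc) / n1
        sa = ((ssd_t - ssd_wg) / (G - 1) - sc - n2 * sb) / n3
        assert res.components["within_sites"] == pytest.approx(sc)
        assert res.components["among_sites_within"] == pytest.approx(sb)
        assert res.components["among_clusters"] == pytest.approx(sa)

    def test_one_site_per_cluster_collapses_to_one_factor(self, make_table):
        rng = np.random.default_rng(5)
        groups = {f"S{s}": list(rng.integers(10, 16, size=4)) for s in range(4)}
        t = make_table(groups)
        site_g = {r.sample_id: r.site_id for r in t.records}
        one = amova_one_factor(t, site_g, ("M1",), permutations=0)
        two = amova_two_factor(t, site_g, dict(site_g), ("M1",), permutations=0)
        assert two.components["among_sites_within"] == pytest.approx(0.0)
        assert two.components["among_clusters"] == pytest.approx(one.components["among"])
        assert "cluster with a single site" in two.flags

    def test_cluster_recovery_on_structured_data(self, make_table):
        # clusters separated by a big shift: among-cluster dominates
        t, cluster_of = self._nested_table(make_table, seed=2, shift=(0, 12))
        site_g = {r.sample_id: r.site_id for r in t.records}
        clus_g = {r.sample_id: cluster_of[r.site_id] for r in t.records}
        res = amova_two_factor(t, site_g, clus_g, ("M1",), permutations=199, seed=0)
        assert res.percentages["among_clusters"] > 60.0
        assert res.p_values["Phi_CT"] <= 0.35  # only 3 distinct site-to-cluster splits

    def test_non_nested_sites_rejected(self, make_table):
        t, cluster_of = self._nested_table(make_table)
        site_g = {r.sample_id: r.site_id for r in t.records}
        clus_g = {r.sample_id: ("A1" if i % 2 else "A2") for i, r in enumerate(t.records)}
        with pytest.raises(ValueError, match="nested"):
            amova_two_factor(t, site_g, clus_g, ("M1",), permutations=0)


class TestMatchedSubsample:
    def _reference(self, make_table, seed=0):
        rng = np.random.default_rng(seed)
        groups, cluster_of = {}, {}
        for s in range(8):
            c = f"A{s // 2 + 1}"
            cluster_of[f"S{s}"] = c
            groups[f"S{s}"] = list(rng.integers(10, 15, size=6) + 2 * (s // 2))
        return make_table(groups, cluster_of=cluster_of)

    def test_full_template_reproduces_full_amova(self, make_table):
        t = self._reference(make_table)
        res = matched_subsample_amova(
            t, [6] * 8, n_replicates=4, marker_set=("M1",), seed=1
        )
        site_g = {r.sample_id: r.site_id for r in t.records}
        clus_g = {r.sample_id: t.sites[r.site_id].cluster_A for r in t.records}
        full = amova_two_factor(t, site_g, clus_g, ("M1",), permutations=0)
        for p in res.percentages:
            assert p == pytest.approx(full.percentages["among_clusters"])

    def test_deterministic_under_fixed_seed(self, make_table):
        t = self._reference(make_table)
        a = matched_subsample_amova(t, [4] * 5, n_replicates=1, marker_set=("M1",), seed=9)
        b = matched_subsample_amova(t, [4] * 5, n_replicates=1, marker_set=("M1",), seed=9)
        assert a.percentages == b.percentages

    def test_subsample_brackets_full_value(self, make_table):
        t = self._reference(make_table, seed=3)
        res = matched_subsample_amova(t, [5] * 6, n_replicates=25, marker_set=("M1",), seed=2)
        site_g = {r.sample_id: r.site_id for r in t.records}
        clus_g = {r.sample_id: t.sites[r.site_id].cluster_A for r in t.records}
        full = amova_two_factor(t, site_g, clus_g, ("M1",), permutations=0)
        target = full.percentages["among_clusters"]
        assert res.minimum - 10 < target < res.maximum + 10

    def test_unattainable_template_lists_blocking_sizes(self, make_table):
        t = self._reference(make_table)
        with pytest.raises(ValueError, match="blocking"):
            matched_subsample_amova(t, [50, 4], n_replicates=1, marker_set=("M1",), seed=0)
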