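import numpy as np
import pytest

from ystrpopgen.autocorr import (
    DistanceClassing,
    build_distance_classes,
    morans_i,
    spatial_autocorrelogram,
)
from ystrpopgen.data import SampleTable


def classing_from_pairs(n, pairs_by_class):
    """Hand-built classing for formula tests."""
    empty = (np.array([], int), np.array([], int))
    pairs = [empty] + [
        (np.array([a for a, _ in ps]), np.array([b for _, b in ps]))
        for ps in pairs_by_class
    ]
    return DistanceClassing(
        sample_ids=tuple(f"x{i}" for i in range(n)),
        bounds=[(0.0, 0.0)] + [(0.0, 1.0)] * len(pairs_by_class),
        pair_counts=[0] + [len(p) for p in pairs_by_class],
        pairs=pairs,
    )


class TestMoransI:
    def test_hand_computed_four_point_example(self):
        c = classing_from_pairs(4, [[(0, 1), (2, 3)]])
        assert morans_i([1, 2, 3, 4], c, 1) == pytest.approx(0.6)

    def test_complete_graph_equals_expected_value(self):
        n = 7
        ii, jj = np.triu_indices(n, 1)
        c = classing_from_pairs(n, [list(zip(ii, jj))])
        vals = np.random.default_rng(0).normal(size=n)
        assert morans_i(vals, c, 1) == pytest.approx(-1.0 / (n - 1))

    def test_expected_value_closed_form(self):
        n = 11
        assert -1.0 / (n - 1) == pytest.approx(-0.1)

    def test_monomorphic_rejected(self):
        c = classing_from_pairs(4, [[(0, 1)]])
        with pytest.raises(ValueError, match="monomorphic"):
            morans_i([5, 5, 5, 5], c, 1)

    def test_empty_class_is_nan(self):
        c = classing_from_pairs(4, [[(0, 1)]])
        assert np.isnan(morans_i([1, 2, 3, 4], c, 0))


class TestDistanceClasses:
    def test_two_site_enumeration(self, make_table):
        t = make_table(
            {"A": [10, 11], "B": [12, 13]}, coords={"A": (0.0, 0.0), "B": (0.9, 0.0)}
        )
        c = build_distance_classes(t.sites, t, k=1)
        assert c.pair_counts == [2, 4]
        assert c.bounds[0] == (0.0, 0.0)
        assert c.bounds[1][1] == pytest.approx(100.0, rel=0.01)

    def test_equal_pair_counts_within_one(self, survey):
        from ystrpopgen.data import filter_complete
        from ystrpopgen.markers import SMALL_SET

        t = filter_complete(survey, SMALL_SET)
        c = build_distance_classes(t.sites, t, k=10)
        nonzero = c.pair_counts[1:]
        assert max(nonzero) - min(nonzero) <= 1
        n = len(t.records)
        assert sum(c.pair_counts) == n * (n - 1) // 2

    def test_quantile_split_matches_sort_oracle(self, make_table):
        # 4 sites on a line -> 12-sample pair set with known distances
        coords = {"A": (0.0, 0.0), "B": (1.0, 0.0), "C": (3.0, 0.0), "D": (6.0, 0.0)}
        t = make_table({s: [10, 11] for s in "ABCD"}, coords=coords)
        c = build_distance_classes(t.sites, t, k=3)
        # oracle: sort all nonzero pair distances, split into 3 runs of 8
        from ystrpopgen.distance import great_circle_distance

        site_of = {r.sample_id: r.site_id for r in t.records}
        ids = [r.sample_id for r in t.records]
        dists = []
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                d = great_circle_distance(
                    coords[site_of[ids[i]]], coords[site_of[ids[j]]]
                )
                if d > 0:
                    dists.append(d)
        dists.sort()
        expected_chunks = [dists[0:8], dists[8:16], dists[16:24]]
        for k in (1, 2, 3):
            a, b = c.pairs[k]
            got = sorted(
                great_circle_distance(coords[site_of[ids[x]]], coords[site_of[ids[y]]])
                for x, y in zip(a, b)
            )
            assert got == pytest.approx(expected_chunks[k - 1])

    def test_single_site_rejected(self, make_table):
        t = make_table({"A": [10, 11, 12]})
        with pytest.raises(ValueError):
            build_distance_classes(t.sites, t, k=2)

    def test_class_union_covers_all_pairs(self, make_table):
        t = make_table(
            {s: [10, 11, 12] for s in "ABC"},
            coords={"A": (0, 0), "B": (2, 0), "C": (5, 0)},
        )
        c = build_distance_classes(t.sites, t, k=3)
        seen = set()
        for a, b in c.pairs:
            for x, y in zip(a, b):
                assert (x, y) not in seen
                seen.add((x, y))
        assert len(seen) == 9 * 8 // 2


class TestAutocorrelogram:
    def test_reproducible_with_seed(self, make_table):
        t = make_table(
            {s: list(np.random.default_rng(int(s, 36)).integers(10, 16, 4)) for s in "AB"},
            coords={"A": (0, 0), "B": (3, 0)},
        )
        c = build_distance_classes(t.sites, t, k=1)
        r1 = spatial_autocorrelogram(t, ("M1",), c, permutations=200, seed=5)
        r2 = spatial_autocorrelogram(t, ("M1",), c, permutations=200, seed=5)
        assert [x.p_value for x in r1] == [x.p_value for x in r2]
        assert [x.i_mean for x in r1] == [x.i_mean for x in r2]

    def test_null_calibration(self, make_table):
        """With haplotypes unrelated to geography, ~5% of class p-values fall
        below 0.05."""
        rng = np.random.default_rng(11)
        hits = trials = 0
        coords = {s: (float(i), 0.0) for i, s in enumerate("ABCDE")}
        for rep in range(150):
            t = make_table(
                {s: list(rng.integers(10, 30, size=6)) for s in "ABCDE"},
                coords=coords,
            )
            c = build_distance_classes(t.sites, t, k=3)
            res = spatial_autocorrelogram(
                t, ("M1",), c, permutations=99, seed=int(rng.integers(2**31))
            )
            for r in res:
                trials += 1
                hits += r.p_value <= 0.05
        frac = hits / trials
        assert 0.02 < frac < 0.085, frac

    def test_isolation_by_distance_ordering(self):
        """Stepping-stone migration: short-distance classes show stronger
        repeat-number correlation than the longest-distance class."""
        from ystrpopgen.simulate import SimConfig, simulate_dataset
        from ystrpopgen.markers import SMALL_SET
        from ystrpopgen.data import filter_complete

        wins = 0
        reps = 15
        for rep in range(reps):
            cfg = SimConfig(
                n_sites=8,
                site_sizes=[8] * 8,
                n_demes=4,
                deme_size=150.0,
                migration_rate=0.01,
                migration_model="stepping_stone",
                rare_clades={},
                dominant_frequency=1.0,
                seed=900 + rep,
            )
            table, _ = simulate_dataset(cfg)
            t = filter_complete(table, SMALL_SET)
            c = build_distance_classes(t.sites, t, k=4)
            res = spatial_autocorrelogram(t, SMALL_SET, c, permutations=0)
            wins += res[1].i_mean > res[4].i_mean
        assert wins >= int(0.8 * reps), wins

    def test_averaging_convention_pinned(self):
        """Per-marker I then unweighted mean differs from pooled cross-products
        when marker variances differ; this pins the implemented convention."""
        n = 6
        ii, jj = np.triu_indices(n, 1)
        c = classing_from_pairs(n, [list(zip(ii[:5], jj[:5]))])
        rng = np.random.default_rng(2)
        x1 = rng.normal(size=n)  # variance ~1
        x2 = 10.0 * rng.normal(size=n)  # variance ~100
        i1 = morans_i(x1, c, 1)
        i2 = morans_i(x2, c, 1)
        mean_i = 0.5 * (i1 + i2)
        # pooled alternative: weight by marker variance
        z1, z2 = x1 - x1.mean(), x2 - x2.mean()
        pooled = (
            n
            / (2.0 * 5)
            * 2.0
            * ((z1[ii[:5]] * z1[jj[:5]]).sum() + (z2[ii[:5]] * z2[jj[:5]]).sum())
            / ((z1**2).sum() + (z2**2).sum())
        )
        assert mean_i != pytest.approx(pooled, abs=1e-6)
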