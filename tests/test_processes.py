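import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ecolinks import (
    AbundanceTable,
    AssociationNetwork,
    DistanceMatrix,
    EnvTable,
    GeoTable,
    ValidationError,
    assign_processes,
    env_distance,
    generate_community,
    geo_distance,
    mantel_test,
    pair_abundance_distance,
    process_fractions,
    screen_env_covariance,
)
from ecolinks.simulate import SyntheticSpec


class TestGeoDistance:
    def test_same_point_zero(self):
        geo = GeoTable(
            pd.DataFrame({"longitude": [5.0, 5.0], "latitude": [10.0, 10.0]}, index=["a", "b"])
        )
        assert geo_distance(geo).values[0, 1] == 0.0

    def test_haversine_quarter_circle(self):
        geo = GeoTable(
            pd.DataFrame({"longitude": [0.0, 90.0], "latitude": [0.0, 0.0]}, index=["a", "b"])
        )
        d = geo_distance(geo, mode="haversine")
        assert d.values[0, 1] == pytest.approx(6371.0 * math.pi / 2, rel=1e-9)

    def test_symmetry_random(self):
        rng = np.random.default_rng(0)
        geo = GeoTable(
            pd.DataFrame(
                {"longitude": rng.uniform(-180, 180, 8), "latitude": rng.uniform(-90, 90, 8)},
                index=[f"s{i}" for i in range(8)],
            )
        )
        d = geo_distance(geo).values
        np.testing.assert_allclose(d, d.T, atol=1e-12)

    def test_elevation_euclidean_combination(self):
        geo = GeoTable(
            pd.DataFrame(
                {"longitude": [0.0, 0.0], "latitude": [0.0, 0.0], "elevation": [0.0, 1000.0]},
                index=["a", "b"],
            )
        )
        d = geo_distance(geo, include_elevation=True)
        assert d.values[0, 1] == pytest.approx(1.0)  # 1000 m = 1 km

    def test_elevation_missing_errors(self):
        geo = GeoTable(
            pd.DataFrame({"longitude": [0.0], "latitude": [0.0]}, index=["a"])
        )
        with pytest.raises(ValidationError, match="elevation"):
            geo_distance(geo, include_elevation=True)


class TestEnvDistance:
    def test_identical_environments_zero(self):
        env = EnvTable(pd.DataFrame({"ph": [7.0, 7.0], "c": [1.0, 1.0]}, index=["a", "b"]))
        assert env_distance(env, standardize=False).values[0, 1] == 0.0

    def test_single_variable_raw(self):
        env = EnvTable(pd.DataFrame({"x": [1.0, 3.0]}, index=["a", "b"]))
        assert env_distance(env, standardize=False).values[0, 1] == pytest.approx(2.0)

    def test_affine_invariance_under_standardisation(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.random((6, 3)), index=list("abcdef"), columns=["u", "v", "w"])
        d1 = env_distance(EnvTable(df))
        df2 = df.copy()
        df2["v"] = 100.0 * df2["v"] - 7.0
        d2 = env_distance(EnvTable(df2))
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-10)

    def test_zero_variance_named(self):
        env = EnvTable(pd.DataFrame({"flat": [1.0, 1.0], "x": [0.0, 1.0]}, index=["a", "b"]))
        with pytest.raises(ValidationError, match="flat"):
            env_distance(env)


class TestScreenEnvCovariance:
    def test_perfectly_correlated_keeps_first(self):
        x = np.arange(10.0)
        env = EnvTable(pd.DataFrame({"a": x, "b": 2 * x + 1}, index=[f"s{i}" for i in range(10)]))
        assert screen_env_covariance(env) == ["a"]

    def test_independent_variables_all_retained(self):
        rng = np.random.default_rng(5)
        env = EnvTable(
            pd.DataFrame(
                rng.standard_normal((200, 4)),
                index=[f"s{i}" for i in range(200)],
                columns=list("abcd"),
            )
        )
        assert screen_env_covariance(env) == list("abcd")

    def test_single_variable_retained(self):
        env = EnvTable(pd.DataFrame({"only": [1.0, 2.0, 3.0]}, index=["a", "b", "c"]))
        assert screen_env_covariance(env) == ["only"]

    def test_priority_order_respected(self):
        x = np.arange(10.0)
        env = EnvTable(pd.DataFrame({"a": x, "b": 2 * x}, index=[f"s{i}" for i in range(10)]))
        assert screen_env_covariance(env, order=["b", "a"]) == ["b"]


class TestPairAbundanceDistance:
    def make(self, rows):
        return AbundanceTable(
            pd.DataFrame(rows, columns=["X", "Y"], index=[f"s{i}" for i in range(len(rows))])
        )

    def test_identical_pair_abundance_zero(self):
        t = self.make([[1.0, 2.0], [1.0, 2.0]])
        assert pair_abundance_distance(t, "X", "Y").values[0, 1] == 0.0

    def test_euclidean(self):
        t = self.make([[1.0, 0.0], [0.0, 1.0]])
        d = pair_abundance_distance(t, "X", "Y", metric="euclidean")
        assert d.values[0, 1] == pytest.approx(math.sqrt(2))

    def test_braycurtis_disjoint_is_one(self):
        # sum|a-b| / sum(a+b) = 2/2
        t = self.make([[1.0, 0.0], [0.0, 1.0]])
        d = pair_abundance_distance(t, "X", "Y", metric="braycurtis")
        assert d.values[0, 1] == pytest.approx(1.0)

    def test_double_zero_defined_as_zero(self):
        t = self.make([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        d = pair_abundance_distance(t, "X", "Y")
        assert d.values[0, 1] == 0.0

    def test_missing_taxon_errors(self):
        t = self.make([[1.0, 2.0], [2.0, 1.0]])
        with pytest.raises(ValidationError, match="not found"):
            pair_abundance_distance(t, "X", "Z")


def mantel_brute_force(D1, D2):
    """All-permutation oracle: r_obs and p = #{perm: r >= r_obs} / n!."""
    n = D1.shape[0]
    iu = np.triu_indices(n, 1)
    v2 = D2[iu]
    r_obs = np.corrcoef(D1[iu], v2)[0, 1]
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        p = np.array(perm)
        v1 = D1[np.ix_(p, p)][iu]
        if np.corrcoef(v1, v2)[0, 1] >= r_obs - 1e-12:
            count += 1
        total += 1
    return r_obs, count / total


def dm(offdiag3):
    a, b, c = offdiag3
    m = np.array([[0, a, b], [a, 0, c], [b, c, 0]], dtype=float)
    return DistanceMatrix(["x", "y", "z"], m)


class TestMantel:
    def test_exact_enumeration_three_samples(self):
        d1 = dm([1.0, 2.0, 3.0])
        d2 = dm([2.0, 4.0, 6.0])
        res = mantel_test(d1, d2)
        assert res.exact
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.p == pytest.approx(1 / 6)

    def test_self_r_one(self):
        d1 = dm([1.0, 2.0, 3.0])
        assert mantel_test(d1, d1).r == pytest.approx(1.0)

    def test_matches_brute_force_oracle_n5(self):
        rng = np.random.default_rng(9)
        for _ in range(3):
            A = rng.random((5, 5))
            B = rng.random((5, 5))
            D1 = np.triu(A, 1) + np.triu(A, 1).T
            D2 = np.triu(B, 1) + np.triu(B, 1).T
            labels = list("abcde")
            res = mantel_test(DistanceMatrix(labels, D1), DistanceMatrix(labels, D2))
            r_ref, p_ref = mantel_brute_force(D1, D2)
            assert res.exact
            assert res.r == pytest.approx(r_ref, abs=1e-12)
            assert res.p == p_ref

    def test_relabel_invariance_exact(self):
        rng = np.random.default_rng(10)
        A, B = rng.random((4, 4)), rng.random((4, 4))
        D1 = np.triu(A, 1) + np.triu(A, 1).T
        D2 = np.triu(B, 1) + np.triu(B, 1).T
        labels = list("abcd")
        res1 = mantel_test(DistanceMatrix(labels, D1), DistanceMatrix(labels, D2))
        perm = [2, 0, 3, 1]
        P1 = D1[np.ix_(perm, perm)]
        P2 = D2[np.ix_(perm, perm)]
        res2 = mantel_test(DistanceMatrix(labels, P1), DistanceMatrix(labels, P2))
        assert res1.r == pytest.approx(res2.r, abs=1e-12)
        assert res1.p == res2.p

    def test_label_mismatch_errors(self):
        d1 = dm([1.0, 2.0, 3.0])
        d2 = DistanceMatrix(["x", "y", "w"], d1.values)
        with pytest.raises(ValidationError, match="label"):
            mantel_test(d1, d2)

    def test_zero_variance_warns(self):
        d1 = dm([1.0, 1.0, 1.0])
        d2 = dm([1.0, 2.0, 3.0])
        with pytest.warns(UserWarning, match="zero variance"):
            res = mantel_test(d1, d2)
        assert (res.r, res.p) == (0.0, 1.0)

    def test_null_pvalues_super_uniform(self):
        # i.i.d. noise matrices: empirical Pr(p < 0.05) should stay near 0.05
        rng = np.random.default_rng(11)
        n = 12
        labels = [f"s{i}" for i in range(n)]
        hits = 0
        reps = 400
        for k in range(reps):
            A, B = rng.random((n, n)), rng.random((n, n))
            D1 = np.triu(A, 1) + np.triu(A, 1).T
            D2 = np.triu(B, 1) + np.triu(B, 1).T
            res = mantel_test(
                DistanceMatrix(labels, D1), DistanceMatrix(labels, D2),
                n_perm=99, seed=k,
            )
            hits += res.p < 0.05
        assert hits / reps <= 0.08

    def test_spearman_mode(self):
        d1 = dm([1.0, 2.0, 3.0])
        d2 = dm([1.0, 8.0, 27.0])  # monotone transform
        res = mantel_test(d1, d2, method="spearman")
        assert res.r == pytest.approx(1.0)


@pytest.fixture(scope="module")
def planted():
    spec = SyntheticSpec(
        n_samples=60, n_noise_taxa=40, n_env_pairs=4, n_space_pairs=4,
        n_biotic_pos_pairs=4, seed=21,
    )
    bundle = generate_community(spec)
    edges = [(r.taxon_a, r.taxon_b, r.sign) for r in bundle.truth.table.itertuples()]
    net = AssociationNetwork.from_edges(bundle.table.taxa, edges)
    geo_d = geo_distance(bundle.geo, mode="euclidean")
    env_d = env_distance(bundle.env)
    assignment = assign_processes(
        net, bundle.table, geo_d, env_d, n_perm=199, seed=1
    )
    return bundle, assignment


class TestAssignProcesses:
    def test_planted_env_pairs_classified_env_or_overlap(self, planted):
        bundle, assignment = planted
        truth = {
            tuple(sorted((r.taxon_a, r.taxon_b))): r.true_class
            for r in bundle.truth.table.itertuples()
        }
        for row in assignment.table.itertuples():
            key = tuple(sorted((row.taxon_a, row.taxon_b)))
            if truth[key] == "environmental_selection":
                assert row.process in ("environmental_selection", "overlap")

    def test_planted_space_pairs_classified_dl_or_overlap(self, planted):
        bundle, assignment = planted
        truth = {
            tuple(sorted((r.taxon_a, r.taxon_b))): r.true_class
            for r in bundle.truth.table.itertuples()
        }
        for row in assignment.table.itertuples():
            key = tuple(sorted((row.taxon_a, row.taxon_b)))
            if truth[key] == "dispersal_limitation":
                assert row.process in ("dispersal_limitation", "overlap")

    def test_most_biotic_pairs_recovered(self, planted):
        bundle, assignment = planted
        truth = {
            tuple(sorted((r.taxon_a, r.taxon_b))): r.true_class
            for r in bundle.truth.table.itertuples()
        }
        biotic = [
            row.process
            for row in assignment.table.itertuples()
            if truth[tuple(sorted((row.taxon_a, row.taxon_b)))] == "biotic"
        ]
        assert biotic.count("biotic") >= 3  # of 4, at this seed

    def test_deterministic_given_seed(self, planted):
        bundle, assignment = planted
        edges = [(r.taxon_a, r.taxon_b, r.sign) for r in bundle.truth.table.itertuples()]
        net = AssociationNetwork.from_edges(bundle.table.taxa, edges)
        geo_d = geo_distance(bundle.geo, mode="euclidean")
        env_d = env_distance(bundle.env)
        again = assign_processes(net, bundle.table, geo_d, env_d, n_perm=199, seed=1)
        pd.testing.assert_frame_equal(assignment.table, again.table)

    def test_empty_network_empty_assignment(self, planted):
        bundle, _ = planted
        net = AssociationNetwork.from_edges(bundle.table.taxa, [])
        geo_d = geo_distance(bundle.geo, mode="euclidean")
        env_d = env_distance(bundle.env)
        out = assign_processes(net, bundle.table, geo_d, env_d, n_perm=99, seed=0)
        assert len(out.table) == 0


class TestProcessFractions:
    def make_assignment(self, processes):
        from ecolinks.processes import EdgeProcessAssignment

        df = pd.DataFrame(
            {
                "taxon_a": [f"a{i}" for i in range(len(processes))],
                "taxon_b": [f"b{i}" for i in range(len(processes))],
                "weight": 0.5,
                "r_geo": 0.0,
                "p_geo": 1.0,
                "r_env": 0.0,
                "p_env": 1.0,
                "process": processes,
            }
        )
        return EdgeProcessAssignment(df, 0.05, 999)

    def test_counting_example(self):
        fr = process_fractions(
            self.make_assignment(
                ["biotic"] * 7 + ["environmental_selection"] * 2 + ["dispersal_limitation"]
            )
        )
        assert fr == {
            "biotic": 0.7,
            "environmental_selection": 0.2,
            "dispersal_limitation": 0.1,
            "overlap": 0.0,
        }

    def test_all_biotic(self):
        fr = process_fractions(self.make_assignment(["biotic"] * 5))
        assert fr["biotic"] == 1.0

    def test_sums_to_one(self):
        fr = process_fractions(
            self.make_assignment(["biotic", "overlap", "dispersal_limitation"])
        )
        assert sum(fr.values()) == pytest.approx(1.0, abs=1e-12)

    def test_reorder_invariant(self):
        a = ["biotic", "overlap", "biotic", "environmental_selection"]
        assert process_fractions(self.make_assignment(a)) == process_fractions(
            self.make_assignment(list(reversed(a)))
        )

    def test_empty_errors(self):
        with pytest.raises(ValidationError):
            process_fractions(self.make_assignment([]))
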