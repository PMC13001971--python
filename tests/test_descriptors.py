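import itertools
import math

import numpy as np
import pytest

from trophonet.anm_core import NetworkEnsemble, TrophicNetwork, pure_anm_ensemble
from trophonet.descriptors import (
    beta_diversity,
    cohen_chains,
    compute_descriptors,
    connectivity_stats,
    degree_distributions,
    fit_powerlaw_exponent,
    loops,
    model_error,
    nestedness,
    taxonomic_richness,
    topological_consistency,
    trophic_fractions,
)
from trophonet.species_table import SpeciesTable

from conftest import record


def net_from(matrix, ids=None):
    matrix = np.asarray(matrix)
    ids = ids or [f"s{i}" for i in range(matrix.shape[0])]
    return TrophicNetwork(index=ids, matrix=matrix)


class TestDegreeDistributions:
    def test_two_nodes_one_link(self):
        deg, gen, vul = degree_distributions(net_from([[0, 1], [0, 0]]))
        assert deg[1] == 1.0  # both nodes have total degree 1

    def test_star_generality(self):
        T = np.zeros((5, 5), dtype=int)
        T[0, 1:] = 1  # one consumer eats 4 prey
        _, gen, _ = degree_distributions(net_from(T))
        assert gen[4] == pytest.approx(0.2)
        assert gen[0] == pytest.approx(0.8)

    def test_normalization(self, wetland_table):
        from trophonet.anm_core import BuildParams, build_network

        net = build_network(wetland_table, BuildParams(seed=1))
        for vec in degree_distributions(net):
            assert vec.sum() == pytest.approx(1.0)


class TestConnectivityStats:
    def test_formulas(self):
        stats = connectivity_stats(net_from([[0, 1, 0], [0, 0, 1], [1, 0, 0]]))
        assert stats["AVL"] == pytest.approx(1.0)
        assert stats["CON"] == pytest.approx(1 / 3)

    def test_empty_network_convention(self):
        stats = connectivity_stats(net_from(np.zeros((4, 4), dtype=int)))
        assert all(stats[k] == 0 for k in ("AVL", "CON", "IND", "OUT", "ASYM", "MAXDEG"))

    def test_reciprocal_network_symmetric(self):
        T = np.array([[0, 1], [1, 0]])
        assert connectivity_stats(net_from(T))["ASYM"] == 0.0

    def test_ind_over_nonzero_rows_only(self):
        # one consumer with 2 prey, two pure resources: IND = 2, not 2/3
        T = np.array([[0, 1, 1], [0, 0, 0], [0, 0, 0]])
        stats = connectivity_stats(net_from(T))
        assert stats["IND"] == 2.0
        assert stats["OUT"] == 1.0


class TestTrophicFractions:
    def _chain(self):
        table = SpeciesTable(
            "c",
            [
                record("plant", mass=1.0, producer=True),
                record("vole", mass=30.0, diet=("herbivore",)),
                record("fox", mass=5e3, diet=("carnivore",)),
            ],
        )
        net = net_from([[0, 0, 0], [1, 0, 0], [0, 1, 0]], ids=table.taxon_ids)
        return net, table

    def test_three_level_chain(self):
        net, table = self._chain()
        fr = trophic_fractions(net, table)
        for key in ("TOP", "BAS", "INT"):
            assert fr[key] == pytest.approx(1 / 3)
        assert fr["PC"] == pytest.approx(0.5)

    def test_partition_of_unity(self, wetland_table):
        from trophonet.anm_core import BuildParams, build_network

        net = build_network(wetland_table, BuildParams(seed=8))
        fr = trophic_fractions(net, wetland_table)
        assert fr["TOP"] + fr["BAS"] + fr["INT"] == pytest.approx(1.0, abs=1e-12)

    def test_no_producers(self):
        net = net_from([[0, 1], [0, 0]])
        table = SpeciesTable(
            "s",
            [record("a", mass=10.0, diet=("carnivore",)), record("b", mass=1.0, diet=("omnivore",))],
        )
        fr = trophic_fractions(net, table)
        assert fr["BAS"] == 0.0 and fr["PC"] == 0.0

    def test_all_producers_sentinel(self):
        table = SpeciesTable("s", [record("p1", mass=1.0, producer=True), record("p2", mass=1.0, producer=True)])
        net = net_from(np.zeros((2, 2), dtype=int), ids=table.taxon_ids)
        with pytest.warns(UserWarning):
            fr = trophic_fractions(net, table)
        assert math.isinf(fr["PC"])

    def test_strict_detritivores_are_basal(self):
        table = SpeciesTable(
            "s",
            [
                record("worm", mass=1.0, diet=("detritivore",)),
                record("mixed", mass=1.0, diet=("detritivore", "carnivore")),
            ],
        )
        net = net_from(np.zeros((2, 2), dtype=int), ids=table.taxon_ids)
        fr = trophic_fractions(net, table)
        assert fr["BAS"] == pytest.approx(0.5)


# --- brute-force oracles for chains and loops ------------------------------

from oracles import brute_force_chains, brute_force_cycles  # noqa: E402


class TestChainsAndLoops:
    def test_single_chain(self):
        net = net_from([[0, 0, 0], [1, 0, 0], [0, 1, 0]])
        out = cohen_chains(net)
        assert out["NCHA"] == 1 and out["AVGL"] == out["MINL"] == out["MAXCHAIN"] == 3

    def test_diamond(self):
        # plant -> {h1, h2} -> top
        T = np.zeros((4, 4), dtype=int)
        T[1, 0] = T[2, 0] = T[3, 1] = T[3, 2] = 1
        out = cohen_chains(net_from(T))
        assert out["NCHA"] == 2 and out["AVGL"] == pytest.approx(3.0)

    def test_cycle_not_a_chain_end(self):
        # plant -> a; a <-> b form a 2-cycle; c eats a (true top)
        T = np.zeros((4, 4), dtype=int)
        T[1, 0] = 1  # a eats plant
        T[2, 1] = T[1, 2] = 1  # a <-> b
        T[3, 1] = 1  # c eats a
        out = cohen_chains(net_from(T))
        assert out["NCHA"] == 1 and out["MAXCHAIN"] == 3  # plant -> a -> c only

    def test_loop_formulas(self):
        out = loops(net_from([[0, 1], [1, 0]]))
        assert out["NLOOPS"] == 1 and out["LOOP1"] == 0.0
        out = loops(net_from([[0, 1], [0, 0]]))
        assert out["NLOOPS"] == 0 and out["LOOP1"] == pytest.approx(2 / 8)

    def test_acyclic(self):
        T = np.triu(np.ones((4, 4), dtype=int), k=1)
        assert loops(net_from(T))["NLOOPS"] == 0

    def test_oracle_sweep_small_digraphs(self):
        rng = np.random.default_rng(2024)
        for _ in range(120):
            N = int(rng.integers(2, 6))
            T = (rng.uniform(size=(N, N)) < 0.4).astype(int)
            np.fill_diagonal(T, 0)
            net = net_from(T)
            basal = np.asarray(net.matrix).sum(axis=1) == 0
            expected = brute_force_chains(T, basal)
            got = cohen_chains(net)
            assert got["NCHA"] == len(expected)
            if expected:
                assert got["AVGL"] == pytest.approx(np.mean(expected))
                assert got["MAXCHAIN"] == max(expected)
                assert got["MINL"] == min(expected)
            assert loops(net)["NLOOPS"] == brute_force_cycles(T)


class TestNestedness:
    def test_perfectly_nested_scores_zero(self):
        T = np.array(
            [
                [1, 1, 1, 0],
                [1, 1, 0, 0],
                [1, 0, 0, 0],
                [0, 0, 0, 0],
            ]
        )
        assert nestedness(net_from(T)) == 0.0

    def test_checkerboard_matches_brute_force(self):
        T = np.array(
            [
                [1, 0, 1, 0],
                [0, 1, 0, 1],
                [1, 0, 1, 0],
                [0, 1, 0, 1],
            ]
        )
        # independent re-derivation: sort rows/cols by degree (stable),
        # reference = leftmost-d cells per row, count escapees
        row_order = np.argsort(-T.sum(axis=1), kind="stable")
        col_order = np.argsort(-T.sum(axis=0), kind="stable")
        M = T[np.ix_(row_order, col_order)]
        misplaced = sum(int(r.sum()) - int(r[: int(r.sum())].sum()) for r in M)
        assert nestedness(net_from(T)) == pytest.approx(misplaced / T.sum())

    def test_bounds(self, rng):
        for _ in range(50):
            T = (rng.uniform(size=(6, 6)) < 0.3).astype(int)
            assert 0.0 <= nestedness(net_from(T)) <= 1.0

    def test_empty_convention(self):
        assert nestedness(net_from(np.zeros((3, 3), dtype=int))) == 0.0


@pytest.fixture(scope="module")
def baseline():
    rng = np.random.default_rng(3)
    return pure_anm_ensemble(40, 0.12, 25, rng)


class TestModelError:
    def test_scalar_identity_and_shift(self, baseline):
        mean_con = np.mean([net.connectance for net in baseline])
        assert model_error(mean_con, baseline, "CON") == pytest.approx(0.0, abs=1e-12)
        assert model_error(mean_con + 0.3, baseline, "CON") == pytest.approx(0.3)

    def test_vector_identity(self, baseline):
        from trophonet.descriptors import degree_distributions as dd

        vecs = [dd(net)[0] for net in baseline]
        width = max(len(v) for v in vecs)
        mean = np.zeros(width)
        for v in vecs:
            mean[: len(v)] += v / len(vecs)
        assert model_error(mean, baseline, "DEG") == pytest.approx(0.0, abs=1e-12)

    def test_own_replicate_small_error(self, baseline):
        me = model_error(baseline.networks[0].connectance, baseline, "CON")
        assert me < 0.05  # within Monte-Carlo noise of its own ensemble

    def test_minimum_baseline_size(self):
        rng = np.random.default_rng(3)
        small = pure_anm_ensemble(20, 0.12, 5, rng)
        with pytest.raises(ValueError):
            model_error(0.1, small, "CON")


class TestTopologicalConsistency:
    def test_definitions(self):
        always = net_from([[0, 1], [0, 0]])
        never = net_from([[0, 0], [1, 0]])
        ens = NetworkEnsemble("s", [always] * 9 + [never])
        prof = topological_consistency(ens)
        assert prof.link_tc[("s0", "s1")] == pytest.approx(0.9)
        assert prof.link_tc[("s1", "s0")] == pytest.approx(0.1)
        assert sum(prof.histogram.values()) == pytest.approx(1.0)

    def test_needs_two_replicates(self):
        ens = NetworkEnsemble("s", [net_from([[0, 1], [0, 0]])])
        with pytest.raises(ValueError):
            topological_consistency(ens)


class TestBetaDiversity:
    def test_disjoint_is_zero(self):
        assert beta_diversity({"a", "b"}, {"c", "d"}) == 0.0

    def test_identical_is_one(self):
        assert beta_diversity({"a", "b"}, {"a", "b"}) == 1.0

    def test_formula(self):
        site = {f"s{i}" for i in range(10)}
        pool = site | {f"t{i}" for i in range(80)}
        assert beta_diversity(site, pool) == pytest.approx(0.2)


class TestTaxonomicRichness:
    def test_counting(self):
        table = SpeciesTable(
            "s",
            [
                record("a", mass=2.0, diet=("omnivore",), genus="Aus", family="Fam"),
                record("b", mass=8.0, diet=("omnivore",), genus="Aus", family="Fam"),
                record("c", mass=5.0, diet=("omnivore",), genus="Bus", family="Fam"),
            ],
        )
        out = taxonomic_richness(table)
        assert out["N"] == 3 and out["G"] == 2 and out["F"] == 1
        assert out["ABM"] == pytest.approx(5.0)

    def test_producers_excluded_from_averages(self):
        table = SpeciesTable("s", [record("p", mass=100.0, producer=True)])
        out = taxonomic_richness(table)
        assert out["ABM"] is None and out["ABS"] is None

    def test_missing_ranks(self):
        table = SpeciesTable("s", [record("x", mass=1.0, diet=("omnivore",))])
        out = taxonomic_richness(table)
        assert out["G"] is None and out["N"] == 1


def test_powerlaw_exponent_recovers_known_slope(rng):
    # inverse-CDF samples from P(k) ~ k^-2.5
    u = rng.uniform(size=8000)
    k = np.floor((1 - u) ** (-1 / 1.5)).astype(int)
    alpha = fit_powerlaw_exponent(k, kmin=1)
    assert 2.2 < alpha < 2.8


def test_compute_descriptors_full_set(wetland_table):
    from trophonet.anm_core import BuildParams, build_network

    net = build_network(wetland_table, BuildParams(seed=21))
    ds = compute_descriptors(net, wetland_table, max_chains=5000, max_loops=500)
    assert ds["N"] == wetland_table.n_species
    assert 0 <= ds["CON"] <= 1
    assert 0 <= ds["NEST"] <= 1
    assert ds["TOP"] + ds["BAS"] + ds["INT"] == pytest.approx(1.0)
    for name in ("DEG", "GEN", "VUL"):
        assert ds[name].sum() == pytest.approx(1.0)
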