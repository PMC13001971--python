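import math

import numpy as np
import pytest

from trophonet.anm_core import (
    BuildParams,
    NicheParams,
    allometric_criterion,
    build_ensemble,
    build_network,
    diet_criterion,
    producer_link,
    pure_anm_network,
    replicate_count,
    sample_niche,
    trophic_positions,
)
from trophonet.species_table import SpeciesTable

from conftest import record


class TestTrophicPositions:
    def test_minmax_of_logs(self):
        table = SpeciesTable(
            "s",
            [
                record("a", mass=1.0, diet=("omnivore",)),
                record("b", mass=10.0, diet=("omnivore",)),
                record("c", mass=100.0, diet=("omnivore",)),
            ],
        )
        assert trophic_positions(table) == pytest.approx([0.0, 0.5, 1.0])

    def test_degenerate_equal_masses(self):
        table = SpeciesTable(
            "s", [record(f"x{i}", mass=50.0, diet=("omnivore",)) for i in range(3)]
        )
        assert trophic_positions(table) == pytest.approx([0.5, 0.5, 0.5])

    def test_producers_at_zero(self, toy_table):
        n = trophic_positions(toy_table)
        assert n[0] == 0.0  # the reed, despite its 50 g
        assert n[3] == 1.0  # heaviest consumer

    def test_missing_consumer_mass_names_taxon(self):
        table = SpeciesTable("s", [record("plant", producer=True), record("ghost", diet=("omnivore",))])
        with pytest.raises(ValueError, match="ghost"):
            trophic_positions(table)


class TestSampleNiche:
    def test_classic_mean_range(self, rng):
        # x ~ Beta(1, 1/(2C) - 1) has mean 2C, so E[r | n] = 2C * n
        C, n_i = 0.12, 0.8
        rs = np.array([sample_niche(n_i, C, "classic", rng)[1] for _ in range(20000)])
        assert rs.mean() == pytest.approx(2 * C * n_i, rel=0.03)
        assert (rs <= n_i + 1e-12).all()

    def test_literal_mean_range(self, rng):
        # untruncated Beta(1, 2C) mean is 1 / (1 + 2C); at n = 0.5 the cap
        # sits at the support edge, so the mean is unaffected
        C = 0.12
        rs = np.array([sample_niche(0.5, C, "literal", rng)[1] for _ in range(20000)])
        assert rs.mean() == pytest.approx(1 / (1 + 2 * C), rel=0.03)

    def test_literal_truncation(self, rng):
        rs = np.array([sample_niche(0.1, 0.12, "literal", rng)[1] for _ in range(2000)])
        assert (rs <= 0.2 + 1e-12).all()

    def test_zero_position_forces_zero(self, rng):
        assert sample_niche(0.0, 0.12, "classic", rng) == (0.0, 0.0)

    def test_optimum_between_half_range_and_position(self, rng):
        for _ in range(500):
            n_i = rng.uniform(0.01, 1)
            c, r = sample_niche(n_i, 0.2, "classic", rng)
            assert r / 2 - 1e-12 <= c <= n_i + 1e-12

    @pytest.mark.parametrize("C", [0.0, 0.5, 0.7, -0.1])
    def test_connectivity_domain(self, C, rng):
        with pytest.raises(ValueError):
            sample_niche(0.5, C, "classic", rng)


class TestAllometricCriterion:
    @pytest.mark.parametrize(
        "n_j,c,r,expected",
        [
            (0.5, 0.5, 0.2, True),   # interior
            (0.9, 0.3, 0.2, False),  # exterior
            (0.4, 0.3, 0.2, True),   # upper boundary, closed
            (0.2, 0.3, 0.2, True),   # lower boundary, closed
        ],
    )
    def test_closed_interval(self, n_j, c, r, expected):
        assert allometric_criterion(n_j, c, r) is expected


class TestDietCriterion:
    def test_insectivore_eats_insects(self):
        consumer = record("bat", mass=20.0, diet=("insectivore",))
        bug = record("bug", mass=0.5, diet=("herbivore",), **{"class": "Insecta"})
        assert diet_criterion(consumer, bug)

    def test_strict_herbivore_rejects_animals(self):
        consumer = record("vole", mass=30.0, diet=("herbivore",))
        bug = record("bug", mass=0.5, diet=("herbivore",), **{"class": "Insecta"})
        assert not diet_criterion(consumer, bug)

    def test_omnivore_wildcard(self):
        consumer = record("boar", mass=8e4, diet=("omnivore",))
        for target in (
            record("bug", mass=0.5, diet=("herbivore",), **{"class": "Insecta"}),
            record("carp", mass=2e3, diet=("omnivore",), habitat=("aquatic",), **{"class": "Actinopterygii"}),
            record("fern", producer=True),
        ):
            assert diet_criterion(consumer, target)

    def test_piscivore_needs_fish(self):
        heron = record("heron", mass=1500.0, diet=("piscivore",))
        carp = record("carp", mass=2e3, habitat=("aquatic",), **{"class": "Actinopterygii"})
        vole = record("vole", mass=30.0, diet=("herbivore",))
        assert diet_criterion(heron, carp)
        assert not diet_criterion(heron, vole)


class TestProducerLink:
    def test_degenerate_probabilities(self, rng):
        plant = record("plant", producer=True)
        herb = record("vole", mass=30.0, diet=("herbivore",))

        class Lo:
            def uniform(self):
                return 0.999

        class Hi:
            def uniform(self):
                return 0.0

        assert not producer_link(plant, herb, 0.001, Lo())
        assert producer_link(plant, herb, 0.499, Hi())

    def test_carnivore_gate(self, rng):
        plant = record("plant", producer=True)
        fox = record("fox", mass=5e3, diet=("carnivore",))
        assert not any(producer_link(plant, fox, 0.49, rng) for _ in range(200))

    def test_non_producer_rejected(self, rng):
        vole = record("vole", mass=30.0, diet=("herbivore",))
        with pytest.raises(ValueError):
            producer_link(vole, vole, 0.12, rng)


class TestBuildNetwork:
    def test_toy_web_matches_hand_rules(self, toy_table):
        # frozen niche: shrew targets the grasshopper, fox targets the shrew
        n = trophic_positions(toy_table)  # [0, 0, 0.325, 1] (reed, hopper, shrew, fox)
        niche = NicheParams(
            n=n, c=np.array([0.0, 0.0, 0.1, 0.5]), r=np.array([0.0, 0.0, 0.3, 0.4])
        )
        draws = np.full((4, 4), 0.99)
        draws[1, 0] = 0.0  # grasshopper grazes the reed
        params = BuildParams(relaxation=False)
        net = build_network(toy_table, params, niche=niche, producer_draws=draws)
        expected = np.zeros((4, 4), dtype=int)
        expected[1, 0] = 1  # hopper -> reed (grazing draw)
        expected[2, 1] = 1  # shrew eats the insect at n=0 (0 in [-.05, .25])
        expected[3, 2] = 1  # fox eats the shrew at n=0.325 (in [.3, .7])
        assert np.array_equal(net.matrix, expected)

    def test_producers_only_zero_links(self):
        table = SpeciesTable("p", [record(f"p{i}", mass=1.0, producer=True) for i in range(3)])
        with pytest.warns(UserWarning, match="producers only"):
            net = build_network(table, BuildParams(seed=0))
        assert net.n_links == 0

    def test_seed_determinism(self, wetland_table):
        a = build_network(wetland_table, BuildParams(seed=11))
        b = build_network(wetland_table, BuildParams(seed=11))
        assert np.array_equal(a.matrix, b.matrix)

    def test_unenriched_table_lists_deficient_taxa(self):
        table = SpeciesTable(
            "s", [record("plant", producer=True), record("ghost", diet=("omnivore",))]
        )
        with pytest.raises(ValueError, match="ghost"):
            build_network(table, BuildParams(seed=0))

    def test_relaxation_guarantee(self, wetland_table):
        net = build_network(wetland_table, BuildParams(seed=3))
        off = net.matrix.copy()
        np.fill_diagonal(off, 0)
        for i, rec in enumerate(wetland_table.records):
            if rec.is_producer:
                assert off[:, i].sum() >= 1, f"uneaten producer {rec.taxon_id}"
            else:
                assert off[i].sum() >= 1, f"starving consumer {rec.taxon_id}"

    def test_no_self_links_by_default(self, wetland_table):
        net = build_network(wetland_table, BuildParams(seed=5))
        assert np.diag(net.matrix).sum() == 0


class TestReplicateCount:
    @pytest.mark.parametrize("N,expected", [(10, 100), (100, 50), (1000, 33)])
    def test_formula(self, N, expected):
        assert replicate_count(N, 100) == expected

    def test_floor_of_three(self):
        assert replicate_count(10**40, 100) == 3

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            replicate_count(1)


class TestEnsemble:
    def test_count_and_shared_index(self, wetland_table):
        ens = build_ensemble(wetland_table, BuildParams(seed=2), n_replicates=5)
        assert len(ens) == 5
        assert all(net.index == ens.index for net in ens)

    def test_replicates_differ(self, wetland_table):
        ens = build_ensemble(wetland_table, BuildParams(seed=2), n_replicates=10)
        distinct = {net.matrix.tobytes() for net in ens}
        assert len(distinct) >= 2

    def test_master_seed_reproducibility(self, wetland_table):
        e1 = build_ensemble(wetland_table, BuildParams(seed=9), n_replicates=4)
        e2 = build_ensemble(wetland_table, BuildParams(seed=9), n_replicates=4)
        for a, b in zip(e1, e2):
            assert np.array_equal(a.matrix, b.matrix)


class TestPureANM:
    def test_realized_connectivity(self):
        rng = np.random.default_rng(77)
        cons = np.array([pure_anm_network(100, 0.12, rng).connectance for _ in range(200)])
        se = cons.std(ddof=1) / math.sqrt(len(cons))
        assert abs(cons.mean() - 0.12) < 3 * se

    def test_low_connectivity_limit(self):
        rng = np.random.default_rng(1)
        net = pure_anm_network(100, 0.001, rng)
        assert net.connectance < 0.01

    def test_seed_determinism(self):
        a = pure_anm_network(50, 0.12, np.random.default_rng(5))
        b = pure_anm_network(50, 0.12, np.random.default_rng(5))
        assert np.array_equal(a.matrix, b.matrix)

    def test_monotone_in_connectivity(self):
        # raising C never lowers the expected link count
        means = []
        for C in (0.05, 0.12, 0.25):
            rng = np.random.default_rng(4)
            means.append(np.mean([pure_anm_network(60, C, rng).n_links for _ in range(50)]))
        assert means[0] < means[1] < means[2]


def test_build_params_validation():
    with pytest.raises(ValueError):
        BuildParams(C=0.6)
    with pytest.raises(ValueError):
        BuildParams(K=0)
    with pytest.raises(ValueError):
        BuildParams(niche_mode="mystic")
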