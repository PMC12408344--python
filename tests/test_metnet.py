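"""Network expansion, cooperation added value, minimal communities."""

import numpy as np
import pytest

from fermentome.metnet import (
    OrganismNetwork,
    Reaction,
    SeedSet,
    added_value,
    community_scope,
    coverage_stats,
    individual_scope,
    minimal_communities,
    networks_from_json,
    networks_to_json,
)
from oracles import minimal_communities_powerset, rxn_triples, scope_naive


def rxn(rid, subs, prods, rev=False):
    return Reaction(id=rid, substrates=frozenset(subs),
                    products=frozenset(prods), reversible=rev)


def org(name, *reactions):
    return OrganismNetwork(organism=name, reactions=reactions)


SEED_A = SeedSet(frozenset({"A"}))


def random_network(rng, name, metabolites, n_rxns):
    rxns = []
    for i in range(n_rxns):
        ns, np_ = rng.integers(1, 4), rng.integers(1, 4)
        subs = rng.choice(metabolites, size=ns, replace=False)
        prods = rng.choice(metabolites, size=np_, replace=False)
        subs, prods = frozenset(subs), frozenset(prods) - frozenset(subs)
        if not prods:
            continue
        rxns.append(rxn(f"{name}_r{i}", subs, prods, rev=bool(rng.random() < 0.3)))
    return org(name, *rxns)


class TestScopes:
    def test_no_reactions_reaches_only_seeds(self):
        assert individual_scope(org("o"), SEED_A).reachable == {"A"}

    def test_chain_closure(self):
        o = org("o", rxn("1", {"A"}, {"B"}), rxn("2", {"B"}, {"C"}))
        s = individual_scope(o, SEED_A)
        assert s.reachable == {"A", "B", "C"}
        assert s.produced == {"B", "C"}

    def test_reversible_fires_backwards(self):
        o = org("o", rxn("1", {"B"}, {"A"}, rev=True))
        assert individual_scope(o, SEED_A).reachable == {"A", "B"}

    def test_cross_feeding_chain(self):
        o1, o2 = org("o1", rxn("1", {"A"}, {"B"})), org("o2", rxn("2", {"B"}, {"C"}))
        assert community_scope([o1, o2], SEED_A).reachable == {"A", "B", "C"}

    def test_single_member_community_equals_individual(self):
        o = org("o", rxn("1", {"A"}, {"B"}))
        assert community_scope([o], SEED_A).reachable == individual_scope(o, SEED_A).reachable

    def test_empty_community_reaches_seeds(self):
        assert community_scope([], SEED_A).reachable == {"A"}

    def test_matches_naive_oracle_on_random_networks(self, rng):
        mets = np.array([f"m{i}" for i in range(25)] + ["A"])
        for _ in range(200):
            nets = [random_network(rng, f"o{k}", mets, int(rng.integers(1, 15)))
                    for k in range(3)]
            for n in nets:
                got = individual_scope(n, SEED_A).reachable
                assert got == scope_naive(rxn_triples(n), {"A"})
            comm = community_scope(nets, SEED_A).reachable
            all_rxns = [tr for n in nets for tr in rxn_triples(n)]
            assert comm == scope_naive(all_rxns, {"A"})
            # community scope contains every individual scope
            for n in nets:
                assert individual_scope(n, SEED_A).reachable <= comm

    def test_order_independence_and_monotonicity(self, rng):
        mets = np.array([f"m{i}" for i in range(20)] + ["A"])
        for _ in range(50):
            n = random_network(rng, "o", mets, 12)
            base = individual_scope(n, SEED_A).reachable
            shuffled = list(n.reactions)
            rng.shuffle(shuffled)
            assert individual_scope(org("o", *shuffled), SEED_A).reachable == base
            # enlarging seeds never shrinks the scope
            bigger = SeedSet(frozenset({"A", "m0"}))
            assert base <= individual_scope(n, bigger).reachable
            # expansion from the returned scope is idempotent
            assert individual_scope(n, SeedSet(base)).reachable == base


class TestAddedValue:
    def test_cooperative_chain_product(self):
        o1, o2 = org("o1", rxn("1", {"A"}, {"B"})), org("o2", rxn("2", {"B"}, {"C"}))
        assert added_value([o1, o2], SEED_A) == {"C"}

    def test_single_organism_has_no_added_value(self):
        o = org("o", rxn("1", {"A"}, {"B"}))
        assert added_value([o], SEED_A) == frozenset()

    def test_decomposition_identity(self, rng):
        # community scope = union of individual scopes ⊎ added value
        mets = np.array([f"m{i}" for i in range(20)] + ["A"])
        for _ in range(100):
            nets = [random_network(rng, f"o{k}", mets, int(rng.integers(2, 10)))
                    for k in range(3)]
            union_ind = frozenset().union(
                *(individual_scope(n, SEED_A).reachable for n in nets))
            av = added_value(nets, SEED_A)
            comm = community_scope(nets, SEED_A).reachable
            assert union_ind | av == comm
            assert union_ind & av == frozenset()
            for n in nets:
                assert av.isdisjoint(individual_scope(n, SEED_A).reachable)


class TestMinimalCommunities:
    def chain_pool(self):
        return [
            org("o1", rxn("1", {"A"}, {"B"})),
            org("o2", rxn("2", {"B"}, {"C"})),
        ]

    def test_chain_both_essential(self):
        red = minimal_communities(self.chain_pool(), SEED_A, targets={"C"})
        assert red.min_size == 2
        assert red.minimal_communities == (frozenset({"o1", "o2"}),)
        assert red.essential_species == {"o1", "o2"}
        assert red.alternative_species == frozenset()

    def test_targets_within_seeds_give_empty_community(self):
        red = minimal_communities(self.chain_pool(), SEED_A, targets={"A"})
        assert red.min_size == 0
        assert red.minimal_communities == (frozenset(),)

    def test_infeasible_targets_reported(self):
        with pytest.raises(ValueError, match="unreachable.*Z"):
            minimal_communities(self.chain_pool(), SEED_A, targets={"Z"})

    def test_redundant_organisms_are_alternatives(self):
        pool = self.chain_pool() + [org("o3", rxn("3", {"B"}, {"C"}))]
        red = minimal_communities(pool, SEED_A, targets={"C"})
        assert red.min_size == 2
        assert set(red.minimal_communities) == {
            frozenset({"o1", "o2"}), frozenset({"o1", "o3"})}
        assert red.essential_species == {"o1"}
        assert red.alternative_species == {"o2", "o3"}

    def test_matches_powerset_oracle(self, rng):
        mets = np.array([f"m{i}" for i in range(12)] + ["A"])
        checked = 0
        for _ in range(30):
            nets = [random_network(rng, f"o{k}", mets, int(rng.integers(2, 6)))
                    for k in range(6)]
            comm = community_scope(nets, SEED_A)
            produced = sorted(comm.produced)
            if not produced:
                continue
            targets = set(rng.choice(produced, size=min(3, len(produced)), replace=False))
            red = minimal_communities(nets, SEED_A, targets=targets)
            want_size, want_sets = minimal_communities_powerset(nets, {"A"}, targets)
            assert red.min_size == want_size
            assert set(red.minimal_communities) == want_sets
            # every solution is minimal under single-member deletion
            for com in red.minimal_communities:
                for drop in com:
                    rest = [n for n in nets if n.organism in com - {drop}]
                    assert not targets <= community_scope(rest, SEED_A).reachable
            checked += 1
        assert checked >= 10


class TestCoverageStats:
    def test_identical_sets(self):
        s = {"x", "y"}
        c = coverage_stats(s, set(s))
        assert c["pct_shared_of_union"] == 100.0
        assert c["pct_shared_of_reference"] == 100.0

    def test_disjoint_sets(self):
        c = coverage_stats({"x"}, {"y"})
        assert c["pct_shared_of_union"] == 0.0
        assert c["n_reference_only"] == 1 and c["n_candidate_only"] == 1

    def test_both_empty_warns(self):
        with pytest.warns(UserWarning):
            c = coverage_stats(set(), set())
        assert c["pct_shared_of_union"] == 0.0

    def test_random_pairs_match_set_arithmetic(self, rng):
        universe = [f"m{i}" for i in range(30)]
        for _ in range(50):
            a = set(rng.choice(universe, size=rng.integers(1, 20), replace=False))
            b = set(rng.choice(universe, size=rng.integers(1, 20), replace=False))
            c = coverage_stats(a, b)
            assert c["n_shared"] == len(a & b)
            assert c["pct_shared_of_union"] == pytest.approx(100 * len(a & b) / len(a | b))
            assert c["pct_shared_of_reference"] == pytest.approx(100 * len(a & b) / len(a))


def test_json_round_trip(tmp_path):
    nets = [
        org("o1", rxn("1", {"A"}, {"B"}), rxn("2", {"B", "C"}, {"D"}, rev=True)),
        org("o2", rxn("1", {"A"}, {"C"})),
    ]
    path = tmp_path / "nets.json"
    networks_to_json(nets, path)
    back = networks_from_json(path)
    assert [n.organism for n in back] == ["o1", "o2"]
    assert back[0].reactions[1].reversible
    assert back[0].reactions[1].substrates == {"B", "C"}


def test_reaction_validation():
    with pytest.raises(ValueError, match="non-empty"):
        Reaction(id="bad", substrates=frozenset(), products=frozenset({"A"}))
    with pytest.raises(ValueError, match="duplicate"):
        OrganismNetwork("o", (rxn("r", {"A"}, {"B"}), rxn("r", {"B"}, {"C"})))
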