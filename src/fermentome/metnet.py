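"""Seed-based metabolic network expansion and minimal community design.

A genome-scale metabolic network is treated as a set of reactions over
metabolite identifiers, without stoichiometry or flux constraints.  The
*scope* of an organism given a seed set (here: cocoa-pulp components) is
the fixpoint of iteratively firing every reaction whose substrates are
all reachable; reversible reactions may also fire backwards.  A
community's scope is the expansion over the union of all member
reactions, i.e. with unrestricted metabolite exchange.  The *added
value of cooperation* is what the community reaches beyond every member
alone — the gain from cross-feeding.

Given a target metabolite set (by default everything the full community
can produce), :func:`minimal_communities` enumerates all smallest
subsets of organisms whose community scope covers the targets.  Members
of any such subset are *key species*; members of all of them are
*essential*.  This is the procedure that condenses a fermentation
microbiome into a defined starter community with equivalent metabolic
capabilities.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Reaction",
    "OrganismNetwork",
    "SeedSet",
    "Scope",
    "CommunityReduction",
    "SolveConfig",
    "COCOA_PULP_SEEDS",
    "individual_scope",
    "community_scope",
    "added_value",
    "minimal_communities",
    "coverage_stats",
    "networks_to_json",
    "networks_from_json",
    "read_sbml",
]

#: Cocoa-pulp components used to seed the expansion: the sugars, acids,
#: polysaccharides and salts of artificial cocoa pulp, with yeast
#: extract/peptone represented by amino-acid proxies.
COCOA_PULP_SEEDS = (
    "sucrose",
    "glucose",
    "fructose",
    "citric_acid",
    "pectin",
    "carboxymethyl_cellulose_high_viscosity",
    "carboxymethyl_cellulose_low_viscosity",
    "amino_acids_yeast_extract",
    "amino_acids_peptone",
    "calcium_lactate",
    "tween_80",
    "magnesium_sulfate",
    "manganese_sulfate",
)


@dataclass(frozen=True)
class Reaction:
    id: str
    substrates: frozenset
    products: frozenset
    reversible: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "substrates", frozenset(self.substrates))
        object.__setattr__(self, "products", frozenset(self.products))
        if not self.substrates or not self.products:
            raise ValueError(f"reaction {self.id!r}: substrates and products must be non-empty")


@dataclass(frozen=True)
class OrganismNetwork:
    organism: str
    reactions: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "reactions", tuple(self.reactions))
        ids = [r.id for r in self.reactions]
        if len(ids) != len(set(ids)):
            raise ValueError(f"organism {self.organism!r}: duplicate reaction ids")


@dataclass(frozen=True)
class SeedSet:
    metabolites: frozenset
    label: str = "seeds"

    def __post_init__(self) -> None:
        object.__setattr__(self, "metabolites", frozenset(self.metabolites))
        if not self.metabolites:
            raise ValueError("seed set must be non-empty")


@dataclass(frozen=True)
class Scope:
    owner: str
    reachable: frozenset
    seeds: frozenset

    @property
    def produced(self) -> frozenset:
        return self.reachable - self.seeds


@dataclass(frozen=True)
class SolveConfig:
    exhaustive_max_organisms: int = 20
    greedy_restarts: int = 100
    seed: int = 0


@dataclass(frozen=True)
class CommunityReduction:
    targets: frozenset
    min_size: int
    minimal_communities: tuple  # of frozensets of organism ids
    exhaustive: bool

    @property
    def key_species(self) -> frozenset:
        return frozenset().union(*self.minimal_communities) if self.minimal_communities else frozenset()

    @property
    def essential_species(self) -> frozenset:
        if not self.minimal_communities:
            return frozenset()
        out = set(self.minimal_communities[0])
        for com in self.minimal_communities[1:]:
            out &= com
        return frozenset(out)

    @property
    def alternative_species(self) -> frozenset:
        return self.key_species - self.essential_species


def _expand(reactions, seeds: frozenset) -> frozenset:
    """Fixpoint expansion: fire reactions until no new metabolite appears.

    Order-independent: the loop rescans all reactions after every
    change, so the result is the least fixpoint regardless of input
    ordering.
    """
    reachable = set(seeds)
    changed = True
    while changed:
        changed = False
        for rxn in reactions:
            if rxn.substrates <= reachable and not rxn.products <= reachable:
                reachable |= rxn.products
                changed = True
            if rxn.reversible and rxn.products <= reachable and not rxn.substrates <= reachable:
                reachable |= rxn.substrates
                changed = True
    return frozenset(reachable)


def individual_scope(network: OrganismNetwork, seeds: SeedSet) -> Scope:
    """Metabolites one organism can reach alone from the seeds."""
    return Scope(
        owner=network.organism,
        reachable=_expand(network.reactions, seeds.metabolites),
        seeds=seeds.metabolites,
    )


def community_scope(networks, seeds: SeedSet) -> Scope:
    """Metabolites a community reaches with unrestricted exchange.

    Expansion runs over the union of all member reactions; the result is
    a superset of every member's individual scope.  An empty community
    reaches exactly the seeds.
    """
    all_rxns = [r for net in networks for r in net.reactions]
    return Scope(
        owner="community",
        reachable=_expand(all_rxns, seeds.metabolites),
        seeds=seeds.metabolites,
    )


def added_value(networks, seeds: SeedSet) -> frozenset:
    """Cooperation gain: community scope minus the union of individual scopes."""
    networks = list(networks)
    union_individual = frozenset().union(
        *(individual_scope(n, seeds).reachable for n in networks)
    ) if networks else seeds.metabolites
    return community_scope(networks, seeds).reachable - union_individual


def default_targets(networks, seeds: SeedSet) -> frozenset:
    """Everything the full community can make: union of individual
    produced sets plus the added value of cooperation."""
    networks = list(networks)
    comm = community_scope(networks, seeds)
    return comm.produced


def minimal_communities(
    networks,
    seeds: SeedSet,
    targets=None,
    solve_config: SolveConfig | None = None,
) -> CommunityReduction:
    """Enumerate all smallest sub-communities whose scope covers the targets.

    ``targets=None`` uses everything the full community can produce
    (individual capabilities plus the added value of cooperation), so
    "equivalent metabolic capabilities" means covering the full
    community's entire producible set.  Pass ``added_value(...)`` to
    target the cooperation gain only.

    Exhaustive enumeration (all subsets by increasing size, stopping at
    the first feasible size) is used for pools up to
    ``solve_config.exhaustive_max_organisms``; larger pools fall back to
    a seeded greedy cover with local pruning and restarts, flagged
    ``exhaustive=False``.
    """
    cfg = solve_config or SolveConfig()
    networks = list(networks)
    by_id = {n.organism: n for n in networks}
    if len(by_id) != len(networks):
        raise ValueError("duplicate organism ids in pool")

    full = community_scope(networks, seeds)
    targets = frozenset(default_targets(networks, seeds) if targets is None else targets)
    unreachable = targets - full.reachable
    if unreachable:
        raise ValueError(
            "targets unreachable even by the full community: "
            + ", ".join(sorted(unreachable))
        )

    if targets <= seeds.metabolites:
        return CommunityReduction(
            targets=targets, min_size=0,
            minimal_communities=(frozenset(),), exhaustive=True,
        )

    ids = sorted(by_id)

    def covers(subset) -> bool:
        return targets <= community_scope([by_id[i] for i in subset], seeds).reachable

    if len(ids) <= cfg.exhaustive_max_organisms:
        for m in range(1, len(ids) + 1):
            hits = [frozenset(c) for c in itertools.combinations(ids, m) if covers(c)]
            if hits:
                return CommunityReduction(
                    targets=targets, min_size=m,
                    minimal_communities=tuple(hits), exhaustive=True,
                )
        raise AssertionError("full community covers targets but no subset found")

    # large pools: greedy set cover with deletion pruning, random restarts
    rng = np.random.default_rng(cfg.seed)
    best: set | None = None
    found: set = set()
    for _ in range(cfg.greedy_restarts):
        order = list(ids)
        rng.shuffle(order)
        chosen: list[str] = []
        reach = set(seeds.metabolites)
        remaining = set(order)
        while not targets <= reach:
            gains = []
            for org in sorted(remaining):
                trial = community_scope([by_id[i] for i in chosen + [org]], seeds).reachable
                gains.append((len(trial & targets), org, trial))
            gains.sort(key=lambda g: (-g[0], g[1]))
            _, org, reach = gains[0]
            chosen.append(org)
            remaining.discard(org)
        # prune: drop members that are not needed
        pruned = list(chosen)
        for org in list(pruned):
            trial = [o for o in pruned if o != org]
            if trial and covers(trial):
                pruned = trial
        sol = frozenset(pruned)
        if best is None or len(sol) < len(best):
            best, found = set(sol), {sol}
        elif len(sol) == len(best):
            found.add(sol)
    assert best is not None
    return CommunityReduction(
        targets=targets, min_size=len(best),
        minimal_communities=tuple(sorted(found, key=sorted)), exhaustive=False,
    )


def coverage_stats(reference, candidate) -> dict:
    """Overlap record between two metabolite (or label) sets.

    Accepts :class:`Scope` objects or plain sets; percentages are
    reported both relative to the union and to the reference.
    """
    a = frozenset(reference.reachable if isinstance(reference, Scope) else reference)
    b = frozenset(candidate.reachable if isinstance(candidate, Scope) else candidate)
    inter, only_a, only_b = a & b, a - b, b - a
    union = a | b
    if not union:
        warnings.warn("both sets empty; overlap percentages defined as 0")
        pct_union = pct_ref = 0.0
    else:
        pct_union = 100.0 * len(inter) / len(union)
        pct_ref = 100.0 * len(inter) / len(a) if a else 0.0
    return {
        "n_shared": len(inter),
        "n_reference_only": len(only_a),
        "n_candidate_only": len(only_b),
        "pct_shared_of_union": pct_union,
        "pct_shared_of_reference": pct_ref,
    }


# ---------------------------------------------------------------------------
# serialization

def networks_to_json(networks, path=None) -> str:
    payload = {
        "organisms": [
            {
                "id": n.organism,
                "reactions": [
                    {
                        "id": r.id,
                        "substrates": sorted(r.substrates),
                        "products": sorted(r.products),
                        "reversible": r.reversible,
                    }
                    for r in n.reactions
                ],
            }
            for n in networks
        ]
    }
    text = json.dumps(payload, indent=1, sort_keys=True)
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def networks_from_json(source) -> list:
    """Load organism networks from the native JSON format (text or path)."""
    if isinstance(source, str) and source.lstrip().startswith("{"):
        payload = json.loads(source)
    else:
        with open(source) as fh:
            payload = json.load(fh)
    out = []
    for org in payload["organisms"]:
        rxns = [
            Reaction(
                id=r["id"],
                substrates=frozenset(r["substrates"]),
                products=frozenset(r["products"]),
                reversible=bool(r.get("reversible", False)),
            )
            for r in org["reactions"]
        ]
        out.append(OrganismNetwork(organism=org["id"], reactions=rxns))
    return out


def read_sbml(path, organism=None) -> OrganismNetwork:
    """Optional SBML reader (requires cobra); maps reactions to this model.

    Reactant/product species ids become substrate/product metabolite
    ids; reaction reversibility follows the SBML bounds.
    """
    try:
        import cobra
    except ImportError as exc:  # pragma: no cover
        raise ImportError("SBML support requires the 'cobra' package") from exc
    model = cobra.io.read_sbml_model(str(path))
    rxns = []
    for r in model.reactions:
        subs = frozenset(m.id for m, c in r.metabolites.items() if c < 0)
        prods = frozenset(m.id for m, c in r.metabolites.items() if c > 0)
        if not subs or not prods:  # exchange/boundary reactions have one side
            continue
        rxns.append(Reaction(id=r.id, substrates=subs, products=prods,
                             reversible=r.reversibility))
    return OrganismNetwork(organism=organism or model.id or "sbml_model", reactions=rxns)
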