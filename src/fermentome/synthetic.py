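"""Synthetic fermentation studies with known ground truth.

Generates every input the pipeline consumes — temperature/pH kinetic
series, taxon relative-abundance trajectories, sensory score tables and
organism metabolic networks — from configurable ground truth, so each
downstream stage has a recovery test: curve fitting can be checked
against the true 5-parameter values, feature-importance ranking against
the planted informative features, and minimal-community enumeration
against a planted cross-feeding chain.

Noise is additive Gaussian on the measurement scale (°C, pH units,
relative abundance).  All generators are deterministic given the
configuration seed; replicates draw from sub-streams derived from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .kinetics import KineticSeries, five_param_model
from .metnet import (
    OrganismNetwork,
    Reaction,
    SeedSet,
    minimal_communities,
)
from .trajectory import AbundanceTrajectory

__all__ = [
    "SimConfig",
    "GroundTruth",
    "NetworkSpec",
    "DEFAULT_CURVES",
    "DEFAULT_TAXA_SPEC",
    "DEFAULT_SENSORY_SPEC",
    "gen_fermentation",
    "gen_taxa_trajectories",
    "gen_sensory",
    "gen_marker_coefficients",
    "gen_networks",
]

# (variable, compartment) -> true 5-parameter curve (y0, yf, k, ti, nu).
# Plausible farm-fermentation ranges: bean-mass temperature rises from
# ambient ~25 °C to ~48 °C over a 168 h fermentation, testa/pulp pH
# rises from ~3.5 to ~4.6, cotyledon pH falls from ~6.5 to ~4.8.
DEFAULT_CURVES = {
    ("temperature", "top"): (25.0, 46.0, 0.08, 55.0, 1.2),
    ("temperature", "mid-box"): (25.0, 48.0, 0.09, 60.0, 1.0),
    ("pH", "testa_pulp"): (3.5, 4.6, 0.07, 70.0, 1.0),
    ("pH", "cotyledon"): (6.5, 4.8, 0.08, 50.0, 1.0),  # falling sigmoid
}

# (taxon, kingdom, shape, shape params).  Mirrors the succession seen in
# fermenting beans: early enterobacteria collapse, lactic then acetic
# bacteria bloom, yeasts rise; one flat background taxon per kingdom.
DEFAULT_TAXA_SPEC = (
    ("Erwiniaceae", "bacteria", "fall", {"amplitude": 0.8, "rate": 0.09, "midpoint": 30.0, "baseline": 0.02}),
    ("Lactobacillaceae", "bacteria", "rise-fall", {"amplitude": 0.9, "rate": 0.12, "midpoint": 40.0, "rate2": 0.10, "midpoint2": 110.0, "baseline": 0.02}),
    ("Acetobacteraceae", "bacteria", "rise", {"amplitude": 0.9, "rate": 0.10, "midpoint": 70.0, "baseline": 0.02}),
    ("other_bacteria", "bacteria", "flat", {"level": 0.05}),
    ("Nectriaceae", "fungi", "fall", {"amplitude": 0.6, "rate": 0.10, "midpoint": 25.0, "baseline": 0.02}),
    ("Torulaspora", "fungi", "rise-fall", {"amplitude": 0.8, "rate": 0.11, "midpoint": 35.0, "rate2": 0.09, "midpoint2": 100.0, "baseline": 0.02}),
    ("Saccharomyces", "fungi", "rise", {"amplitude": 0.9, "rate": 0.09, "midpoint": 55.0, "baseline": 0.02}),
    ("other_fungi", "fungi", "flat", {"level": 0.05}),
)

# (attribute, {feature: coefficient}, noise sd) on the 0-10 panel scale.
DEFAULT_SENSORY_SPEC = (
    ("cocoa", {}, 0.5),
    ("floral", {}, 0.5),
    ("caramel_panela", {}, 0.5),
)


@dataclass(frozen=True)
class NetworkSpec:
    n_organisms: int = 10
    n_metabolites: int = 30
    n_reactions_per_organism: int = 6
    planted_community_size: int = 3
    planted_target_size: int = 2
    n_seeds: int = 5

    def __post_init__(self) -> None:
        if self.planted_community_size > self.n_organisms:
            raise ValueError("planted_community_size must be <= n_organisms")
        if min(self.n_organisms, self.n_metabolites,
               self.n_reactions_per_organism, self.planted_community_size,
               self.planted_target_size, self.n_seeds) < 1:
            raise ValueError("network spec counts must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic fermentation experiment."""

    seed: int = 0
    n_timepoints: int = 15
    t_end: float = 168.0
    noise_sd: dict | float = field(
        default_factory=lambda: {"temperature": 0.5, "pH": 0.05}
    )
    taxa_noise_sd: float = 0.02
    n_replicates: int = 3
    curves: dict = field(default_factory=lambda: dict(DEFAULT_CURVES))
    taxa_spec: tuple = DEFAULT_TAXA_SPEC
    sensory_spec: tuple = DEFAULT_SENSORY_SPEC
    network_spec: NetworkSpec = field(default_factory=NetworkSpec)

    def __post_init__(self) -> None:
        if self.n_timepoints < 3:
            raise ValueError("n_timepoints must be >= 3")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.t_end <= 0:
            raise ValueError("t_end must be positive")
        sds = (self.noise_sd.values() if isinstance(self.noise_sd, dict)
               else [self.noise_sd])
        if any(s < 0 for s in sds):
            raise ValueError("noise_sd must be >= 0")
        if self.taxa_noise_sd < 0:
            raise ValueError("taxa_noise_sd must be >= 0")

    def sd_for(self, variable: str) -> float:
        if isinstance(self.noise_sd, dict):
            return float(self.noise_sd[variable])
        return float(self.noise_sd)


@dataclass
class GroundTruth:
    """What the generators planted, for downstream recovery tests."""

    true_curve_params: dict = field(default_factory=dict)
    informative_feature_ids: dict = field(default_factory=dict)
    planted_community: frozenset = frozenset()
    planted_targets: frozenset = frozenset()


def _rng(config: SimConfig, stream: int, *extra: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream, *extra])


def gen_fermentation(config: SimConfig) -> tuple[list, GroundTruth]:
    """Simulate temperature and pH kinetic series for every replicate.

    Values are the 5-parameter generalized logistic plus iid Gaussian
    noise with the per-variable standard deviation from the config.
    """
    times = np.linspace(0.0, config.t_end, config.n_timepoints)
    truth = GroundTruth()
    series: list[KineticSeries] = []
    for rep in range(config.n_replicates):
        rep_id = f"r{rep + 1}"
        for idx, ((variable, compartment), params) in enumerate(sorted(config.curves.items())):
            rng = _rng(config, 0, rep, idx)
            clean = five_param_model(times, *params)
            noisy = clean + rng.normal(0.0, config.sd_for(variable), size=times.size)
            series.append(
                KineticSeries(
                    times=times, values=noisy, variable=variable,
                    compartment=compartment, replicate=rep_id,
                )
            )
            truth.true_curve_params[(variable, compartment, rep_id)] = tuple(params)
    return series, truth


def _shape_curve(times: np.ndarray, shape: str, p: dict) -> np.ndarray:
    up = lambda rate, mid: 1.0 / (1.0 + np.exp(-rate * (times - mid)))
    base = p.get("baseline", 0.0)
    if shape == "rise":
        return base + p["amplitude"] * up(p["rate"], p["midpoint"])
    if shape == "fall":
        return base + p["amplitude"] * (1.0 - up(p["rate"], p["midpoint"]))
    if shape == "rise-fall":
        return base + p["amplitude"] * up(p["rate"], p["midpoint"]) * (
            1.0 - up(p["rate2"], p["midpoint2"])
        )
    if shape == "flat":
        return np.full_like(times, float(p["level"]))
    raise ValueError(f"unknown trajectory shape {shape!r}")


def gen_taxa_trajectories(config: SimConfig) -> list:
    """Simulate taxon relative-abundance trajectories per replicate.

    Raw shape curves (logistic up, down, or their product) get additive
    Gaussian noise, are clipped at 0, and are closed per time point so
    abundances across taxa sum to 1.
    """
    if not config.taxa_spec:
        raise ValueError("taxa_spec must be non-empty")
    times = np.linspace(0.0, config.t_end, config.n_timepoints)
    raw_all = np.array([
        _shape_curve(times, shape, params)
        for _, _, shape, params in config.taxa_spec
    ])
    if np.all(raw_all.sum(axis=0) == 0):
        raise ValueError("taxa_spec yields zero total abundance at every time point")

    out: list[AbundanceTrajectory] = []
    for rep in range(config.n_replicates):
        rng = _rng(config, 1, rep)
        noisy = raw_all + rng.normal(0.0, config.taxa_noise_sd, size=raw_all.shape)
        noisy = np.clip(noisy, 0.0, None)
        totals = noisy.sum(axis=0)
        if np.any(totals == 0):
            raise ValueError("zero total abundance after noise; raise baselines")
        closed = noisy / totals
        for (taxon, kingdom, _, _), abund in zip(config.taxa_spec, closed):
            out.append(
                AbundanceTrajectory(
                    taxon=taxon, kingdom=kingdom, times=times,
                    abundances=abund, replicate=f"r{rep + 1}",
                )
            )
    return out


def gen_sensory(
    features: pd.DataFrame, config: SimConfig, truth: GroundTruth | None = None
) -> pd.DataFrame:
    """Panel scores: clip(linear combination of features + noise, 0, 10).

    ``features`` must be normalized to [0, 1].  Each sensory_spec entry
    gives (attribute, coefficients, noise sd); coefficients are a dict
    over feature names or a vector aligned with the feature columns.
    Informative features (non-zero coefficient) are recorded in the
    ground truth.
    """
    X = features.to_numpy(dtype=float)
    if X.size and (X.min() < -1e-9 or X.max() > 1 + 1e-9):
        raise ValueError("features must be normalized to [0, 1] (use rescale01)")
    cols = list(features.columns)
    scores = {}
    truth = truth if truth is not None else GroundTruth()
    for i, (attr, coeffs, sd) in enumerate(config.sensory_spec):
        if isinstance(coeffs, dict):
            unknown = set(coeffs) - set(cols)
            if unknown:
                raise ValueError(f"{attr}: unknown feature(s) {sorted(unknown)}")
            vec = np.array([float(coeffs.get(c, 0.0)) for c in cols])
        else:
            vec = np.asarray(coeffs, dtype=float)
            if vec.size != len(cols):
                raise ValueError(
                    f"{attr}: coefficient vector length {vec.size} != "
                    f"{len(cols)} features"
                )
        rng = _rng(config, 2, i)
        raw = X @ vec + rng.normal(0.0, sd, size=X.shape[0])
        scores[attr] = np.clip(raw, 0.0, 10.0)
        truth.informative_feature_ids[attr] = tuple(
            c for c, v in zip(cols, vec) if v != 0
        )
    return pd.DataFrame(scores, index=features.index)


def gen_marker_coefficients(config: SimConfig) -> pd.DataFrame:
    """Community-dissimilarity coefficients for the marker filter.

    Taxa with a non-flat planted trajectory receive a coefficient above
    their kingdom's selection threshold (bacteria 10, fungi 5); flat
    background taxa fall below it.
    """
    rows = []
    for taxon, kingdom, shape, _ in config.taxa_spec:
        high = 12.0 if kingdom == "bacteria" else 6.0
        low = 1.0
        rows.append(
            {"taxon": taxon, "kingdom": kingdom,
             "coefficient": low if shape == "flat" else high}
        )
    return pd.DataFrame(rows)


def gen_networks(
    config: SimConfig, max_retries: int = 20
) -> tuple[list, SeedSet, GroundTruth]:
    """Random organism networks with a planted cross-feeding chain.

    A chain of single reactions is distributed over exactly
    ``planted_community_size`` distinct organisms: each link consumes
    the previous link's product (the first consumes a seed) and the last
    produces the planted target metabolites.  Background reactions never
    produce chain intermediates or targets, so the planted community is
    the unique minimal community for the targets; this is verified by
    enumeration before returning, with bounded retries.
    """
    spec = config.network_spec
    last_err = None
    for attempt in range(max_retries):
        rng = _rng(config, 3, attempt)
        try:
            nets, seeds, truth = _build_networks(spec, rng)
        except ValueError as err:  # degenerate draw; retry
            last_err = err
            continue
        red = minimal_communities(nets, seeds, targets=truth.planted_targets)
        if (red.min_size == spec.planted_community_size
                and truth.planted_community in red.minimal_communities):
            return nets, seeds, truth
        last_err = ValueError("planted community not recovered as minimal")
    raise RuntimeError(
        f"network construction failed after {max_retries} retries: {last_err}"
    )


def _build_networks(spec: NetworkSpec, rng: np.random.Generator):
    seeds = [f"seed_{i}" for i in range(spec.n_seeds)]
    background = [f"met_{i}" for i in range(spec.n_metabolites)]
    chain_size = spec.planted_community_size
    chain_mets = [f"chain_{i}" for i in range(chain_size - 1)]
    targets = [f"target_{i}" for i in range(spec.planted_target_size)]

    organisms = [f"org_{i}" for i in range(spec.n_organisms)]
    planted = sorted(rng.choice(spec.n_organisms, size=chain_size, replace=False))
    planted_ids = [organisms[i] for i in planted]

    substrate_pool = seeds + background  # products drawn from background only
    nets = []
    for oi, org in enumerate(organisms):
        rxns = []
        for ri in range(spec.n_reactions_per_organism):
            ns = int(rng.integers(1, 3))
            np_ = int(rng.integers(1, 3))
            subs = rng.choice(len(substrate_pool), size=ns, replace=False)
            prods = rng.choice(len(background), size=np_, replace=False)
            sub_set = frozenset(substrate_pool[i] for i in subs)
            prod_set = frozenset(background[i] for i in prods) - sub_set
            if not prod_set:
                continue
            rxns.append(
                Reaction(
                    id=f"{org}_rx{ri}", substrates=sub_set, products=prod_set,
                    reversible=bool(rng.random() < 0.2),
                )
            )
        if org in planted_ids:
            step = planted_ids.index(org)
            sub = seeds[0] if step == 0 else chain_mets[step - 1]
            prod = frozenset(targets) if step == chain_size - 1 else frozenset({chain_mets[step]})
            rxns.append(
                Reaction(id=f"{org}_chain", substrates=frozenset({sub}), products=prod)
            )
        if not rxns:
            raise ValueError(f"organism {org} drew no valid reactions")
        nets.append(OrganismNetwork(organism=org, reactions=rxns))

    truth = GroundTruth(
        planted_community=frozenset(planted_ids),
        planted_targets=frozenset(targets),
    )
    return nets, SeedSet(frozenset(seeds), label="synthetic pulp"), truth
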