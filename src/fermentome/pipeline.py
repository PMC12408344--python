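"""End-to-end orchestration of the two analysis chains.

``run_flavour_analysis`` executes simulate (or load) → invert → fit →
13 abiotic features → marker selection → 7 growth features → rescale →
correlation clustering → representatives → per-attribute random-forest
importance, writing TSV/JSON artifacts plus a run report whose manifest
records a content hash for every output.  ``run_community_design``
executes networks → scopes → added value → minimal communities →
coverage statistics.  Both are deterministic under a fixed seed:
re-running an identical configuration reproduces identical hashes.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .flavour import RFConfig, corr_cluster, importance_map, rescale01
from .io import (
    series_from_long,
    series_to_long,
    trajectories_from_long,
    trajectories_to_long,
    write_table,
)
from .kinetics import (
    FitConfig,
    extract_abiotic_features,
    fit_five_param,
    invert_series,
)
from .metnet import (
    SeedSet,
    SolveConfig,
    added_value,
    community_scope,
    coverage_stats,
    individual_scope,
    minimal_communities,
    networks_from_json,
    networks_to_json,
)
from .synthetic import (
    GroundTruth,
    SimConfig,
    gen_fermentation,
    gen_marker_coefficients,
    gen_networks,
    gen_sensory,
    gen_taxa_trajectories,
)
from .trajectory import SmoothConfig, extract_growth_features, select_markers

__all__ = [
    "RunConfig",
    "RunReport",
    "PipelineError",
    "run_flavour_analysis",
    "run_community_design",
    "run_all",
]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and the underlying error."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """One run: either a simulation config or paths to input tables."""

    seed: int = 0
    outdir: str = "fermentome_out"
    sim: SimConfig | None = None
    series_path: str | None = None
    trajectories_path: str | None = None
    sensory_path: str | None = None
    coefficients_path: str | None = None
    networks_path: str | None = None
    seeds_path: str | None = None
    n_clusters: int | None = None
    smooth_window: int = 3
    n_trees: int = 500
    targets_mode: str = "full"  # or "added_value"
    n_informative_per_attribute: int = 1

    def __post_init__(self) -> None:
        if self.sim is not None and self.series_path is not None:
            raise ValueError("provide either a SimConfig or input paths, not both")
        if self.targets_mode not in ("full", "added_value"):
            raise ValueError("targets_mode must be 'full' or 'added_value'")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        sim = payload.pop("sim", None)
        cfg = cls(**payload)
        if sim is not None:
            cfg.sim = SimConfig(**sim)
        return cfg

    def config_hash(self) -> str:
        def norm(o):
            if dataclasses.is_dataclass(o):
                o = dataclasses.asdict(o)
            if isinstance(o, dict):
                return sorted((str(k), norm(v)) for k, v in o.items())
            if isinstance(o, (frozenset, set)):
                return sorted(str(x) for x in o)
            if isinstance(o, (list, tuple)):
                return [norm(v) for v in o]
            return o

        payload = dataclasses.asdict(self)
        payload.pop("outdir")  # output location is run metadata, not configuration
        text = json.dumps(norm(payload), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    config_hash: str
    seed: int
    version: str = __version__
    stages: list = field(default_factory=list)
    warnings: list = field(default_factory=list)
    manifest: dict = field(default_factory=dict)

    def record(self, stage: str, **info) -> None:
        self.stages.append({"stage": stage, "status": "ok", **info})

    def fail(self, stage: str, error: Exception) -> None:
        self.stages.append({"stage": stage, "status": "failed", "error": str(error)})

    def add_artifact(self, path: Path) -> None:
        self.manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        payload = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "version": self.version,
            "stages": self.stages,
            "warnings": self.warnings,
            "manifest": self.manifest,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))


def _is_falling(series) -> bool:
    """Overall-decreasing series (e.g. cotyledon pH) get reflected before
    fitting so the same rising model applies."""
    slope = np.polyfit(series.times, series.values, 1)[0]
    return slope < 0


def _feature_name(series, feat: str) -> str:
    return f"{series.variable}_{series.compartment}:{feat}"


def _default_sensory_spec(config: RunConfig, feature_names, truth: GroundTruth):
    """Fill in sensory coefficients when the sim spec leaves them empty.

    Each attribute gets ``n_informative_per_attribute`` distinct planted
    features with coefficient 8 on the rescaled scale and the spec's
    noise sd; assignments are deterministic given the run seed.
    """
    assert config.sim is not None
    rng = np.random.default_rng([config.seed, 99])
    names = list(feature_names)
    spec = []
    for attr, coeffs, sd in config.sim.sensory_spec:
        if coeffs:
            spec.append((attr, coeffs, sd))
            continue
        picks = rng.choice(len(names), size=min(config.n_informative_per_attribute, len(names)), replace=False)
        spec.append((attr, {names[i]: 8.0 for i in picks}, sd))
    return tuple(spec)


def run_flavour_analysis(config: RunConfig) -> RunReport:
    """Simulate/load inputs and run the full flavour-linkage chain."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash(), seed=config.seed)
    truth = GroundTruth()

    stage = "inputs"
    try:
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            series, truth = gen_fermentation(sim)
            trajectories = gen_taxa_trajectories(sim)
            coefficients = gen_marker_coefficients(sim)
            sensory = None  # generated after features exist
        else:
            if config.series_path is None or config.trajectories_path is None:
                raise ValueError("series_path and trajectories_path are required")
            if config.sensory_path is None:
                raise ValueError("sensory table is required (sensory_path)")
            sim = None
            series = series_from_long(config.series_path)
            trajectories = trajectories_from_long(config.trajectories_path)
            sensory = pd.read_csv(config.sensory_path, sep="\t", index_col=0)
            coefficients = pd.read_csv(config.coefficients_path, sep="\t")
        series_to_long(series, out / "series.csv")
        trajectories_to_long(trajectories, out / "trajectories.tsv")
        report.record(stage, n_series=len(series), n_trajectories=len(trajectories))
    except Exception as err:
        report.fail(stage, err)
        report.write(out / "report.json")
        raise PipelineError(stage, err) from err

    stage = "kinetic_features"
    try:
        fit_cfg = FitConfig(seed=config.seed)
        rows: dict[str, dict[str, float]] = {}
        for s in series:
            s_fit = invert_series(s) if _is_falling(s) else s
            fit = fit_five_param(s_fit, fit_cfg)
            if not fit.converged:
                report.warnings.append(
                    f"fit did not converge: {s.variable}/{s.compartment}/{s.replicate}"
                )
                continue
            feats = extract_abiotic_features(fit, s_fit, fit_cfg)
            row = rows.setdefault(s.replicate, {})
            for name, value in feats.as_dict().items():
                row[_feature_name(s, name)] = value
        abiotic = pd.DataFrame(rows).T.sort_index()
        report.record(stage, n_rows=len(abiotic), n_features=abiotic.shape[1])
    except Exception as err:
        report.fail(stage, err)
        report.write(out / "report.json")
        raise PipelineError(stage, err) from err

    stage = "growth_features"
    try:
        markers = select_markers(coefficients)
        smooth = SmoothConfig(window=config.smooth_window)
        grows: dict[str, dict[str, float]] = {}
        for tr in trajectories:
            if tr.taxon not in markers.selected:
                continue
            feats = extract_growth_features(tr, smooth)
            row = grows.setdefault(tr.replicate, {})
            for name, value in feats.as_dict().items():
                row[f"{tr.taxon}:{name}"] = value
        biotic = pd.DataFrame(grows).T.sort_index()
        report.record(
            stage, n_markers=len(markers.selected), n_features=biotic.shape[1]
        )
    except Exception as err:
        report.fail(stage, err)
        report.write(out / "report.json")
        raise PipelineError(stage, err) from err

    stage = "feature_matrix"
    try:
        features = pd.concat([abiotic, biotic], axis=1).sort_index(axis=1)
        if features.isna().any().any():
            features = features.dropna()
        normalized = rescale01(features)
        write_table(features, out / "features.tsv")
        report.record(stage, shape=list(features.shape))
    except Exception as err:
        report.fail(stage, err)
        report.write(out / "report.json")
        raise PipelineError(stage, err) from err

    stage = "clustering"
    try:
        clusters = corr_cluster(normalized, k=config.n_clusters, raw_matrix=features)
        reps = list(clusters.representatives)
        report.record(stage, n_clusters=clusters.n_clusters, representatives=reps)
    except Exception as err:
        report.fail(stage, err)
        report.write(out / "report.json")
        raise PipelineError(stage, err) from err

    stage = "sensory"
    try:
        if sensory is None:
            assert sim is not None
            # planted effects act on representatives so the importance
            # stage can recover them
            spec = _default_sensory_spec(config, reps, truth)
            sim = dataclasses.replace(sim, sensory_spec=spec)
            sensory = gen_sensory(normalized, sim, truth)
        sensory = sensory.loc[normalized.index]
        write_table(sensory, out / "sensory.tsv")
        report.record(
            stage, attributes=list(sensory.columns),
            informative={k: list(v) for k, v in truth.informative_feature_ids.items()},
        )
    except Exception as err:
        report.fail(stage, err)
        report.write(out / "report.json")
        raise PipelineError(stage, err) from err

    stage = "importance"
    try:
        imap = importance_map(
            normalized[reps], sensory,
            RFConfig(n_trees=config.n_trees, seed=config.seed),
        )
        write_table(imap.table, out / "importance.tsv", index_label="attribute")
        row_order, col_order = imap.clustered_order()
        (out / "clusters.json").write_text(json.dumps(
            {
                "config_hash": config.config_hash(),
                "version": __version__,
                "assignment": clusters.assignment,
                "representatives": reps,
                "cv": clusters.cv,
                "importance_row_order": row_order,
                "importance_col_order": col_order,
                "oob_r2": {k: (None if np.isnan(v) else v) for k, v in imap.oob_r2.items()},
            },
            indent=1, sort_keys=True,
        ))
        report.record(stage, n_clusters=clusters.n_clusters, representatives=reps)
    except Exception as err:
        report.fail(stage, err)
        report.write(out / "report.json")
        raise PipelineError(stage, err) from err

    for name in ("series.csv", "trajectories.tsv", "features.tsv",
                 "sensory.tsv", "importance.tsv", "clusters.json"):
        report.add_artifact(out / name)
    report.write(out / "report.json")
    return report


def run_community_design(config: RunConfig) -> RunReport:
    """Networks → scopes → added value → minimal communities → coverage."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report = RunReport(config_hash=config.config_hash(), seed=config.seed)

    stage = "networks"
    try:
        if config.sim is not None:
            sim = dataclasses.replace(config.sim, seed=config.seed)
            nets, seeds, truth = gen_networks(sim)
        else:
            if config.networks_path is None:
                raise ValueError("networks_path is required")
            nets = networks_from_json(config.networks_path)
            if config.seeds_path is None:
                raise ValueError("seeds_path is required")
            seed_text = Path(config.seeds_path).read_text().split()
            if not seed_text:
                raise ValueError("seeds file is empty")
            seeds = SeedSet(frozenset(seed_text))
            truth = GroundTruth()
        networks_to_json(nets, out / "networks.json")
        report.record(stage, n_organisms=len(nets), n_seeds=len(seeds.metabolites))
    except Exception as err:
        report.fail(stage, err)
        report.write(out / "report.json")
        raise PipelineError(stage, err) from err

    stage = "reduction"
    try:
        scopes = {n.organism: individual_scope(n, seeds) for n in nets}
        comm = community_scope(nets, seeds)
        coop = added_value(nets, seeds)
        targets = coop if config.targets_mode == "added_value" else None
        red = minimal_communities(
            nets, seeds, targets=targets, solve_config=SolveConfig(seed=config.seed)
        )
        minimal = red.minimal_communities[0] if red.minimal_communities else frozenset()
        minimal_scope = community_scope(
            [n for n in nets if n.organism in minimal], seeds
        )
        coverage = coverage_stats(comm, minimal_scope)
        payload = {
            "config_hash": config.config_hash(),
            "version": __version__,
            "individual_scopes": {k: sorted(v.reachable) for k, v in scopes.items()},
            "community_scope": sorted(comm.reachable),
            "added_value": sorted(coop),
            "targets_mode": config.targets_mode,
            "targets": sorted(red.targets),
            "min_size": red.min_size,
            "minimal_communities": [sorted(c) for c in red.minimal_communities],
            "key_species": sorted(red.key_species),
            "essential_species": sorted(red.essential_species),
            "alternative_species": sorted(red.alternative_species),
            "exhaustive": red.exhaustive,
            "coverage_full_vs_minimal": coverage,
            "planted_community": sorted(truth.planted_community),
        }
        (out / "reduction.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
        report.record(
            stage, min_size=red.min_size,
            n_minimal=len(red.minimal_communities),
            n_added_value=len(coop),
        )
    except Exception as err:
        report.fail(stage, err)
        report.write(out / "report.json")
        raise PipelineError(stage, err) from err

    for name in ("networks.json", "reduction.json"):
        report.add_artifact(out / name)
    report.write(out / "report.json")
    return report


def run_all(config: RunConfig) -> tuple[RunReport, RunReport]:
    """Both chains under one seed; artifacts land in subdirectories."""
    base = Path(config.outdir)
    flavour_cfg = dataclasses.replace(config, outdir=str(base / "flavour"))
    design_cfg = dataclasses.replace(config, outdir=str(base / "community"))
    return run_flavour_analysis(flavour_cfg), run_community_design(design_cfg)
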