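"""End-to-end screen driver: placement -> supervised replicas -> cluster
analysis -> consensus ranking, for a whole fragment library.

This is the library-level entry point the CLI wraps.  Everything is
deterministic given the configuration seeds: replica seeds come from the run
manifest, placement directions from the replica seed, and every dynamics
noise stream from (base seed, system seed, replica, step, attempt).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import ClusterParams, ConformationCluster, analyze_trajectory
from .energetics import EnergyModel, HBondCriteria
from .engine import (RunManifestEntry, SuMDConfig, ToyBrownianBackend,
                     Trajectory, run_sumd, schedule_replicas)
from .ranking import DEFAULT_EXTENDED, rank_pipeline
from .systems import Fragment, Receptor, SiteDefinition, place_fragment


@dataclass
class ScreenConfig:
    sumd: SuMDConfig = field(default_factory=SuMDConfig)
    cluster: ClusterParams = field(default_factory=ClusterParams)
    model: EnergyModel = field(default_factory=EnergyModel)
    hbond: HBondCriteria = field(default_factory=HBondCriteria)
    min_separation: float = 50.0
    electrostatic_cutoff: float = 9.0
    min_occupancy: float = 10.0
    decile_fraction: float = 0.10
    policy: str = "extended"


@dataclass
class ScreenResult:
    manifest: list[RunManifestEntry]
    outcomes: dict[tuple[str, int], str]
    clusters: list[ConformationCluster]
    report: dict

    @property
    def hits(self) -> list[str]:
        return self.report["hits"]


def run_replica(receptor: Receptor, fragment: Fragment, site: SiteDefinition,
                entry: RunManifestEntry, config: ScreenConfig,
                backend=None) -> Trajectory:
    system = place_fragment(receptor, fragment, site,
                            config.min_separation,
                            config.electrostatic_cutoff, seed=entry.seed)
    return run_sumd(system, site, config.sumd, backend=backend,
                    replica_id=entry.replica, model=config.model)


def run_screen(receptor: Receptor, fragments: list[Fragment],
               site: SiteDefinition,
               config: ScreenConfig | None = None,
               keep_trajectories: bool = False) -> ScreenResult:
    """Run the full screen for a library; replica trajectories are analysed
    per replica and the scored clusters pooled into one consensus ranking."""
    config = config or ScreenConfig()
    manifest = schedule_replicas(fragments, config.sumd)
    by_index: dict[int, list[RunManifestEntry]] = {}
    for e in manifest:
        by_index.setdefault(e.fragment_index, []).append(e)

    outcomes: dict[tuple[str, int], str] = {}
    clusters: list[ConformationCluster] = []
    trajectories: list[Trajectory] = []
    for fi, entries in by_index.items():
        fragment = fragments[fi]
        backend = ToyBrownianBackend(receptor, fragment, model=config.model)
        for entry in entries:
            traj = run_replica(receptor, fragment, site, entry, config,
                               backend=backend)
            outcomes[(entry.fragment_id, entry.replica)] = traj.outcome
            clusters.extend(analyze_trajectory(
                traj, receptor, fragment, config.cluster,
                model=config.model, criteria=config.hbond))
            if keep_trajectories:
                trajectories.append(traj)

    report = rank_pipeline(clusters, config.min_occupancy,
                           config.decile_fraction, config.policy,
                           DEFAULT_EXTENDED)
    result = ScreenResult(manifest=manifest, outcomes=outcomes,
                          clusters=clusters, report=report)
    if keep_trajectories:
        result.trajectories = trajectories  # type: ignore[attr-defined]
    return result


def screen_summary(result: ScreenResult) -> dict:
    """Plain-dict summary suitable for JSON reports."""
    outcome_counts: dict[str, int] = {}
    for o in result.outcomes.values():
        outcome_counts[o] = outcome_counts.get(o, 0) + 1
    calls = result.report.get("calls", {})
    return {
        "n_runs": len(result.manifest),
        "outcomes": outcome_counts,
        "n_clusters": len(result.clusters),
        "n_gated": len(result.report.get("gated", [])),
        "hits": result.hits,
        "classes": {f: c.venn_class.name for f, c in calls.items()},
    }
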