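"""Turn a binding trajectory into scored conformation clusters.

The pipeline per replica is: pairwise fragment-coordinate RMSD matrix (no
rotational superposition — the receptor frame is the reference and the pose
*location* is the signal), DBSCAN on the precomputed distance matrix
(defaults eps = 1.5 A, min_samples = 10, the point itself counted), then
per-cluster descriptors:

* ``SIZE_clust`` — member-frame count, also as % of the parent trajectory;
* ``MMGBSA_clust`` — the mean surrogate interaction energy (best value kept
  alongside; the best-energy frame is the cluster representative);
* ``HYD_clust`` — mean hydrophobic-contact score (best kept alongside);
* hydrogen-bond records with per-cluster occupancy percentages.

Clash-flagged frames (NaN energy) are excluded from the energy aggregates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .energetics import HBondCriteria, HBondRecord, hbond_occupancy
from .errors import ValidationError

NOISE_LABEL = -1


@dataclass(frozen=True)
class ClusterParams:
    eps: float = 1.5          # A
    min_samples: int = 10     # the point itself is counted

    def __post_init__(self) -> None:
        if self.eps <= 0 or self.min_samples < 1:
            raise ValueError("eps must be > 0 and min_samples >= 1")


@dataclass
class ConformationCluster:
    """One DBSCAN cluster of fragment poses with its consensus descriptors."""

    cluster_id: int
    fragment_id: str
    replica_id: int
    members: np.ndarray           # frame indices into the parent trajectory
    size: int                     # SIZE_clust
    population_pct: float         # 100 * size / n_frames
    representative: int           # frame index of the best energy
    dg_best: float                # kcal/mol
    dg_ave: float                 # MMGBSA_clust
    hyd_best: float
    hyd_ave: float                # HYD_clust
    hbonds: list[HBondRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.isfinite(self.dg_best) and self.dg_best > self.dg_ave + 1e-9:
            raise ValidationError("dg_best must not exceed dg_ave")
        if self.hyd_best < self.hyd_ave - 1e-9:
            raise ValidationError("hyd_best must not be below hyd_ave")


def pairwise_rmsd(frames: np.ndarray) -> np.ndarray:
    """n_f x n_f matrix of fragment-coordinate RMSDs (A), computed in the
    receptor-fixed frame without superposition."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValidationError("frames must be (n_frames, n_atoms, 3)")
    diff = frames[:, None, :, :] - frames[None, :, :, :]
    msd = np.mean(np.sum(diff * diff, axis=3), axis=2)
    return np.sqrt(msd)


def density_cluster(matrix: np.ndarray,
                    params: ClusterParams | None = None) -> np.ndarray:
    """DBSCAN labels over a precomputed distance matrix; -1 marks noise.

    Standard semantics: core points have >= min_samples neighbours within eps
    (self included); clusters are the density-connected components; border
    points reachable from cores of several clusters go to the cluster formed
    earliest, i.e. the one whose first core point has the lowest frame index
    (deterministic given the frame order).
    """
    params = params or ClusterParams()
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] != matrix.shape[1]:
        raise ValidationError("distance matrix must be square")
    if matrix.shape[0] == 0:
        return np.empty(0, dtype=np.int64)
    labels = DBSCAN(eps=params.eps, min_samples=params.min_samples,
                    metric="precomputed").fit(matrix).labels_
    return labels.astype(np.int64)


def cluster_population(labels: np.ndarray, n_f: int | None = None
                       ) -> dict[int, tuple[int, float]]:
    """Per-cluster (absolute frame count, % of the parent trajectory)."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValidationError("empty label set")
    n_f = len(labels) if n_f is None else n_f
    out: dict[int, tuple[int, float]] = {}
    for lab in sorted(set(labels.tolist())):
        if lab == NOISE_LABEL:
            continue
        count = int(np.sum(labels == lab))
        out[int(lab)] = (count, 100.0 * count / n_f)
    return out


def cluster_representative(member_frames: np.ndarray,
                           energies: np.ndarray) -> int:
    """Frame index of the minimum energy; ties go to the lowest frame index;
    clash-flagged (NaN) members are ineligible."""
    member_frames = np.asarray(member_frames)
    energies = np.asarray(energies, dtype=float)
    if len(member_frames) != len(energies):
        raise ValidationError("need one energy per member frame")
    ok = np.isfinite(energies)
    if not ok.any():
        raise ValidationError("all member frames are clash-flagged")
    masked = np.where(ok, energies, np.inf)
    order = np.lexsort((member_frames, masked))
    return int(member_frames[order[0]])


def score_clusters(trajectory, receptor, fragment, labels: np.ndarray,
                   model=None, hyd_params=None,
                   criteria: HBondCriteria | None = None,
                   hyd_scores: np.ndarray | None = None
                   ) -> list[ConformationCluster]:
    """Aggregate per-frame observables into per-cluster descriptors."""
    from .energetics import frame_hyd_scores

    labels = np.asarray(labels)
    n_f = len(trajectory.frames)
    if len(labels) != n_f:
        raise ValidationError("one label per frame required")
    energies = trajectory.energies
    if hyd_scores is None:
        hyd_scores = frame_hyd_scores(receptor, fragment, trajectory.frames,
                                      hyd_params)
    clusters: list[ConformationCluster] = []
    for lab, (count, pct) in cluster_population(labels, n_f).items():
        members = np.flatnonzero(labels == lab)
        e = energies[members]
        ok = np.isfinite(e)
        dg_best = float(np.min(e[ok])) if ok.any() else np.nan
        dg_ave = float(np.mean(e[ok])) if ok.any() else np.nan
        h = hyd_scores[members]
        rep = cluster_representative(members, e) if ok.any() else int(members[0])
        records = hbond_occupancy(receptor, fragment,
                                  trajectory.frames[members], criteria)
        clusters.append(ConformationCluster(
            cluster_id=int(lab), fragment_id=trajectory.fragment_id,
            replica_id=trajectory.replica_id, members=members, size=count,
            population_pct=pct, representative=rep, dg_best=dg_best,
            dg_ave=dg_ave, hyd_best=float(np.max(h)),
            hyd_ave=float(np.mean(h)), hbonds=records))
    return clusters


def analyze_trajectory(trajectory, receptor, fragment,
                       params: ClusterParams | None = None,
                       model=None, criteria=None) -> list[ConformationCluster]:
    """RMSD matrix -> DBSCAN -> scored clusters, for one replica."""
    if len(trajectory.frames) == 0:
        return []
    matrix = pairwise_rmsd(trajectory.frames)
    labels = density_cluster(matrix, params)
    return score_clusters(trajectory, receptor, fragment, labels,
                          model=model, criteria=criteria)


def clusters_to_table(clusters: list[ConformationCluster]):
    """Flatten scored clusters into a pandas DataFrame (CSV-ready)."""
    import json

    import pandas as pd

    rows = []
    for uid, c in enumerate(clusters):
        rows.append({
            "uid": uid, "cluster_id": c.cluster_id,
            "fragment_id": c.fragment_id, "replica": c.replica_id,
            "size_clust": c.size, "population_pct": c.population_pct,
            "dg_best": c.dg_best, "dg_ave": c.dg_ave,
            "hyd_best": c.hyd_best, "hyd_ave": c.hyd_ave,
            "representative": c.representative,
            "hbonds": json.dumps([
                {"residue": h.residue, "occupancy": h.occupancy}
                for h in c.hbonds]),
        })
    return pd.DataFrame(rows)
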