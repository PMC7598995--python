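"""Consensus hit ranking over scored conformation clusters.

The triage mirrors a fragment screen's cluster bookkeeping: (1) keep only
clusters that carry at least one hydrogen bond (occupancy gate); (2) build
three independent ranks over the survivors — SIZE_clust and HYD_clust
descending, MMGBSA_clust ascending (most negative binding energy first) —
keeping the top decile of each, k = max(1, round(0.10 n)); (3) classify each
cluster by which retained rank sets it belongs to (the Venn diagram regions),
give every fragment the best class among its clusters, and keep only the
highest-score cluster (best mean energy) per fragment; (4) emit the hit list:
"first_choice" returns only fragments with maximum three-way convergence,
"extended" adds the configured two-way regions (default HYD&SIZE and
HYD&MMGBSA — the regions that converge best with orthogonal experiments).

Ties everywhere break by better mean energy then lower cluster uid, so
reports are byte-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .analysis import ConformationCluster
from .errors import ConfigError, ValidationError

DESCRIPTOR_SIZE = "SIZE_clust"
DESCRIPTOR_HYD = "HYD_clust"
DESCRIPTOR_MMGBSA = "MMGBSA_clust"


class VennClass(Enum):
    """Convergence class; lower value = stronger consensus."""

    FIRST_CHOICE = 0       # in all three top-decile ranks
    HYD_SIZE = 1
    HYD_MMGBSA = 2
    MMGBSA_SIZE = 3
    SINGLE = 4
    NONE = 5


PAIRWISE_CLASSES = (VennClass.HYD_SIZE, VennClass.HYD_MMGBSA,
                    VennClass.MMGBSA_SIZE)
DEFAULT_EXTENDED = (VennClass.HYD_SIZE, VennClass.HYD_MMGBSA)


@dataclass(frozen=True)
class RankSet:
    """One descriptor rank with its retained top-decile subset."""

    descriptor: str
    ordered: tuple[int, ...]       # cluster uids, best first
    retained: frozenset            # the top max(1, round(0.10 n)) uids


@dataclass
class FragmentCall:
    """Per-fragment consensus outcome."""

    fragment_id: str
    venn_class: VennClass
    best_cluster_uid: int | None


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.total

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else np.nan

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else np.nan


def hbond_gate(clusters: list[ConformationCluster],
               min_occupancy: float = 10.0) -> list[ConformationCluster]:
    """Keep clusters with at least one H-bond record at or above the
    occupancy threshold (percent)."""
    return [c for c in clusters
            if any(h.occupancy >= min_occupancy for h in c.hbonds)]


def top_decile_count(n: int, fraction: float = 0.10) -> int:
    return max(1, round(fraction * n))


def _ordered(values, dg_ave, ascending: bool) -> tuple[int, ...]:
    """Stable order: descriptor value, then better dg_ave, then lower uid."""
    vals = np.asarray(values, dtype=float)
    key = vals if ascending else -vals
    order = np.lexsort((np.arange(len(vals)), np.asarray(dg_ave), key))
    return tuple(int(i) for i in order)


def top_decile_ranks(clusters: list[ConformationCluster],
                     fraction: float = 0.10) -> dict[str, RankSet]:
    """The three descriptor ranks with their retained top-decile subsets."""
    if not clusters:
        raise ValidationError("no clusters to rank")
    k = top_decile_count(len(clusters), fraction)
    dg_ave = [c.dg_ave for c in clusters]
    out = {}
    for name, values, ascending in (
            (DESCRIPTOR_SIZE, [c.size for c in clusters], False),
            (DESCRIPTOR_HYD, [c.hyd_ave for c in clusters], False),
            (DESCRIPTOR_MMGBSA, [c.dg_ave for c in clusters], True)):
        order = _ordered(values, dg_ave, ascending)
        out[name] = RankSet(descriptor=name, ordered=order,
                            retained=frozenset(order[:k]))
    return out


def classify_cluster(uid: int, ranks: dict[str, RankSet]) -> VennClass:
    in_size = uid in ranks[DESCRIPTOR_SIZE].retained
    in_hyd = uid in ranks[DESCRIPTOR_HYD].retained
    in_mm = uid in ranks[DESCRIPTOR_MMGBSA].retained
    n_in = in_size + in_hyd + in_mm
    if n_in == 3:
        return VennClass.FIRST_CHOICE
    if n_in == 2:
        if in_hyd and in_size:
            return VennClass.HYD_SIZE
        if in_hyd and in_mm:
            return VennClass.HYD_MMGBSA
        return VennClass.MMGBSA_SIZE
    return VennClass.SINGLE if n_in == 1 else VennClass.NONE


def venn_classify(ranks: dict[str, RankSet],
                  clusters: list[ConformationCluster]
                  ) -> tuple[dict[int, VennClass], dict[str, FragmentCall]]:
    """Cluster-level Venn classes, then per-fragment calls.

    A fragment inherits the best class among its clusters; within that class
    only its highest-score cluster (best mean energy, then lowest uid) is
    retained as the fragment's representative.
    """
    cluster_classes = {uid: classify_cluster(uid, ranks)
                       for uid in range(len(clusters))}
    calls: dict[str, FragmentCall] = {}
    for uid, c in enumerate(clusters):
        cls = cluster_classes[uid]
        cur = calls.get(c.fragment_id)
        if cur is None or cls.value < cur.venn_class.value:
            calls[c.fragment_id] = FragmentCall(c.fragment_id, cls, uid)
        elif cls.value == cur.venn_class.value and cur.best_cluster_uid is not None:
            best = clusters[cur.best_cluster_uid]
            if (c.dg_ave, uid) < (best.dg_ave, cur.best_cluster_uid):
                calls[c.fragment_id] = FragmentCall(c.fragment_id, cls, uid)
    return cluster_classes, calls


def hit_list(calls: dict[str, FragmentCall], policy: str = "first_choice",
             extended_classes=DEFAULT_EXTENDED) -> list[str]:
    """Fragment ids predicted as hits under the given policy."""
    if policy == "first_choice":
        keep = {VennClass.FIRST_CHOICE}
    elif policy == "extended":
        bad = set(extended_classes) - set(PAIRWISE_CLASSES)
        if bad:
            raise ConfigError(f"not pairwise classes: {sorted(bad)}")
        keep = {VennClass.FIRST_CHOICE, *extended_classes}
    else:
        raise ConfigError(f"unknown hit-list policy {policy!r}")
    return sorted(f for f, call in calls.items() if call.venn_class in keep)


def confusion_metrics(predicted, truth, total: int) -> ConfusionCounts:
    """Standard confusion counts of a screen against ground truth."""
    predicted = set(predicted)
    truth = set(truth)
    if len(predicted | truth) > total:
        raise ValidationError("universe smaller than predicted | truth")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = total - len(predicted | truth)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def rank_pipeline(clusters: list[ConformationCluster],
                  min_occupancy: float = 10.0, fraction: float = 0.10,
                  policy: str = "extended",
                  extended_classes=DEFAULT_EXTENDED):
    """Gate -> ranks -> Venn classes -> hit list; returns a report dict."""
    gated = hbond_gate(clusters, min_occupancy)
    if not gated:
        return {"gated": [], "ranks": None, "cluster_classes": {},
                "calls": {}, "hits": []}
    ranks = top_decile_ranks(gated, fraction)
    cluster_classes, calls = venn_classify(ranks, gated)
    hits = hit_list(calls, policy, extended_classes)
    return {"gated": gated, "ranks": ranks,
            "cluster_classes": cluster_classes, "calls": calls, "hits": hits}
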