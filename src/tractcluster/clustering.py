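"""Connectivity-constrained agglomerative clustering (Ward linkage).

This is the analytical core of the pipeline, written from scratch: pixels
inside the white-matter mask, described by min–max normalized morphometric
features, are greedily agglomerated under a pixel-adjacency constraint.
At every step the pair of *adjacent* clusters with the smallest Ward cost

    Δ(i, j) = nᵢ·nⱼ / (nᵢ + nⱼ) · ‖μᵢ − μⱼ‖²

is merged (the increase in total within-cluster variance).  Costs are
computed from maintained (count, feature-sum) statistics — the same
quantity the Lance–Williams Ward recurrence propagates, but well defined
also for cluster pairs that first become adjacent mid-agglomeration.
Candidate merges live in a lazy-deletion heap; merged clusters get fresh
ids, so stale heap entries are detected by liveness alone.  Ties on merge
cost break toward the lexicographically smallest id pair, making the whole
procedure deterministic.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np

from .images import MetricStack, Parcellation
from .levels import LevelScheme


# ---------------------------------------------------------------------------
# features

@dataclass
class FeatureTable:
    """One row per masked pixel: normalized metrics + pixel coordinates."""

    values: np.ndarray   # (N, F) in [0, 1]
    coords: np.ndarray   # (N, 2) int row/col
    metric_names: tuple[str, ...]
    shape: tuple[int, int]

    def __post_init__(self) -> None:
        if self.values.ndim != 2 or self.coords.shape != (len(self.values), 2):
            raise ValueError("values must be (N, F) with matching (N, 2) coords")

    @property
    def n_pixels(self) -> int:
        return len(self.values)


def normalize_metrics(
    stack: MetricStack, metrics: tuple[str, ...] | None = None
) -> FeatureTable:
    """Min–max scale each metric to [0, 1] over masked pixels.

    A constant metric carries no contrast; it maps to an all-zero column
    and a warning is emitted.
    """
    mask = stack.mask
    if not mask.any():
        raise ValueError("empty mask")
    names = tuple(metrics) if metrics is not None else stack.metric_names
    coords = np.argwhere(mask)
    cols = []
    for name in names:
        vals = stack.channels[name][mask]
        if not np.all(np.isfinite(vals)):
            raise ValueError(f"metric {name!r} has undefined values inside the mask")
        lo, hi = vals.min(), vals.max()
        if hi - lo <= 0:
            warnings.warn(
                f"metric {name!r} is constant over the mask; normalized to zeros",
                stacklevel=2,
            )
            cols.append(np.zeros_like(vals))
        else:
            cols.append((vals - lo) / (hi - lo))
    return FeatureTable(
        values=np.stack(cols, axis=1),
        coords=coords,
        metric_names=names,
        shape=stack.shape,
    )


# ---------------------------------------------------------------------------
# pixel adjacency

_OFFSETS = {
    "axial4": ((0, 1), (1, 0)),
    "axial8": ((0, 1), (1, 0), (1, 1), (1, -1)),
}


@dataclass
class ConnectivityGraph:
    """Symmetric pixel-adjacency lists over masked pixel indices."""

    neighbors: list[set[int]]
    scheme: str
    component_labels: np.ndarray  # (N,) component id per pixel
    n_components: int

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.neighbors) // 2


def build_connectivity(mask: np.ndarray, scheme: str = "axial4") -> ConnectivityGraph:
    """Adjacency between in-mask neighbor pixels under a 4- or 8-neighborhood."""
    if scheme not in _OFFSETS:
        raise ValueError(f"unknown connectivity scheme {scheme!r}")
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("empty mask")
    index = -np.ones(mask.shape, dtype=np.int64)
    coords = np.argwhere(mask)
    index[mask] = np.arange(len(coords))
    neighbors: list[set[int]] = [set() for _ in range(len(coords))]
    h, w = mask.shape
    for dr, dc in _OFFSETS[scheme]:
        for i, (r, c) in enumerate(coords):
            rr, cc = r + dr, c + dc
            if 0 <= rr < h and 0 <= cc < w and mask[rr, cc]:
                j = int(index[rr, cc])
                neighbors[i].add(j)
                neighbors[j].add(i)

    comp = -np.ones(len(coords), dtype=np.int64)
    n_comp = 0
    for start in range(len(coords)):
        if comp[start] >= 0:
            continue
        stack = [start]
        comp[start] = n_comp
        while stack:
            cur = stack.pop()
            for nb in neighbors[cur]:
                if comp[nb] < 0:
                    comp[nb] = n_comp
                    stack.append(nb)
        n_comp += 1
    return ConnectivityGraph(
        neighbors=neighbors, scheme=scheme, component_labels=comp, n_components=n_comp
    )


# ---------------------------------------------------------------------------
# Ward agglomeration

@dataclass
class MergeRecord:
    cluster_a: int
    cluster_b: int
    cost: float
    new_id: int
    new_size: int


@dataclass
class Dendrogram:
    """Ordered merge history plus the final flat labels."""

    merges: list[MergeRecord] = field(default_factory=list)
    leaf_count: int = 0
    final_members: dict[int, list[int]] = field(default_factory=dict)


def _ward_cost(n_i: float, s_i: np.ndarray, n_j: float, s_j: np.ndarray) -> float:
    mu_i = s_i / n_i
    mu_j = s_j / n_j
    diff = mu_i - mu_j
    return float(n_i * n_j / (n_i + n_j) * (diff @ diff))


def _apportion(counts: list[int], total_clusters: int) -> list[int]:
    """Split a cluster budget across components by pixel share (≥ 1 each,
    largest-remainder rounding, never more clusters than pixels)."""
    n_comp = len(counts)
    k = max(total_clusters, n_comp)
    n_total = sum(counts)
    quotas = [k * c / n_total for c in counts]
    targets = [min(max(1, int(np.floor(q))), c) for q, c in zip(quotas, counts)]
    remainders = [q - np.floor(q) for q in quotas]
    # top up by largest remainder, or trim by smallest, until the budget fits
    while sum(targets) < k:
        order = sorted(
            (i for i in range(n_comp) if targets[i] < counts[i]),
            key=lambda i: (-remainders[i], i),
        )
        if not order:
            break  # fewer pixels than requested clusters overall
        targets[order[0]] += 1
        remainders[order[0]] -= 1
    while sum(targets) > k:
        order = sorted(
            (i for i in range(n_comp) if targets[i] > 1),
            key=lambda i: (remainders[i], i),
        )
        targets[order[0]] -= 1
        remainders[order[0]] += 1
    return targets


def ward_cluster(
    features: FeatureTable,
    graph: ConnectivityGraph,
    n_clusters: int,
    provenance: dict | None = None,
) -> tuple[Parcellation, Dendrogram]:
    """Greedy constrained Ward agglomeration down to ``n_clusters``.

    On a connected graph exactly ``N − n_clusters`` merges are performed.
    A disconnected graph is clustered per component, with the cluster
    budget apportioned by component pixel share (at least one each), so
    the result has ``max(n_clusters, n_components)`` clusters.
    """
    n = features.n_pixels
    if n == 0:
        raise ValueError("empty feature table")
    if len(graph.neighbors) != n:
        raise ValueError("connectivity graph and feature table disagree on pixels")
    if not 1 <= n_clusters <= n:
        raise ValueError(f"n_clusters must lie in [1, {n}]")

    # per-cluster state; merged clusters get fresh ids
    counts: dict[int, int] = {i: 1 for i in range(n)}
    sums: dict[int, np.ndarray] = {i: features.values[i].copy() for i in range(n)}
    nbrs: dict[int, set[int]] = {i: set(graph.neighbors[i]) for i in range(n)}
    members: dict[int, list[int]] = {i: [i] for i in range(n)}
    comp_of: dict[int, int] = {i: int(graph.component_labels[i]) for i in range(n)}

    comp_counts = [0] * graph.n_components
    for i in range(n):
        comp_counts[comp_of[i]] += 1
    targets = _apportion(comp_counts, n_clusters)
    active_in_comp = list(comp_counts)

    heap: list[tuple[float, int, int]] = []
    for i in range(n):
        for j in graph.neighbors[i]:
            if i < j:
                heap.append((_ward_cost(1, sums[i], 1, sums[j]), i, j))
    heapq.heapify(heap)

    dendro = Dendrogram(leaf_count=n)
    next_id = n
    pending = sum(
        max(c - t, 0) for c, t in zip(comp_counts, targets)
    )  # merges still to perform
    while pending > 0 and heap:
        cost, a, b = heapq.heappop(heap)
        if a not in counts or b not in counts:
            continue  # stale: one side already merged away
        if b not in nbrs[a]:
            continue
        comp = comp_of[a]
        if active_in_comp[comp] <= targets[comp]:
            continue  # this component already reached its budget
        new_sum = sums[a] + sums[b]
        new_n = counts[a] + counts[b]
        new_nbrs = (nbrs[a] | nbrs[b]) - {a, b}
        for old in (a, b):
            for nb in nbrs[old]:
                nbrs[nb].discard(old)
            del counts[old], sums[old], nbrs[old]
        cid = next_id
        next_id += 1
        counts[cid] = new_n
        sums[cid] = new_sum
        nbrs[cid] = new_nbrs
        members[cid] = members.pop(a) + members.pop(b)
        comp_of[cid] = comp
        for nb in new_nbrs:
            nbrs[nb].add(cid)
            lo, hi = (nb, cid) if nb < cid else (cid, nb)
            heapq.heappush(
                heap, (_ward_cost(counts[nb], sums[nb], new_n, new_sum), lo, hi)
            )
        dendro.merges.append(MergeRecord(a, b, cost, cid, new_n))
        active_in_comp[comp] -= 1
        pending -= 1

    # deterministic flat labels: 1..k ordered by each cluster's first pixel
    final = sorted(counts, key=lambda cid: min(members[cid]))
    labels = np.zeros(features.shape, dtype=np.int32)
    for lab, cid in enumerate(final, start=1):
        for pix in members[cid]:
            r, c = features.coords[pix]
            labels[r, c] = lab
        dendro.final_members[lab] = sorted(members[cid])

    parc = Parcellation(
        labels=labels,
        n_clusters=len(final),
        provenance=dict(provenance or {}, scheme=graph.scheme, requested=n_clusters),
    )
    return parc, dendro


# ---------------------------------------------------------------------------
# drivers

def cluster_stack(
    stack: MetricStack,
    n_clusters: int,
    scheme: str = "axial4",
    metrics: tuple[str, ...] | None = None,
    provenance: dict | None = None,
) -> tuple[Parcellation, Dendrogram]:
    """Normalize, build adjacency and cluster one metric stack."""
    features = normalize_metrics(stack, metrics)
    graph = build_connectivity(stack.mask, scheme)
    return ward_cluster(features, graph, n_clusters, provenance)


def cluster_slicewise(
    templates: dict[str, MetricStack],
    n_clusters: int,
    scheme: str = "axial4",
    metrics: tuple[str, ...] | None = None,
) -> dict[str, Parcellation]:
    """Independent clustering per spinal level ('slice-wise' mode)."""
    out: dict[str, Parcellation] = {}
    for level, stack in templates.items():
        try:
            parc, _ = cluster_stack(
                stack, n_clusters, scheme, metrics,
                {"mode": "slice-wise", "level": level},
            )
        except Exception as exc:
            raise RuntimeError(f"slice-wise clustering failed at level {level}") from exc
        out[level] = parc
    return out


def cluster_regionwise(
    region_stacks: dict[str, MetricStack],
    n_clusters: int,
    scheme: str = "axial4",
    metrics: tuple[str, ...] | None = None,
) -> dict[str, Parcellation]:
    """Clustering of the registration-aggregated region stacks."""
    out: dict[str, Parcellation] = {}
    for region, stack in region_stacks.items():
        try:
            parc, _ = cluster_stack(
                stack, n_clusters, scheme, metrics,
                {"mode": "region-wise", "region": region},
            )
        except Exception as exc:
            raise RuntimeError(f"region-wise clustering failed for {region}") from exc
        out[region] = parc
    return out


def sweep_cluster_counts(
    stack: MetricStack,
    counts: range,
    scheme: str = "axial4",
    metrics: tuple[str, ...] | None = None,
) -> dict[int, Parcellation]:
    """Cluster one stack at every count in ``counts`` (cluster-count sweep)."""
    return {
        k: cluster_stack(stack, k, scheme, metrics, {"mode": "sweep", "k": k})[0]
        for k in counts
    }
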