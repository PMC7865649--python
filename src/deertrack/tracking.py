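"""Interval accumulation, same-individual clustering, movement paths.

Male deer are territorial during the rut, so calls localized at adjacent
positions are attributed to one animal. Deduplication is single-linkage
clustering under the flat-earth metric: calls are nodes, pairs closer than
the linkage threshold are edges, individuals are connected components.
Components are order-free, so shuffling the input never changes the result.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist, squareform

from .geodesy import (
    EarthModel,
    GeoPoint,
    flat_earth_distance,
    local_offset_m,
    offset_point,
)

__all__ = [
    "CallRecord",
    "IndividualCluster",
    "IntervalCounts",
    "MovementPath",
    "interval_counts",
    "cluster_individuals",
    "deduplicated_count",
    "movement_path",
]


@dataclass(frozen=True)
class CallRecord:
    """One localized, timestamped call."""

    call_id: str
    position: GeoPoint
    time_s: float
    rmse_m: float = float("nan")


@dataclass(frozen=True)
class IndividualCluster:
    """Calls attributed to a single animal."""

    cluster_id: int
    call_ids: tuple[str, ...]
    centroid: GeoPoint
    first_time: float
    last_time: float

    @property
    def size(self) -> int:
        return len(self.call_ids)


@dataclass(frozen=True)
class IntervalCounts:
    """Per-interval call counts over a session, with summary statistics."""

    counts: tuple[int, ...]
    interval_s: float
    session_start: float
    session_end: float
    last_interval_truncated: bool

    @property
    def n_calls(self) -> int:
        return int(sum(self.counts))

    @property
    def mean(self) -> float:
        return self.n_calls / len(self.counts) if self.counts else 0.0

    @property
    def sd(self) -> float:
        """Population standard deviation (divide by the number of intervals)."""
        return float(np.std(self.counts)) if self.counts else 0.0

    @property
    def sd_sample(self) -> float:
        if len(self.counts) < 2:
            return 0.0
        return float(np.std(self.counts, ddof=1))


def interval_counts(
    calls: Sequence[CallRecord],
    interval_s: float,
    session_start: float,
    session_end: float,
) -> IntervalCounts:
    """Count calls per fixed interval within [session_start, session_end).

    The last interval is truncated (and flagged) when the interval length
    does not divide the session. Calls outside the session are ignored.
    """
    if session_end <= session_start:
        raise ValueError("session_end must exceed session_start")
    if interval_s <= 0:
        raise ValueError("interval_s must be positive")
    length = session_end - session_start
    n = math.ceil(length / interval_s - 1e-12)
    truncated = not math.isclose(n * interval_s, length, rel_tol=0, abs_tol=1e-9)
    counts = [0] * n
    for c in calls:
        if session_start <= c.time_s < session_end:
            k = min(int((c.time_s - session_start) / interval_s), n - 1)
            counts[k] += 1
    return IntervalCounts(
        counts=tuple(counts),
        interval_s=interval_s,
        session_start=session_start,
        session_end=session_end,
        last_interval_truncated=truncated,
    )


def cluster_individuals(
    calls: Sequence[CallRecord],
    linkage_distance_m: float = 50.0,
    max_time_gap_s: float | None = None,
    earth: EarthModel = EarthModel(),
) -> list[IndividualCluster]:
    """Group calls into individuals by single-linkage spatial adjacency.

    Two calls are linked when their flat-earth distance is at most
    ``linkage_distance_m`` (and, if ``max_time_gap_s`` is set, their times
    differ by no more than that); clusters are the connected components of
    the link graph. Time gating is off by default — territorial males sit
    on a spot for long stretches, and calls tens of minutes apart can still
    be the same animal.

    Cluster ids are assigned in order of each cluster's earliest call.
    """
    if linkage_distance_m <= 0:
        raise ValueError("linkage_distance_m must be positive")
    if not calls:
        return []
    ref = calls[0].position
    xy = np.array([local_offset_m(ref, c.position, earth) for c in calls])
    if len(calls) == 1:
        dmat = np.zeros((1, 1))
    else:
        dmat = squareform(pdist(xy))
    adj = dmat <= linkage_distance_m
    if max_time_gap_s is not None:
        t = np.array([c.time_s for c in calls])
        adj &= np.abs(t[:, None] - t[None, :]) <= max_time_gap_s
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    clusters: list[IndividualCluster] = []
    for comp in range(n_comp):
        idx = np.flatnonzero(labels == comp)
        members = sorted(idx, key=lambda i: (calls[i].time_s, calls[i].call_id))
        e, nn = xy[idx].mean(axis=0)
        clusters.append(
            IndividualCluster(
                cluster_id=-1,  # assigned after time-sorting below
                call_ids=tuple(calls[i].call_id for i in members),
                centroid=offset_point(ref, float(e), float(nn), earth),
                first_time=float(min(calls[i].time_s for i in idx)),
                last_time=float(max(calls[i].time_s for i in idx)),
            )
        )
    clusters.sort(key=lambda c: (c.first_time, c.call_ids[0]))
    return [
        IndividualCluster(
            cluster_id=k,
            call_ids=c.call_ids,
            centroid=c.centroid,
            first_time=c.first_time,
            last_time=c.last_time,
        )
        for k, c in enumerate(clusters)
    ]


def deduplicated_count(clusters: Sequence[IndividualCluster]) -> int:
    """Number of distinct individuals after repetitive-call elimination."""
    return len(clusters)


@dataclass(frozen=True)
class MovementPath:
    """Time-ordered positions of one individual with displacement summary."""

    cluster_id: int
    positions: tuple[GeoPoint, ...]
    times: tuple[float, ...]
    net_displacement_m: float
    path_length_m: float
    bearing_deg: float  # compass bearing first -> last (0 = north, 90 = east)


def movement_path(
    cluster: IndividualCluster,
    calls: Sequence[CallRecord],
    earth: EarthModel = EarthModel(),
) -> MovementPath:
    """Polyline of a cluster's calls in time order.

    Net displacement is the flat-earth distance from first to last call;
    bearing is the compass heading of that net move. A singleton cluster
    yields an empty path with zero displacement.
    """
    by_id = {c.call_id: c for c in calls}
    members = [by_id[cid] for cid in cluster.call_ids]
    members.sort(key=lambda c: (c.time_s, c.call_id))
    if len(members) < 2:
        pos = tuple(c.position for c in members)
        t = tuple(c.time_s for c in members)
        return MovementPath(cluster.cluster_id, pos, t, 0.0, 0.0, float("nan"))
    pos = tuple(c.position for c in members)
    t = tuple(c.time_s for c in members)
    seg = [
        flat_earth_distance(pos[i], pos[i + 1], earth) for i in range(len(pos) - 1)
    ]
    net = flat_earth_distance(pos[0], pos[-1], earth)
    e, n = local_offset_m(pos[0], pos[-1], earth)
    bearing = math.degrees(math.atan2(e, n)) % 360.0 if net > 0 else float("nan")
    return MovementPath(
        cluster_id=cluster.cluster_id,
        positions=pos,
        times=t,
        net_displacement_m=net,
        path_length_m=float(sum(seg)),
        bearing_deg=bearing,
    )
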