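"""Chain-aggregate detection and length statistics.

Under a magnetic field the beads line up into chain-shaped aggregates; the
experimental observable is the chain length (micrometres) versus exposure
time, coil current, particle diameter and suspension density.  An aggregate
is operationalized as a connected component of the contact graph whose
edges join pairs closer than ``tolerance * (Ri + Rj)``; its length is the
maximal end-to-end extent, max over member pairs of
(center distance + Ri + Rj).

``normalized_rates`` divides each sweep's final mean length by a nominal
length (default 6.2 um, the nominal-condition aggregate length) to rank
parameter effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .dynamics import SimulationState, Trajectory, _grid_pairs

__all__ = [
    "Cluster",
    "AggregateStats",
    "find_clusters",
    "chain_length",
    "aggregate_stats",
    "growth_ratio",
    "normalized_rates",
    "NOMINAL_LENGTH_UM",
]

#: Nominal-condition aggregate length (um) used to normalize sweep rates.
NOMINAL_LENGTH_UM = 6.2


@dataclass(frozen=True)
class Cluster:
    """A detected aggregate: member particle ids and its length in um."""

    member_ids: FrozenSet[int]
    length: float

    def __post_init__(self):
        if not self.member_ids:
            raise ValueError("cluster must be non-empty")


@dataclass
class AggregateStats:
    """Per-frame chain statistics: times (s), mean length (um), counts."""

    times: List[float]
    mean_length: List[float]
    count: List[int]

    def __post_init__(self):
        if not (len(self.times) == len(self.mean_length) == len(self.count)):
            raise ValueError("times, mean_length and count must have equal length")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            dict(time=self.times, mean_length_um=self.mean_length, n_clusters=self.count)
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "AggregateStats":
        df = pd.read_csv(path)
        return cls(
            times=list(df["time"]),
            mean_length=list(df["mean_length_um"]),
            count=[int(c) for c in df["n_clusters"]],
        )


def _component_labels(state: SimulationState, tolerance: float) -> np.ndarray:
    pos = state.positions()
    rad = state.radii()
    n = len(state.particles)
    if n == 0:
        return np.zeros(0, dtype=int)
    cutoff = float(tolerance * 2.0 * rad.max())
    pairs = _grid_pairs(pos, cutoff)
    ii, jj = [], []
    for i, j in pairs:
        d = float(np.linalg.norm(pos[i] - pos[j]))
        if d <= tolerance * (rad[i] + rad[j]):
            ii.append(i)
            jj.append(j)
    adj = csr_matrix(
        (np.ones(2 * len(ii)), (ii + jj, jj + ii)), shape=(n, n)
    )
    _, labels = connected_components(adj, directed=False)
    return labels


def find_clusters(state: SimulationState, tolerance: float = 1.05) -> List[Cluster]:
    """Connected components of the contact graph (edge iff the gap between
    centers is within ``tolerance * (Ri + Rj)``), with lengths attached."""
    if tolerance < 1.0:
        raise ValueError("tolerance must be >= 1")
    labels = _component_labels(state, tolerance)
    clusters: List[Cluster] = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        ids = frozenset(int(state.particles[k].id) for k in members)
        length = _extent_um(state, members)
        clusters.append(Cluster(member_ids=ids, length=length))
    clusters.sort(key=lambda c: min(c.member_ids))
    return clusters


def _extent_um(
    state: SimulationState, members: np.ndarray, drop_axis: Optional[int] = None
) -> float:
    pos = state.positions()[members]
    rad = state.radii()[members]
    if drop_axis is not None:
        keep = [a for a in range(3) if a != drop_axis]
        pos = pos[:, keep]
    if len(members) == 1:
        return float(2.0 * rad[0] * 1e6)
    diff = pos[:, None, :] - pos[None, :, :]
    dist = np.linalg.norm(diff, axis=-1)
    extent = dist + rad[:, None] + rad[None, :]
    np.fill_diagonal(extent, 2.0 * rad)
    return float(extent.max() * 1e6)


def chain_length(
    cluster: Cluster, state: SimulationState, drop_axis: Optional[int] = None
) -> float:
    """Maximal end-to-end extent of a cluster in um: max over member pairs
    of center distance + Ri + Rj (a singleton reports its own diameter).

    ``drop_axis`` projects out one coordinate, emulating a 2D microscope
    measurement of a 3D chain.
    """
    id_to_idx = {p.id: k for k, p in enumerate(state.particles)}
    try:
        members = np.array([id_to_idx[i] for i in sorted(cluster.member_ids)])
    except KeyError as err:
        raise KeyError(f"cluster references missing particle id {err}") from err
    return _extent_um(state, members, drop_axis=drop_axis)


def aggregate_stats(traj: Trajectory, tolerance: float = 1.05) -> AggregateStats:
    """Mean chain length and cluster count for every saved frame."""
    if len(traj) == 0:
        raise ValueError("trajectory is empty")
    times, means, counts = [], [], []
    for frame in traj.frames:
        clusters = find_clusters(frame, tolerance)
        times.append(frame.time)
        counts.append(len(clusters))
        means.append(float(np.mean([c.length for c in clusters])))
    return AggregateStats(times=times, mean_length=means, count=counts)


def growth_ratio(stats: AggregateStats) -> float:
    """Final over initial mean chain length (the 30 s / 1 s style ratio)."""
    return stats.mean_length[-1] / stats.mean_length[0]


def normalized_rates(
    sweeps: Dict, nominal_length: float = NOMINAL_LENGTH_UM
) -> Dict:
    """Final mean length of each sweep divided by the nominal length,
    giving the dimensionless parameter-effect ranking."""
    if not nominal_length > 0:
        raise ValueError("nominal_length must be positive")
    return {key: stats.mean_length[-1] / nominal_length for key, stats in sweeps.items()}
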