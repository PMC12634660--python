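"""Egocentric syllable trajectories, cosine-distance similarity and
movement-class contrasts.

Each bout instance of a syllable is translated so its onset is the origin
and rotated so the onset heading (displacement over the first two frames)
points along +x, then resampled to a fixed number of points; the syllable
trajectory is the mean over instances.  Pairwise cosine distances between
flattened mean paths feed an average-linkage dendrogram; per-syllable
movement metrics (net displacement, path length, net heading change)
support the stationary/undirected-vs-directed contrast between DM and DU
syllables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .io_core import Bout, CentroidTrack, FormatError, TestResult
from .syllables import _mwu_family

__all__ = [
    "SyllableTrajectory",
    "egocentric_instances",
    "egocentric_mean_trajectory",
    "cosine_distance",
    "similarity_dendrogram",
    "movement_metrics",
    "movement_class_test",
    "resample_path",
]

DEFAULT_RESAMPLE_POINTS = 10  # the median bout length in frames


@dataclass
class SyllableTrajectory:
    syllable: int
    mean_path: np.ndarray          # (L, 2), path[0] == (0, 0)
    n_instances: int
    net_displacement: float        # mm
    path_length: float             # mm
    net_heading_change: float      # rad, signed


def resample_path(path: np.ndarray, n_points: int) -> np.ndarray:
    """Resample a polyline to ``n_points`` by linear interpolation in
    normalized frame time."""
    path = np.asarray(path, dtype=float)
    t_old = np.linspace(0.0, 1.0, len(path))
    t_new = np.linspace(0.0, 1.0, n_points)
    return np.column_stack(
        [np.interp(t_new, t_old, path[:, k]) for k in range(2)]
    )


def _onset_rotation(path: np.ndarray) -> np.ndarray | None:
    """Rotation matrix aligning the onset heading with +x.

    Heading is the displacement over the first two frames; if that is zero
    the first nonzero displacement is used; an entirely stationary instance
    keeps its original orientation.
    """
    deltas = np.diff(path, axis=0)
    norms = np.linalg.norm(deltas, axis=1)
    nz = np.flatnonzero(norms > 1e-9)
    if nz.size == 0:
        return None
    v = deltas[nz[0]] / norms[nz[0]]
    return np.array([[v[0], v[1]], [-v[1], v[0]]])


def egocentric_instances(
    bouts: list[Bout], track: CentroidTrack, n_points: int = DEFAULT_RESAMPLE_POINTS
) -> list[np.ndarray]:
    """Aligned, resampled per-instance paths for the given bouts."""
    out = []
    for b in bouts:
        seg = track.positions[b.start : b.end]
        if len(seg) < 2 or not np.isfinite(seg).all():
            continue
        seg = seg - seg[0]
        rot = _onset_rotation(seg)
        if rot is not None:
            seg = seg @ rot.T
        out.append(resample_path(seg, n_points))
    return out


def egocentric_mean_trajectory(
    syllable: int,
    bouts: list[Bout],
    track: CentroidTrack | list[np.ndarray],
    n_points: int = DEFAULT_RESAMPLE_POINTS,
) -> SyllableTrajectory:
    """Mean egocentric trajectory and movement metrics for one syllable.

    ``track`` may also be a pre-computed list of aligned instance paths
    (used when pooling instances across recordings).
    """
    if isinstance(track, CentroidTrack):
        instances = egocentric_instances(bouts, track, n_points)
    else:
        instances = track
    if not instances:
        raise FormatError(f"syllable {syllable}: no usable instances")
    stack = np.stack(instances)
    mean_path = stack.mean(axis=0)
    mean_path = mean_path - mean_path[0]
    net, plen, turn = movement_metrics(stack)
    return SyllableTrajectory(
        syllable=syllable,
        mean_path=mean_path,
        n_instances=len(instances),
        net_displacement=net,
        path_length=plen,
        net_heading_change=turn,
    )


def movement_metrics(stack: np.ndarray) -> tuple[float, float, float]:
    """Mean (net displacement, path length, net heading change) over an
    (n_instances, L, 2) stack of aligned paths."""
    net = float(np.linalg.norm(stack[:, -1] - stack[:, 0], axis=1).mean())
    deltas = np.diff(stack, axis=1)
    plen = float(np.linalg.norm(deltas, axis=2).sum(axis=1).mean())
    first = deltas[:, 0]
    last = deltas[:, -1]
    cross = first[:, 0] * last[:, 1] - first[:, 1] * last[:, 0]
    dot = (first * last).sum(axis=1)
    ok = (np.linalg.norm(first, axis=1) > 1e-9) & (
        np.linalg.norm(last, axis=1) > 1e-9
    )
    turn = float(np.arctan2(cross[ok], dot[ok]).mean()) if ok.any() else 0.0
    return net, plen, turn


def cosine_distance(u: np.ndarray, v: np.ndarray) -> float:
    """1 - cos(u, v); lies in [0, 2].  Errors on a zero vector."""
    u = np.asarray(u, dtype=float).ravel()
    v = np.asarray(v, dtype=float).ravel()
    if u.shape != v.shape:
        raise FormatError("vectors must have equal length")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise FormatError("cosine distance undefined for a zero vector")
    return float(np.clip(1.0 - (u @ v) / (nu * nv), 0.0, 2.0))


def similarity_dendrogram(
    trajectories: list[SyllableTrajectory],
) -> tuple[np.ndarray, np.ndarray, str]:
    """Pairwise cosine-distance matrix, average-linkage tree and Newick.

    Returns ``(distance_matrix, linkage_matrix, newick)`` with leaves named
    by syllable id.
    """
    if len(trajectories) < 2:
        raise FormatError("need at least 2 syllables for a dendrogram")
    vecs = [t.mean_path.ravel() for t in trajectories]
    n = len(vecs)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = cosine_distance(vecs[i], vecs[j])
    if not np.isfinite(dist).all():
        bad = np.argwhere(~np.isfinite(dist))[0]
        raise FormatError(
            f"non-finite distance between syllables "
            f"{trajectories[bad[0]].syllable} and {trajectories[bad[1]].syllable}"
        )
    link = linkage(squareform(dist, checks=False), method="average")
    from skbio import TreeNode

    tree = TreeNode.from_linkage_matrix(
        link, [str(t.syllable) for t in trajectories]
    )
    newick = str(tree).strip()
    return dist, link, newick


def movement_class_test(
    trajectories: list[SyllableTrajectory],
    dm: list[int],
    alpha: float = 0.05,
    heading_alternative: str = "two-sided",
) -> dict:
    """DM-vs-DU contrast on movement metrics.

    One-sided Mann-Whitney U per metric (net displacement and path length:
    DM expected lower; absolute net heading change: direction configurable),
    Bonferroni-corrected across the metrics.
    """
    dm_set = set(dm)
    dm_traj = [t for t in trajectories if t.syllable in dm_set]
    du_traj = [t for t in trajectories if t.syllable not in dm_set]
    if not dm_traj or not du_traj:
        raise FormatError("both DM and DU groups must be non-empty")
    metrics = {
        "net_displacement": (
            [t.net_displacement for t in dm_traj],
            [t.net_displacement for t in du_traj],
            "less",
        ),
        "path_length": (
            [t.path_length for t in dm_traj],
            [t.path_length for t in du_traj],
            "less",
        ),
        "abs_heading_change": (
            [abs(t.net_heading_change) for t in dm_traj],
            [abs(t.net_heading_change) for t in du_traj],
            heading_alternative,
        ),
    }
    results: dict[str, TestResult] = {}
    for name, (a, b, alt) in metrics.items():
        res, _ = _mwu_family(
            np.asarray(a)[:, None],
            np.asarray(b)[:, None],
            [0],
            alpha / len(metrics),
            "bonferroni",
            alternative=alt,
        )
        if res:
            r = res[0]
            # Bonferroni across the metric family, not within
            p_adj = min(r.p_raw * len(metrics), 1.0)
            results[name] = TestResult(
                statistic=r.statistic,
                p_raw=r.p_raw,
                p_adjusted=p_adj,
                method="mann_whitney_u",
                correction="bonferroni",
                significant=p_adj < alpha,
                name=name,
            )
    return results
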