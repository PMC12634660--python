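"""Bout-transition networks, eigenvector centrality and context contrasts.

The transition network of one animal-recording is the row-normalized matrix
of bout-to-bout transition counts (structurally zero diagonal, since
adjacent bouts always differ).  Node influence is scored with the dominant
LEFT eigenvector of the transition matrix — incoming influence, i.e. how
strongly a syllable is fed by syllables that are themselves strongly fed —
computed by power iteration and L1-normalized.  For a strongly connected
row-stochastic matrix this coincides with the stationary bout distribution,
which is asserted on every computed vector.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from statsmodels.stats.multitest import multipletests

from .io_core import Bout, FormatError, TestResult
from .syllables import _mwu_family

__all__ = [
    "TransitionNetwork",
    "CentralityVector",
    "transition_matrix",
    "eigenvector_centrality",
    "centrality_context_test",
    "transition_modulation",
    "to_graphml",
]


@dataclass
class TransitionNetwork:
    counts: np.ndarray
    probabilities: np.ndarray
    animal_id: str = ""
    context: str = ""
    empty_rows: np.ndarray = field(default_factory=lambda: np.zeros(0, bool))


@dataclass
class CentralityVector:
    c: np.ndarray
    iterations: int
    tolerance: float
    restricted_to_scc: bool = False


def transition_matrix(
    bouts: list[Bout],
    n_syllables: int,
    animal_id: str = "",
    context: str = "",
) -> TransitionNetwork:
    """Count and row-normalize transitions between frame-adjacent bouts.

    Bout pairs separated by a missing-label gap are not counted.
    """
    if len(bouts) < 2:
        raise FormatError("need at least 2 bouts for a transition matrix")
    counts = np.zeros((n_syllables, n_syllables))
    labs = np.array([b.syllable for b in bouts])
    starts = np.array([b.start for b in bouts])
    ends = np.array([b.end for b in bouts])
    adjacent = ends[:-1] == starts[1:]
    np.add.at(counts, (labs[:-1][adjacent], labs[1:][adjacent]), 1.0)
    row_sums = counts.sum(axis=1)
    empty = row_sums == 0
    probs = np.zeros_like(counts)
    probs[~empty] = counts[~empty] / row_sums[~empty, None]
    return TransitionNetwork(counts, probs, animal_id, context, empty)


def _largest_scc(matrix: np.ndarray) -> np.ndarray:
    support = csr_matrix(matrix > 0)
    n_comp, labels = connected_components(
        support, directed=True, connection="strong"
    )
    if n_comp == 1:
        return np.ones(matrix.shape[0], dtype=bool)
    sizes = np.bincount(labels)
    return labels == np.argmax(sizes)


def eigenvector_centrality(
    net: TransitionNetwork | np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 100_000,
    orientation: str = "incoming",
) -> CentralityVector:
    """Dominant eigenvector centrality of the transition network.

    ``orientation="incoming"`` (default) uses the left eigenvector of P;
    ``"outgoing"`` the right one.  If the support graph is not strongly
    connected, the computation is restricted to the largest strongly
    connected component, zeros elsewhere, with a warning.  Power iteration
    uses the lazy update ``v <- (v + vP) / 2``, which shares fixed points
    with P but converges for periodic chains too.
    """
    P = net.probabilities if isinstance(net, TransitionNetwork) else np.asarray(net, float)
    if (P < 0).any():
        raise FormatError("transition matrix must be non-negative")
    n = P.shape[0]
    if orientation == "outgoing":
        P = P.T
    elif orientation != "incoming":
        raise ValueError(f"unknown orientation {orientation!r}")
    keep = _largest_scc(P)
    restricted = not keep.all()
    if restricted:
        warnings.warn(
            "transition network is not strongly connected; centrality "
            f"restricted to the largest component ({keep.sum()}/{n} nodes)",
            stacklevel=2,
        )
    sub = P[np.ix_(keep, keep)]
    row_sums = sub.sum(axis=1, keepdims=True)
    row_sums[row_sums == 0] = 1.0
    sub = sub / row_sums
    m = sub.shape[0]
    v = np.full(m, 1.0 / m)
    for it in range(1, max_iter + 1):
        nxt = 0.5 * (v + v @ sub)
        nxt /= nxt.sum()
        if np.abs(nxt - v).max() < tol:
            v = nxt
            break
        v = nxt
    else:
        gap = _spectral_gap(sub)
        raise FormatError(
            f"centrality power iteration did not converge in {max_iter} "
            f"iterations (spectral gap ~{gap:.2e})"
        )
    # stationarity check: for a stochastic matrix the left dominant
    # eigenvector is the stationary distribution
    if np.abs(v @ sub - v).max() > 1e-8:
        raise FormatError("centrality vector failed the stationarity check")
    c = np.zeros(n)
    c[keep] = v
    return CentralityVector(c=c, iterations=it, tolerance=tol,
                            restricted_to_scc=restricted)


def _spectral_gap(P: np.ndarray) -> float:
    vals = np.sort(np.abs(np.linalg.eigvals(P)))[::-1]
    return float(vals[0] - vals[1]) if len(vals) > 1 else float("inf")


def centrality_context_test(
    solitary: np.ndarray,
    dyadic: np.ndarray,
    alpha: float = 0.05,
) -> dict:
    """Per-syllable two-sided Mann-Whitney U on per-animal centralities
    across contexts, Bonferroni-corrected over syllables.

    ``solitary`` and ``dyadic`` are (n_animals, n_syllables) arrays.
    """
    if solitary.shape[0] < 2 or dyadic.shape[0] < 2:
        raise FormatError("need at least 2 animals per context")
    names = list(range(solitary.shape[1]))
    results, skipped = _mwu_family(
        solitary, dyadic, names, alpha, "bonferroni"
    )
    return {
        "tests": results,
        "significant": sorted(int(r.name) for r in results if r.significant),
        "skipped": skipped,
    }


def transition_modulation(
    networks_solitary: list[TransitionNetwork],
    networks_dyadic: list[TransitionNetwork],
    dm: list[int],
    alpha: float = 0.05,
    min_count: int = 10,
) -> dict:
    """Per-edge context contrast of transition probabilities.

    The edge universe is restricted to edges whose pooled transition count
    reaches ``min_count`` (an unrestricted family over all n*(n-1) edges
    would make the Bonferroni correction vacuous).  Each edge is tested
    with a two-sided Mann-Whitney U on per-animal probabilities; the output
    reports the probability change, significance and whether the edge
    targets a DM syllable.
    """
    pooled = sum(net.counts for net in networks_solitary + networks_dyadic)
    edges = [
        (int(i), int(j))
        for i, j in np.argwhere(pooled >= min_count)
        if i != j
    ]
    if not edges:
        raise FormatError("edge universe empty; lower min_count")
    sol = np.array(
        [[net.probabilities[i, j] for i, j in edges] for net in networks_solitary]
    )
    dya = np.array(
        [[net.probabilities[i, j] for i, j in edges] for net in networks_dyadic]
    )
    results, skipped_idx = _mwu_family(
        sol, dya, list(range(len(edges))), alpha, "bonferroni"
    )
    dm_set = set(dm)
    table = []
    for r in results:
        i, j = edges[int(r.name)]
        table.append(
            {
                "source": i,
                "target": j,
                "delta_probability": float(dya[:, int(r.name)].mean()
                                           - sol[:, int(r.name)].mean()),
                "p_raw": r.p_raw,
                "p_adjusted": r.p_adjusted,
                "significant": r.significant,
                "targets_dm": j in dm_set,
            }
        )
    sig = [e for e in table if e["significant"]]
    frac = (
        sum(e["targets_dm"] for e in sig) / len(sig) if sig else float("nan")
    )
    return {
        "edges": table,
        "significant": sig,
        "targets_dm_fraction": frac,
        "n_tested": len(results),
    }


def to_graphml(
    path,
    edge_table: list[dict],
    delta_centrality: np.ndarray,
    significant_nodes: list[int],
) -> None:
    """Export the modulation network with edge sign/weight and node
    centrality-change attributes."""
    import networkx as nx

    g = nx.DiGraph()
    for node, dc in enumerate(delta_centrality):
        g.add_node(
            node,
            delta_centrality=float(dc),
            significant=bool(node in significant_nodes),
        )
    for e in edge_table:
        g.add_edge(
            e["source"],
            e["target"],
            delta_probability=e["delta_probability"],
            sign="positive" if e["delta_probability"] > 0 else "negative",
            significant=bool(e["significant"]),
        )
    nx.write_graphml(g, path)
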