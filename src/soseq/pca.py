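"""PCA of per-track syllable and syntax usage, DM-vs-DU loading contrasts
and context separation.

The feature matrix has one row per animal-recording (a "track") and one
column per syllable frame proportion (or per syntax onset proportion for
the syntax variant).  Features are centered but, by default, not scaled —
proportions already share a scale.  The contrast asks whether the
dyadic-modulated syllables carry larger absolute loadings on the leading
components than the unmodulated ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_core import FormatError, TestResult
from .syllables import _mwu_family

__all__ = [
    "PcaResult",
    "pca_features",
    "loading_contrast",
    "context_separation",
    "dm_syntax_features",
]


@dataclass
class PcaResult:
    loadings: np.ndarray           # (n_features, n_components), unit columns
    variance_ratio: np.ndarray
    scores: np.ndarray             # (n_tracks, n_components)
    mean: np.ndarray
    feature_names: list


def pca_features(
    features: pd.DataFrame | np.ndarray,
    center: bool = True,
    scale: bool = False,
) -> PcaResult:
    """Principal components via singular-value decomposition.

    Uses a deterministic sign convention: within each component the entry
    of largest absolute loading is positive.
    """
    if isinstance(features, pd.DataFrame):
        names = list(features.columns)
        X = features.to_numpy(dtype=float)
    else:
        X = np.asarray(features, dtype=float)
        names = list(range(X.shape[1]))
    if X.shape[0] < 3:
        raise FormatError("need at least 3 tracks for PCA")
    mean = X.mean(axis=0) if center else np.zeros(X.shape[1])
    Xc = X - mean
    if scale:
        sd = Xc.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        Xc = Xc / sd
    total_var = (Xc**2).sum() / (X.shape[0] - 1)
    if total_var == 0:
        raise FormatError("feature matrix has zero variance")
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    rank = int((S > S[0] * 1e-12).sum())
    U, S, Vt = U[:, :rank], S[:rank], Vt[:rank]
    # sign convention
    for k in range(rank):
        j = np.argmax(np.abs(Vt[k]))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    var = S**2 / (X.shape[0] - 1)
    return PcaResult(
        loadings=Vt.T,
        variance_ratio=var / total_var,
        scores=U * S,
        mean=mean,
        feature_names=names,
    )


def loading_contrast(
    result: PcaResult,
    dm_features: list,
    n_components: int = 5,
    alpha: float = 0.05,
) -> dict:
    """One-sided Mann-Whitney U on |loadings| of DM vs DU features per
    component, Bonferroni-corrected across the tested components."""
    dm_set = set(dm_features)
    is_dm = np.array([f in dm_set for f in result.feature_names])
    if not is_dm.any() or is_dm.all():
        raise FormatError("both feature partitions must be non-empty")
    k = min(n_components, result.loadings.shape[1])
    abs_load = np.abs(result.loadings[:, :k])
    results, _ = _mwu_family(
        abs_load[is_dm],
        abs_load[~is_dm],
        list(range(k)),
        alpha,
        "bonferroni",
        alternative="greater",
    )
    return {
        "tests": results,
        "significant": sorted(int(r.name) for r in results if r.significant),
        "variance_explained": float(result.variance_ratio[:k].sum()),
    }


def context_separation(
    scores: np.ndarray, groups: np.ndarray, n_components: int = 2
) -> float:
    """Silhouette of a grouping in the leading score space.

    Quantifies the visual separation of e.g. solitary vs dyadic tracks (or
    light-cycle groups) on the first components; near 0 means no
    separation.
    """
    from sklearn.metrics import silhouette_score

    groups = np.asarray(groups)
    uniq, counts = np.unique(groups, return_counts=True)
    if len(uniq) < 2 or counts.min() < 2:
        raise FormatError("every group needs at least 2 tracks")
    pts = scores[:, : min(n_components, scores.shape[1])]
    return float(silhouette_score(pts, groups))


def dm_syntax_features(
    syntax_columns: list[tuple[int, ...]], dm: list[int]
) -> list[tuple[int, ...]]:
    """Syntaxes counted as dyadic-modulated: triples containing at least
    two DM syllables."""
    dm_set = set(dm)
    return [
        s for s in syntax_columns if sum(x in dm_set for x in s) >= 2
    ]
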