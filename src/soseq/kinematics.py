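"""Inter-mouse distance controls, (IMD, CID) behavior classes, class-syntax
association and the class-wise composition divergence matrix.

Social behaviors are parameterized by the inter-mouse distance at the start
of a length-3 syntax (x, mm) and the change of that distance by its end
(y, mm).  The plane splits at the 100 mm contact threshold into four
classes — contact (x < 100, x + y < 100), approach (x > 100, x + y < 100),
leave (x < 100, x + y > 100) and far-stationary (x > 100, x + y > 100) —
plus two control classes matching the distance change while excluding
contact: approach-control (y < 0, x + y > 100) and leave-control
(y > 0, x > 100).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import CentroidTrack, FormatError, TestResult
from .composition import dkl
from .syntax import SyntaxFamily, SyntaxOccurrence

logger = logging.getLogger("soseq")

__all__ = [
    "BehaviorClassConfig",
    "KinematicPoint",
    "imd_series",
    "imd_controls",
    "classify",
    "classify_points",
    "syntax_kinematics",
    "class_family_association",
    "class_dkl_matrix",
    "position_kde",
]

PRIMARY_CLASSES = ("contact", "approach", "leave", "far_stationary")
CONTROL_CLASSES = ("approach_control", "leave_control")


@dataclass
class BehaviorClassConfig:
    contact_mm: float = 100.0


@dataclass(frozen=True)
class KinematicPoint:
    x: float   # IMD at syntax start, mm
    y: float   # CID over the syntax, mm
    occurrence: SyntaxOccurrence | None = None


def imd_series(track_a: CentroidTrack | np.ndarray,
               track_b: CentroidTrack | np.ndarray) -> np.ndarray:
    """Frame-wise Euclidean inter-mouse distance in mm."""
    pa = track_a.positions if isinstance(track_a, CentroidTrack) else np.asarray(track_a)
    pb = track_b.positions if isinstance(track_b, CentroidTrack) else np.asarray(track_b)
    if pa.shape != pb.shape:
        raise FormatError("paired tracks must have equal length")
    return np.linalg.norm(pa - pb, axis=1)


def imd_controls(
    tracks_a: list[np.ndarray],
    tracks_b: list[np.ndarray],
    arena_mm: float = 453.0,
    n_pairs: int = 100_000,
    seed: int = 0,
    bins: np.ndarray | None = None,
) -> dict:
    """Observed, shuffled and random inter-mouse-distance histograms.

    ``shuffled`` pairs independently permuted position samples of the two
    animals (destroying temporal coordination while keeping the marginal
    occupancy); ``random`` pairs uniform points in the arena.  All three
    share one binning; the observed-minus-shuffled difference is included.
    """
    rng = np.random.default_rng(seed)
    obs = np.concatenate(
        [imd_series(a, b) for a, b in zip(tracks_a, tracks_b)]
    )
    pos_a = np.concatenate(tracks_a)
    pos_b = np.concatenate(tracks_b)
    ia = rng.permutation(len(pos_a))[:n_pairs]
    ib = rng.permutation(len(pos_b))[:n_pairs]
    m = min(len(ia), len(ib))
    shuffled = np.linalg.norm(pos_a[ia[:m]] - pos_b[ib[:m]], axis=1)
    random = np.linalg.norm(
        rng.uniform(0, arena_mm, size=(n_pairs, 2))
        - rng.uniform(0, arena_mm, size=(n_pairs, 2)),
        axis=1,
    )
    if bins is None:
        bins = np.linspace(0, arena_mm * np.sqrt(2), 65)
    h_obs, _ = np.histogram(obs, bins=bins, density=True)
    h_shuf, _ = np.histogram(shuffled, bins=bins, density=True)
    h_rand, _ = np.histogram(random, bins=bins, density=True)
    return {
        "bins": bins,
        "observed": h_obs,
        "shuffled": h_shuf,
        "random": h_rand,
        "difference": h_obs - h_shuf,
        "means": {
            "observed": float(obs.mean()),
            "shuffled": float(shuffled.mean()),
            "random": float(random.mean()),
        },
    }


def classify(point: KinematicPoint | tuple[float, float],
             cfg: BehaviorClassConfig | None = None) -> str:
    """Assign one (IMD, CID) point to a primary behavior class.

    Boundary ties (equality with the threshold) go to the stationary
    classes (contact / far_stationary) and are counted in a debug log.
    """
    cfg = cfg or BehaviorClassConfig()
    x, y = (point.x, point.y) if isinstance(point, KinematicPoint) else point
    if not np.isfinite(x) or not np.isfinite(y):
        raise FormatError("kinematic point must be finite")
    if x < 0:
        raise FormatError(f"inter-mouse distance {x} cannot be negative")
    c = cfg.contact_mm
    closing = x + y < c
    opening = x + y > c
    if not closing and not opening:  # x + y == c: tie -> stationary side
        logger.debug("boundary kinematic point (%s, %s)", x, y)
        return "contact" if x < c else "far_stationary"
    if x == c:  # tie -> stationary side
        logger.debug("boundary kinematic point (%s, %s)", x, y)
        return "contact" if closing else "far_stationary"
    if x < c:
        return "contact" if closing else "leave"
    return "approach" if closing else "far_stationary"


def classify_points(
    x: np.ndarray, y: np.ndarray, cfg: BehaviorClassConfig | None = None
) -> np.ndarray:
    """Vectorized :func:`classify` over arrays."""
    cfg = cfg or BehaviorClassConfig()
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if (x < 0).any():
        raise FormatError("inter-mouse distance cannot be negative")
    c = cfg.contact_mm
    near = x < c
    closing = (x + y) < c
    out = np.where(
        near & closing,
        "contact",
        np.where(
            ~near & closing,
            "approach",
            np.where(near & ~closing, "leave", "far_stationary"),
        ),
    )
    # boundary ties (measure zero) go to the stationary classes
    tie_xy = (x + y) == c
    out[tie_xy & near] = "contact"
    out[tie_xy & ~near] = "far_stationary"
    tie_x = (x == c) & ~tie_xy
    out[tie_x & closing] = "contact"
    out[tie_x & ~closing] = "far_stationary"
    return out


def in_control_class(x: np.ndarray, y: np.ndarray, name: str,
                     cfg: BehaviorClassConfig | None = None) -> np.ndarray:
    cfg = cfg or BehaviorClassConfig()
    c = cfg.contact_mm
    if name == "approach_control":
        return (y < 0) & (x + y > c)
    if name == "leave_control":
        return (y > 0) & (x > c)
    raise ValueError(f"unknown control class {name!r}")


def syntax_kinematics(
    occurrences: list[SyntaxOccurrence], imd: np.ndarray
) -> list[KinematicPoint]:
    """(IMD at start, CID over the occurrence) per syntax occurrence."""
    pts = []
    for occ in occurrences:
        if occ.end > imd.size:
            continue
        x = float(imd[occ.start])
        y = float(imd[occ.end - 1] - imd[occ.start])
        if np.isfinite(x) and np.isfinite(y):
            pts.append(KinematicPoint(x, y, occ))
    return pts


def class_family_association(
    labels: np.ndarray,
    family_flags: dict[tuple[int, ...], np.ndarray],
    alpha: float = 0.05,
) -> dict:
    """Chi-squared contingency of syntax family membership vs behavior class.

    Each family is tested (member vs non-member x class) with Bonferroni
    correction across families; per-cell standardized residuals of the full
    family-by-class table summarize the effect direction.
    """
    labels = np.asarray(labels)
    classes = [c for c in PRIMARY_CLASSES if (labels == c).any()]
    if len(classes) < 2 or len(family_flags) < 2:
        raise FormatError("need >= 2 classes and >= 2 families with counts")
    tests = []
    p_raw = []
    for ref, member in family_flags.items():
        table = np.array(
            [
                [(member & (labels == c)).sum() for c in classes],
                [(~member & (labels == c)).sum() for c in classes],
            ]
        )
        if (table.sum(axis=1) == 0).any():
            raise FormatError(f"degenerate table for family {ref}")
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        tests.append((ref, float(chi2), float(p)))
        p_raw.append(p)
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method="bonferroni")
    results = [
        TestResult(
            statistic=chi2,
            p_raw=p,
            p_adjusted=float(q),
            method="chi2_contingency",
            correction="bonferroni",
            significant=bool(r),
            name=str(ref),
        )
        for (ref, chi2, p), q, r in zip(tests, p_adj, reject)
    ]

    full = np.array(
        [
            [(member & (labels == c)).sum() for c in classes]
            for member in family_flags.values()
        ],
        dtype=float,
    )
    expected = (
        full.sum(axis=1, keepdims=True)
        * full.sum(axis=0, keepdims=True)
        / full.sum()
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        residuals = (full - expected) / np.sqrt(expected)
    return {
        "tests": results,
        "classes": classes,
        "table": pd.DataFrame(
            full, index=[str(k) for k in family_flags], columns=classes
        ),
        "residuals": pd.DataFrame(
            residuals, index=[str(k) for k in family_flags], columns=classes
        ),
    }


def class_dkl_matrix(
    labels: np.ndarray,
    points: list[KinematicPoint],
    n_syllables: int,
    pseudocount: float = 1e-6,
) -> pd.DataFrame:
    """Pairwise D_KL between per-class syllable compositions.

    Per class, the syllable identities inside member syntaxes are pooled
    into a distribution; entry (row, col) is D_KL(row || col).  Classes
    without occurrences give masked (NaN) rows/columns with a warning.
    """
    labels = np.asarray(labels)
    comps = {}
    for c in PRIMARY_CLASSES:
        counts = np.zeros(n_syllables)
        for lab, pt in zip(labels, points):
            if lab == c and pt.occurrence is not None:
                for s in pt.occurrence.triple:
                    counts[s] += 1
        if counts.sum() == 0:
            logger.warning("behavior class %s has no occurrences; masked", c)
            comps[c] = None
        else:
            comps[c] = counts / counts.sum()
    mat = np.full((len(PRIMARY_CLASSES), len(PRIMARY_CLASSES)), np.nan)
    for i, a in enumerate(PRIMARY_CLASSES):
        for j, b in enumerate(PRIMARY_CLASSES):
            if comps[a] is not None and comps[b] is not None:
                mat[i, j] = (
                    0.0 if i == j else dkl(comps[a], comps[b], pseudocount)
                )
    return pd.DataFrame(mat, index=PRIMARY_CLASSES, columns=PRIMARY_CLASSES)


def position_kde(
    positions: np.ndarray,
    arena_mm: float = 453.0,
    grid_size: int = 64,
    corner_mm: float = 100.0,
) -> dict:
    """Gaussian kernel density of arena positions (Scott's rule bandwidth).

    Returns the normalized density grid, per-axis marginals and the
    corner-occupancy fraction (positions within ``corner_mm`` of a corner).
    """
    positions = np.asarray(positions, float)
    positions = positions[np.isfinite(positions).all(axis=1)]
    if positions.shape[0] < 100:
        raise FormatError("need at least 100 positions for a density estimate")
    kde = stats.gaussian_kde(positions.T, bw_method="scott")
    axis = np.linspace(0, arena_mm, grid_size)
    xx, yy = np.meshgrid(axis, axis, indexing="ij")
    dens = kde(np.vstack([xx.ravel(), yy.ravel()])).reshape(grid_size, grid_size)
    cell = (axis[1] - axis[0]) ** 2
    corners = np.array(
        [[0, 0], [arena_mm, 0], [0, arena_mm], [arena_mm, arena_mm]]
    )
    dists = np.linalg.norm(
        positions[:, None, :] - corners[None, :, :], axis=2
    )
    corner_frac = float((dists.min(axis=1) < corner_mm).mean())
    return {
        "grid": axis,
        "density": dens,
        "integral": float(dens.sum() * cell),
        "marginal_x": dens.sum(axis=1) * (axis[1] - axis[0]),
        "marginal_y": dens.sum(axis=0) * (axis[1] - axis[0]),
        "corner_occupancy": corner_frac,
    }
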