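"""Length-3 syntaxes, Hamming families and event-aligned syntax dynamics.

A syntax is an ordered triple of consecutive bout labels (~1 s of behavior
at the 10-frame median bout length).  A syntax family collects all triples
within Hamming distance <= 1 of a reference triple — position-wise
substitutions only, no rearrangements — e.g. (9,0,10) belongs to the
(9,0,5) family while (0,5,10) does not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .io_core import (
    AnalysisConfig,
    AnnotationBout,
    Bout,
    Dataset,
    FormatError,
)
from .composition import qualifying_bouts
from .syllables import extract_bouts

__all__ = [
    "SyntaxOccurrence",
    "SyntaxFamily",
    "extract_syntaxes",
    "hamming",
    "zscore_timecourse",
    "family_occupancy",
    "rolling_relation",
    "SyntaxTimeCourse",
]


@dataclass(frozen=True)
class SyntaxOccurrence:
    triple: tuple[int, ...]
    start: int    # first frame of the first bout
    end: int      # end frame of the last bout (exclusive)


def extract_syntaxes(bouts: list[Bout], k: int = 3) -> list[SyntaxOccurrence]:
    """Overlapping sliding window (stride 1) over the bout sequence.

    Windows interrupted by a missing-label gap (non-adjacent bouts) are
    dropped.
    """
    if len(bouts) < k:
        raise FormatError(f"need at least {k} bouts to extract syntaxes")
    out = []
    for i in range(len(bouts) - k + 1):
        win = bouts[i : i + k]
        if all(win[j].end == win[j + 1].start for j in range(k - 1)):
            out.append(
                SyntaxOccurrence(
                    tuple(b.syllable for b in win), win[0].start, win[-1].end
                )
            )
    return out


def hamming(a: Sequence[int], b: Sequence[int]) -> int:
    """Number of differing positions (substitutions only)."""
    if len(a) != len(b):
        raise FormatError("sequences must have equal length")
    return int(sum(x != y for x, y in zip(a, b)))


@dataclass(frozen=True)
class SyntaxFamily:
    """All triples within Hamming distance <= 1 of the reference."""

    reference: tuple[int, ...]

    def is_member(self, triple: Sequence[int]) -> bool:
        return len(triple) == len(self.reference) and hamming(
            self.reference, triple
        ) <= 1

    def max_size(self, n_syllables: int) -> int:
        return 1 + len(self.reference) * (n_syllables - 1)


# ---------------------------------------------------------------------------
# event-aligned syntax frequencies
# ---------------------------------------------------------------------------


@dataclass
class SyntaxTimeCourse:
    """Onset-aligned per-syntax frequency z-scores.

    ``frequency[s][t]`` is the per-onset frequency of syntax ``s`` among
    all syntax onsets at offset bin ``t``; z-scores are taken against the
    mean and standard deviation over the baseline window bins, with a
    resolution floor of one onset on the standard deviation so that rare
    syntaxes remain rankable.
    """

    offsets: np.ndarray
    syntaxes: list[tuple[int, ...]]
    frequency: np.ndarray          # (n_syntaxes, n_offsets)
    z: np.ndarray
    onsets_per_bin: np.ndarray
    baseline_window: tuple[int, int]
    significant: np.ndarray        # boolean, same shape as z
    ranking: list[tuple[int, ...]]  # by peak post-onset z, descending
    n_bouts: int


def zscore_timecourse(
    dataset: Dataset,
    contact_type: str = "active",
    cfg: AnalysisConfig | None = None,
    baseline_frames: tuple[int, int] = (-3, -1),
    min_total: int = 5,
    top_k: int = 4,
) -> SyntaxTimeCourse:
    """Syntax onset frequencies aligned to scored contact onsets.

    For every qualifying contact bout and both animals of the recording,
    syntax occurrences whose first frame falls inside the aligned window
    contribute an onset at their offset bin.  Frequencies are per onset
    (they sum to 1 over syntaxes within a bin), z-scored against the
    baseline window, and tested at |z| with Benjamini-Hochberg correction
    across (syntax, bin) pairs.
    """
    cfg = cfg or dataset.config
    pre = cfg.pre_contact_window_frames
    post = cfg.post_contact_window_frames
    offsets = np.arange(-pre, post + 1)
    t0 = pre  # index of offset 0

    counts: dict[tuple[int, ...], np.ndarray] = {}
    total = np.zeros(offsets.size)
    n_rows = 0
    for rec in dataset.by_context("dyadic"):
        if not rec.annotations:
            continue
        n_frames = min(s.n_frames for s in rec.sequences.values())
        quals = qualifying_bouts(rec.annotations, contact_type, n_frames, pre, post)
        if not quals:
            continue
        for seq in rec.sequences.values():
            occs = extract_syntaxes(extract_bouts(seq), cfg.syntax_length)
            starts = np.array([o.start for o in occs])
            for b in quals:
                n_rows += 1
                lo = np.searchsorted(starts, b.start - pre)
                hi = np.searchsorted(starts, b.start + post + 1)
                for o in occs[lo:hi]:
                    t = o.start - b.start + t0
                    if 0 <= t < offsets.size:
                        counts.setdefault(
                            o.triple, np.zeros(offsets.size)
                        )[t] += 1
                        total[t] += 1
    if n_rows == 0:
        raise FormatError(f"no qualifying {contact_type} contact bouts")

    keep = {s: c for s, c in counts.items() if c.sum() >= min_total}
    if not keep:
        raise FormatError("no syntax reaches the minimum occurrence count")
    syntaxes = sorted(keep, key=lambda s: -keep[s].sum())
    mat = np.stack([keep[s] for s in syntaxes])
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(total[None, :] > 0, mat / total[None, :], np.nan)

    b_lo, b_hi = baseline_frames
    base_sel = (offsets >= b_lo) & (offsets <= b_hi)
    if not base_sel.any():
        raise FormatError("baseline window outside the aligned range")
    base = np.nan_to_num(freq[:, base_sel])
    mu = base.mean(axis=1)
    sigma = base.std(axis=1, ddof=0)
    floor = 1.0 / max(np.median(total[total > 0]), 1.0)
    sigma_eff = np.maximum(sigma, floor)
    z = (np.nan_to_num(freq) - mu[:, None]) / sigma_eff[:, None]

    p = 2.0 * norm.sf(np.abs(z))
    flat = p.ravel()
    reject, _, _, _ = multipletests(flat, alpha=cfg.alpha, method="fdr_bh")
    significant = reject.reshape(p.shape)

    post_sel = offsets >= 0
    peaks = z[:, post_sel].max(axis=1)
    order = np.argsort(-peaks, kind="stable")
    ranking = [syntaxes[i] for i in order[:top_k]]
    return SyntaxTimeCourse(
        offsets=offsets,
        syntaxes=syntaxes,
        frequency=freq,
        z=z,
        onsets_per_bin=total,
        baseline_window=baseline_frames,
        significant=significant,
        ranking=ranking,
        n_bouts=n_rows,
    )


# ---------------------------------------------------------------------------
# families and the distance/occupancy relation
# ---------------------------------------------------------------------------


def family_occupancy(
    occurrences: list[SyntaxOccurrence],
    families: Sequence[SyntaxFamily],
    n_frames: int,
) -> dict[tuple[int, ...], np.ndarray]:
    """Per-frame boolean occupancy per family: a frame belongs to a family
    iff it lies within the span of any member occurrence."""
    out = {}
    for fam in families:
        mask = np.zeros(n_frames, dtype=bool)
        for occ in occurrences:
            if fam.is_member(occ.triple):
                mask[occ.start : min(occ.end, n_frames)] = True
        out[fam.reference] = mask
    return out


def rolling_relation(
    imd: np.ndarray,
    occupancy: np.ndarray,
    window: int = 30,
    bin_width: float = 100.0,
    seed: int = 0,
) -> dict:
    """Change in inter-mouse distance vs family occupancy per rolling window.

    For every window of ``window`` frames: CID = IMD(end) - IMD(start) and
    the fraction of window frames spent inside the family.  Returns the raw
    per-window pairs and a binned summary (median occupancy with a
    bootstrap 95% CI per CID bin).
    """
    imd = np.asarray(imd, dtype=float)
    occupancy = np.asarray(occupancy, dtype=bool)
    if imd.size != occupancy.size:
        raise FormatError("imd and occupancy must have equal length")
    if window >= imd.size:
        raise FormatError("window longer than the recording")
    # window starting at t spans frames [t, t + window)
    cid = imd[window - 1 :] - imd[: -(window - 1)] if window > 1 else np.zeros_like(imd)
    csum = np.concatenate(([0], np.cumsum(occupancy)))
    frac = (csum[window:] - csum[:-window]) / window
    cid = cid[: frac.size]
    df = pd.DataFrame({"cid": cid, "occupancy": frac})

    lo = np.floor(cid.min() / bin_width) * bin_width
    hi = np.ceil(cid.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    rng = np.random.default_rng(seed)
    rows = []
    which = np.digitize(cid, edges) - 1
    for k in range(len(edges) - 1):
        vals = frac[which == k]
        if vals.size == 0:
            continue
        med = float(np.median(vals))
        if vals.size >= 5:
            boots = np.median(
                rng.choice(vals, size=(200, vals.size), replace=True), axis=1
            )
            lo_ci, hi_ci = np.percentile(boots, [2.5, 97.5])
        else:
            lo_ci = hi_ci = med
        rows.append(
            {
                "cid_center": float((edges[k] + edges[k + 1]) / 2),
                "median_occupancy": med,
                "ci_low": float(lo_ci),
                "ci_high": float(hi_ci),
                "n_windows": int(vals.size),
            }
        )
    return {"windows": df, "summary": pd.DataFrame(rows)}
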