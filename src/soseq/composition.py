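"""Kullback-Leibler divergence machinery and contact-aligned composition
time-courses.

The central quantity is D_KL(p || q) = sum_i p_i ln(p_i / q_i) in nats,
between an observed syllable (or syllable-pair) distribution p and an
expected reference q; q is smoothed with a small pseudocount so its support
covers p.  Contact-aligned time-courses collect, for every offset around
the onset of a scored contact bout, the distribution of syllable labels
across qualifying bouts, and compare each offset bin's divergence from the
overall dyadic composition against a bootstrap null built from the
pre-contact baseline window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from statsmodels.stats.multitest import multipletests

from .io_core import (
    AnalysisConfig,
    AnnotationBout,
    Dataset,
    FormatError,
    MISSING_LABEL,
    SyllableSequence,
)
from .syllables import extract_bouts

__all__ = [
    "dkl",
    "smooth_distribution",
    "frame_distribution",
    "joint_frame_distribution",
    "qualifying_bouts",
    "aligned_timecourse",
    "joint_timecourse",
    "shuffle_control",
    "DKLTimeCourse",
]


def smooth_distribution(q: np.ndarray, pseudocount: float = 1e-6) -> np.ndarray:
    """Add ``pseudocount`` per category and renormalize, so every category
    has positive probability."""
    q = np.asarray(q, dtype=float)
    if (q < 0).any():
        raise FormatError("distribution has negative entries")
    out = q + pseudocount
    return out / out.sum()


def dkl(p: np.ndarray, q: np.ndarray, pseudocount: float = 1e-6) -> float:
    """D_KL(p || q) in nats, with q pseudocount-smoothed and 0 ln 0 := 0."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise FormatError("p and q must have the same length")
    if (p < 0).any() or (q < 0).any():
        raise FormatError("distributions must be non-negative")
    psum = p.sum()
    if psum <= 0:
        raise FormatError("p sums to zero")
    p = p / psum
    q = smooth_distribution(q, pseudocount)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / q[nz])))


def _dkl_rows(counts: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Row-wise D_KL of count matrices against a smoothed q (vectorized)."""
    totals = counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = counts / totals
        terms = np.where(p > 0, p * np.log(p / q[None, :]), 0.0)
    return terms.sum(axis=1)


def frame_distribution(
    seqs: list[SyllableSequence], n_syllables: int
) -> np.ndarray:
    """Pooled frame-wise syllable distribution over non-missing frames."""
    counts = np.zeros(n_syllables)
    for s in seqs:
        lab = s.labels[s.labels != MISSING_LABEL]
        counts += np.bincount(lab, minlength=n_syllables)
    return counts / counts.sum()


def joint_frame_distribution(
    pairs: list[tuple[SyllableSequence, SyllableSequence]], n_syllables: int
) -> np.ndarray:
    """Pooled frame-wise distribution over ordered syllable pairs."""
    counts = np.zeros(n_syllables * n_syllables)
    for sa, sb in pairs:
        if sa.n_frames != sb.n_frames:
            raise FormatError("paired sequences have different lengths")
        ok = (sa.labels != MISSING_LABEL) & (sb.labels != MISSING_LABEL)
        cat = sa.labels[ok] * n_syllables + sb.labels[ok]
        counts += np.bincount(cat, minlength=counts.size)
    return counts / counts.sum()


def qualifying_bouts(
    annotations: list[AnnotationBout],
    contact_type: str,
    n_frames: int,
    pre: int,
    post: int,
) -> list[AnnotationBout]:
    """Pooled bouts of one type with a clean pre-onset control window.

    A bout qualifies when no other bout of the same type intersects the
    ``pre``-frame window before its onset, and the full aligned window
    fits inside the recording.
    """
    same = sorted(
        (b for b in annotations if b.contact_type == contact_type),
        key=lambda b: b.start,
    )
    out = []
    for i, b in enumerate(same):
        if b.start - pre < 0 or b.start + post > n_frames:
            continue
        clean = all(
            other.end <= b.start - pre or other.start >= b.start
            for j, other in enumerate(same)
            if j != i
        )
        if clean:
            out.append(b)
    return out


@dataclass
class DKLTimeCourse:
    """Event-aligned divergence time-course.

    ``offsets`` are frame offsets relative to contact-bout onset; ``dkl``
    is in nats; ``significant`` marks bins whose divergence exceeds the
    baseline-window bootstrap null after Benjamini-Hochberg correction;
    bins with support below the minimum are masked (NaN p, False mask).
    """

    offsets: np.ndarray
    dkl: np.ndarray
    z: np.ndarray
    p_values: np.ndarray
    significant: np.ndarray
    n_per_bin: np.ndarray
    baseline_window: tuple[int, int]
    n_bouts: int
    units: str = "nats"


def _aligned_counts(
    rows: np.ndarray, n_categories: int
) -> np.ndarray:
    """(n_offsets, n_categories) counts from an (n_rows, n_offsets) label
    matrix; negative labels are treated as missing."""
    n_offsets = rows.shape[1]
    counts = np.zeros((n_offsets, n_categories))
    for t in range(n_offsets):
        col = rows[:, t]
        col = col[col >= 0]
        counts[t] = np.bincount(col, minlength=n_categories)
    return counts


def _timecourse_from_counts(
    counts: np.ndarray,
    q: np.ndarray,
    offsets: np.ndarray,
    cfg: AnalysisConfig,
    rng: np.random.Generator,
    n_bouts: int,
    n_boot: int = 500,
) -> DKLTimeCourse:
    pre = cfg.pre_contact_window_frames
    qs = smooth_distribution(q, cfg.dkl_pseudocount)
    obs = _dkl_rows(counts, qs)
    n_per_bin = counts.sum(axis=1).astype(int)

    # bootstrap null: resample bin-sized label sets from the pooled
    # baseline-window composition and score them against q
    base_bins = (offsets >= -pre) & (offsets < 0)
    base_counts = counts[base_bins].sum(axis=0)
    if base_counts.sum() == 0:
        raise FormatError("baseline window has no observations")
    p_base = base_counts / base_counts.sum()
    n_typ = int(np.median(n_per_bin[n_per_bin > 0])) if (n_per_bin > 0).any() else 0
    if n_typ == 0:
        raise FormatError("no qualifying observations in any bin")
    null = _dkl_rows(rng.multinomial(n_typ, p_base, size=n_boot).astype(float), qs)
    null_mean, null_std = float(null.mean()), float(null.std(ddof=1))

    supported = n_per_bin >= cfg.min_bin_support
    p_values = np.full(offsets.size, np.nan)
    ge = (null[None, :] >= obs[:, None]).sum(axis=1)
    p_all = (1.0 + ge) / (n_boot + 1.0)
    p_values[supported] = p_all[supported]
    significant = np.zeros(offsets.size, dtype=bool)
    if supported.any():
        reject, _, _, _ = multipletests(
            p_values[supported], alpha=cfg.alpha, method="fdr_bh"
        )
        significant[supported] = reject
    z = (obs - null_mean) / null_std if null_std > 0 else np.zeros_like(obs)
    return DKLTimeCourse(
        offsets=offsets,
        dkl=obs,
        z=z,
        p_values=p_values,
        significant=significant,
        n_per_bin=n_per_bin,
        baseline_window=(-pre, 0),
        n_bouts=n_bouts,
    )


def aligned_timecourse(
    dataset: Dataset,
    contact_type: str = "active",
    cfg: AnalysisConfig | None = None,
    reference: np.ndarray | None = None,
    seed: int = 0,
) -> DKLTimeCourse:
    """Single-mouse syllable-composition divergence around contact onsets.

    For every offset in [-pre, post] the syllable labels of both animals of
    each qualifying contact bout are pooled across recordings into an
    empirical distribution, whose divergence from the overall dyadic
    composition (``reference``, computed from the data when omitted) is
    tested against the pre-onset baseline bootstrap.
    """
    cfg = cfg or dataset.config
    pre = cfg.pre_contact_window_frames
    post = cfg.post_contact_window_frames
    offsets = np.arange(-pre, post + 1)
    n_syll = dataset.n_syllables
    if reference is None:
        reference = frame_distribution(dataset.sequences("dyadic"), n_syll)

    rows = []
    for rec in dataset.by_context("dyadic"):
        if not rec.annotations:
            continue
        n_frames = min(s.n_frames for s in rec.sequences.values())
        for b in qualifying_bouts(rec.annotations, contact_type, n_frames, pre, post):
            for seq in rec.sequences.values():
                rows.append(seq.labels[b.start + offsets])
    if not rows:
        raise FormatError(f"no qualifying {contact_type} contact bouts")
    counts = _aligned_counts(np.asarray(rows), n_syll)
    rng = np.random.default_rng(seed)
    return _timecourse_from_counts(
        counts, reference, offsets, cfg, rng, n_bouts=len(rows)
    )


def joint_timecourse(
    dataset: Dataset,
    contact_type: str = "active",
    cfg: AnalysisConfig | None = None,
    reference: np.ndarray | None = None,
    seed: int = 0,
) -> DKLTimeCourse:
    """Two-mouse joint-composition divergence around contact onsets.

    Categories are ordered syllable pairs (n^2 cells); occupancy is sparse,
    so the pseudocount smoothing of the reference matters and a support
    warning applies at small bout counts.
    """
    cfg = cfg or dataset.config
    pre = cfg.pre_contact_window_frames
    post = cfg.post_contact_window_frames
    offsets = np.arange(-pre, post + 1)
    n_syll = dataset.n_syllables

    pairs = []
    rows = []
    for rec in dataset.by_context("dyadic"):
        if not rec.annotations:
            continue
        a, b = rec.pair()
        sa, sb = rec.sequences[a], rec.sequences[b]
        if sa.n_frames != sb.n_frames:
            raise FormatError(
                f"recording {rec.recording_id}: sequence length mismatch"
            )
        pairs.append((sa, sb))
        for bout in qualifying_bouts(
            rec.annotations, contact_type, sa.n_frames, pre, post
        ):
            la = sa.labels[bout.start + offsets]
            lb = sb.labels[bout.start + offsets]
            cat = np.where(
                (la >= 0) & (lb >= 0), la * n_syll + lb, -1
            )
            rows.append(cat)
    if not rows:
        raise FormatError(f"no qualifying {contact_type} contact bouts")
    if reference is None:
        reference = joint_frame_distribution(pairs, n_syll)
    counts = _aligned_counts(np.asarray(rows), n_syll * n_syll)
    rng = np.random.default_rng(seed)
    return _timecourse_from_counts(
        counts, reference, offsets, cfg, rng, n_bouts=len(rows)
    )


def shuffle_control(
    seq: SyllableSequence, seed: int | np.random.Generator = 0
) -> SyllableSequence:
    """Bout-order shuffle: permute the bout sequence uniformly, keep every
    bout's duration, and re-flatten to frames.

    Frame count and per-syllable frame totals are preserved exactly; all
    temporal alignment to events is destroyed, which is the negative
    control for the aligned time-courses.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    bouts = extract_bouts(seq)
    order = rng.permutation(len(bouts))
    labels = seq.labels.copy()
    fill = np.concatenate(
        [
            np.full(bouts[i].duration, bouts[i].syllable, dtype=np.int64)
            for i in order
        ]
    )
    labels[labels != MISSING_LABEL] = fill
    return SyllableSequence(
        recording_id=seq.recording_id,
        animal_id=seq.animal_id,
        context=seq.context,
        light_cycle=seq.light_cycle,
        labels=labels,
        frame_rate=seq.frame_rate,
    )
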