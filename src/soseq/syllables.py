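"""Bout extraction, usage proportions and the context-modulation tests.

Bouts are maximal runs of one syllable; the ``-1`` missing label breaks a
run and the surrounding bouts are not treated as adjacent.  Usage is
summarized two ways: onset (bout) proportion, which ignores bout length,
and frame proportion over non-missing frames.  The context contrast is a
per-syllable two-sided Mann-Whitney U on per-animal onset proportions with
Benjamini-Hochberg correction; syllables passing it form the
dyadic-modulated (DM) set, the rest the dyadic-unmodulated (DU) set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import (
    AnalysisConfig,
    AnnotationBout,
    Bout,
    CentroidTrack,
    Dataset,
    FormatError,
    MISSING_LABEL,
    SyllableSequence,
    TestResult,
)

__all__ = [
    "extract_bouts",
    "proportions",
    "build_proportion_table",
    "filter_syllables",
    "distance_moved",
    "compare_contexts",
    "contact_association",
    "quartile_association",
    "ProportionTable",
    "ContextComparison",
]


def extract_bouts(seq: SyllableSequence) -> list[Bout]:
    """Run-length encode a label sequence into bouts.

    Missing (-1) runs are skipped; a bout that follows a missing run starts
    a new segment, so it is not frame-adjacent to the previous bout (which
    matters for transition counting and syntax extraction).
    """
    labels = seq.labels
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [labels.size]))
    bouts = [
        Bout(int(labels[s]), int(s), int(e))
        for s, e in zip(starts, ends)
        if labels[s] != MISSING_LABEL
    ]
    if not bouts:
        raise FormatError(
            f"{seq.recording_id}/{seq.animal_id}: sequence is entirely missing"
        )
    return bouts


def proportions(
    bouts: list[Bout], seq: SyllableSequence, n_syllables: int
) -> tuple[np.ndarray, np.ndarray, int, int]:
    """Onset and frame proportion vectors for one animal-recording.

    Returns ``(onset, frame, n_bouts, n_frames)`` where frame proportions
    are over non-missing frames only.
    """
    if not bouts:
        raise FormatError("no bouts to summarize")
    onset = np.zeros(n_syllables)
    frames = np.zeros(n_syllables)
    for b in bouts:
        onset[b.syllable] += 1
        frames[b.syllable] += b.duration
    n_bouts = len(bouts)
    n_frames = int(frames.sum())
    return onset / n_bouts, frames / n_frames, n_bouts, n_frames


@dataclass
class ProportionTable:
    """Per animal-recording usage summaries.

    ``onset`` and ``frame`` are DataFrames indexed by (recording_id,
    animal_id) with one column per syllable id; ``meta`` carries context and
    light-cycle labels on the same index.
    """

    onset: pd.DataFrame
    frame: pd.DataFrame
    meta: pd.DataFrame
    n_bouts: pd.Series
    n_frames: pd.Series

    @property
    def n_syllables(self) -> int:
        return self.onset.shape[1]

    def pooled_onset(self) -> np.ndarray:
        """Onset proportions pooled over all recordings (bout-weighted)."""
        counts = self.onset.mul(self.n_bouts, axis=0).sum(axis=0)
        return (counts / counts.sum()).to_numpy()

    def restrict(self, syllables: list[int]) -> "ProportionTable":
        """Re-normalized table over a retained syllable subset."""
        onset = self.onset[syllables]
        frame = self.frame[syllables]
        return ProportionTable(
            onset.div(onset.sum(axis=1), axis=0),
            frame.div(frame.sum(axis=1), axis=0),
            self.meta,
            self.n_bouts,
            self.n_frames,
        )


def build_proportion_table(dataset: Dataset, n_syllables: int | None = None) -> ProportionTable:
    n_syllables = n_syllables or dataset.n_syllables
    rows_on, rows_fr, idx, meta, nb, nf = [], [], [], [], [], []
    for rec in dataset.recordings:
        for aid, seq in rec.sequences.items():
            bouts = extract_bouts(seq)
            on, fr, b, f = proportions(bouts, seq, n_syllables)
            rows_on.append(on)
            rows_fr.append(fr)
            idx.append((rec.recording_id, aid))
            meta.append((rec.context, rec.light_cycle))
            nb.append(b)
            nf.append(f)
    index = pd.MultiIndex.from_tuples(idx, names=["recording_id", "animal_id"])
    return ProportionTable(
        onset=pd.DataFrame(rows_on, index=index),
        frame=pd.DataFrame(rows_fr, index=index),
        meta=pd.DataFrame(meta, index=index, columns=["context", "light_cycle"]),
        n_bouts=pd.Series(nb, index=index),
        n_frames=pd.Series(nf, index=index),
    )


def filter_syllables(
    pooled_onset: np.ndarray, threshold: float = 0.005
) -> tuple[list[int], dict[int, int]]:
    """Retain syllables with pooled onset proportion strictly above
    ``threshold`` (the 0.5% rule), ordered by descending proportion.

    Returns the retained id list and the old->new id mapping.
    """
    pooled_onset = np.asarray(pooled_onset, dtype=float)
    retained = [int(i) for i in np.argsort(-pooled_onset, kind="stable")
                if pooled_onset[i] > threshold]
    if not retained:
        raise FormatError(
            "no syllables retained; lower the onset threshold "
            f"(currently {threshold})"
        )
    return retained, {old: new for new, old in enumerate(retained)}


def distance_moved(track: CentroidTrack) -> float:
    """Total path length in mm, skipping missing frames."""
    pos = track.positions[~track.missing]
    if pos.shape[0] < 1:
        raise FormatError(
            f"{track.recording_id}/{track.animal_id}: track entirely missing"
        )
    if pos.shape[0] < 2:
        return 0.0
    return float(np.linalg.norm(np.diff(pos, axis=0), axis=1).sum())


# ---------------------------------------------------------------------------
# context modulation
# ---------------------------------------------------------------------------


@dataclass
class ContextComparison:
    results: list[TestResult]
    dm: list[int]          # significantly modulated syllables
    du: list[int]
    skipped: list[int]     # degenerate (absent everywhere) syllables


def _mwu_family(
    group_a: np.ndarray,
    group_b: np.ndarray,
    names: list[int],
    alpha: float,
    correction: str,
    alternative: str = "two-sided",
) -> tuple[list[TestResult], list[int]]:
    """Per-column Mann-Whitney U with a shared multiplicity correction.

    Columns that are constant and identical across the pooled sample are
    skipped (the U test is undefined there) and reported separately.
    """
    stats_, p_raw, tested = [], [], []
    skipped = []
    for j in range(group_a.shape[1]):
        a, b = group_a[:, j], group_b[:, j]
        if np.ptp(np.concatenate([a, b])) == 0:
            skipped.append(names[j])
            continue
        res = stats.mannwhitneyu(a, b, alternative=alternative)
        stats_.append(float(res.statistic))
        p_raw.append(float(res.pvalue))
        tested.append(names[j])
    if not tested:
        return [], skipped
    method = {"benjamini_hochberg": "fdr_bh", "bonferroni": "bonferroni"}[
        correction
    ]
    reject, p_adj, _, _ = multipletests(p_raw, alpha=alpha, method=method)
    results = [
        TestResult(
            statistic=s,
            p_raw=p,
            p_adjusted=float(q),
            method="mann_whitney_u",
            correction=correction,
            significant=bool(r),
            name=str(n),
        )
        for s, p, q, r, n in zip(stats_, p_raw, p_adj, reject, tested)
    ]
    return results, skipped


def compare_contexts(
    table: ProportionTable, alpha: float = 0.05
) -> ContextComparison:
    """Solitary vs dyadic onset-proportion contrast per syllable.

    Two-sided Mann-Whitney U on per-animal onset proportions with
    Benjamini-Hochberg correction across syllables; the significant set is
    the DM set.
    """
    sol = table.onset[table.meta["context"] == "solitary"].to_numpy()
    dya = table.onset[table.meta["context"] == "dyadic"].to_numpy()
    if len(sol) < 2 or len(dya) < 2:
        raise FormatError("need at least 2 animals per context")
    names = [int(c) for c in table.onset.columns]
    results, skipped = _mwu_family(
        sol, dya, names, alpha, "benjamini_hochberg"
    )
    dm = sorted(int(r.name) for r in results if r.significant)
    du = sorted(set(names) - set(dm) - set(skipped))
    return ContextComparison(results, dm, du, skipped)


# ---------------------------------------------------------------------------
# contact / distance association (dyadic recordings)
# ---------------------------------------------------------------------------


def _interval_mask(n_frames: int, bouts: list[AnnotationBout]) -> np.ndarray:
    mask = np.zeros(n_frames, dtype=bool)
    for b in bouts:
        mask[b.start : min(b.end, n_frames)] = True
    return mask


def _two_way_anova(cells: pd.DataFrame, factor_b: str) -> dict:
    """Two-way fixed-effects ANOVA on per-animal proportion cells."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    model = smf.ols(
        f"proportion ~ C(syllable) * C({factor_b})", data=cells
    ).fit()
    tab = anova_lm(model, typ=2)
    return {
        "anova_table": tab,
        "p_syllable": float(tab.loc["C(syllable)", "PR(>F)"]),
        f"p_{factor_b}": float(tab.loc[f"C({factor_b})", "PR(>F)"]),
        "p_interaction": float(
            tab.loc[f"C(syllable):C({factor_b})", "PR(>F)"]
        ),
    }


def contact_association(
    dataset: Dataset,
    syllables: list[int],
    contact_type: str = "active",
    alpha: float = 0.05,
) -> dict:
    """Association of syllable onsets with scored contact.

    For each syllable in ``syllables`` a 2x2 contingency table (onsets of
    this syllable vs all others x onset inside vs outside contact) is
    tested with a chi-squared test, Bonferroni-corrected across the tested
    syllables.  A two-way ANOVA (syllable x contact) on per-animal onset
    proportions is reported alongside.
    """
    n_syll = dataset.n_syllables
    counts_in = np.zeros(n_syll)
    counts_out = np.zeros(n_syll)
    cells = []
    for rec in dataset.by_context("dyadic"):
        if not rec.annotations:
            continue
        ann = [b for b in rec.annotations if b.contact_type == contact_type]
        for aid, seq in rec.sequences.items():
            mask = _interval_mask(seq.n_frames, ann)
            bouts = extract_bouts(seq)
            onsets = np.array([b.start for b in bouts])
            labs = np.array([b.syllable for b in bouts])
            inside = mask[onsets]
            counts_in += np.bincount(labs[inside], minlength=n_syll)
            counts_out += np.bincount(labs[~inside], minlength=n_syll)
            for where, sel in (("inside", inside), ("outside", ~inside)):
                tot = max(sel.sum(), 1)
                sub = np.bincount(labs[sel], minlength=n_syll)
                for s in syllables:
                    cells.append(
                        {
                            "animal": f"{rec.recording_id}/{aid}",
                            "syllable": s,
                            "contact": where,
                            "proportion": sub[s] / tot,
                        }
                    )
    if counts_in.sum() == 0:
        raise FormatError("no contact frames in the dataset")

    results = []
    p_raw = []
    for s in syllables:
        table = np.array(
            [
                [counts_in[s], counts_out[s]],
                [counts_in.sum() - counts_in[s], counts_out.sum() - counts_out[s]],
            ]
        )
        if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
            results.append(None)
            p_raw.append(np.nan)
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        p_raw.append(p)
        results.append((float(chi2), float(p)))
    tested = [i for i, r in enumerate(results) if r is not None]
    reject, p_adj, _, _ = multipletests(
        [p_raw[i] for i in tested], alpha=alpha, method="bonferroni"
    )
    out = []
    for k, i in enumerate(tested):
        chi2, p = results[i]
        out.append(
            TestResult(
                statistic=chi2,
                p_raw=p,
                p_adjusted=float(p_adj[k]),
                method="chi2_contingency",
                correction="bonferroni",
                significant=bool(reject[k]),
                name=str(syllables[i]),
            )
        )
    cells_df = pd.DataFrame(cells)
    anova = (
        _two_way_anova(cells_df, "contact")
        if len(cells_df) and cells_df["syllable"].nunique() > 1
        else None
    )
    return {
        "tests": out,
        "significant": sorted(int(r.name) for r in out if r.significant),
        "anova": anova,
        "counts_in": counts_in,
        "counts_out": counts_out,
    }


def quartile_association(
    dataset: Dataset,
    syllables: list[int],
    alpha: float = 0.05,
) -> dict:
    """Onset proportions per inter-mouse-distance quartile.

    Each onset is assigned the inter-mouse distance at its start frame;
    quartile edges come from the pooled distance distribution over all
    dyadic recordings.  Reports the per-quartile onset-proportion table and
    a two-way ANOVA (syllable x quartile).
    """
    pooled_imd = []
    per_rec = []
    for rec in dataset.by_context("dyadic"):
        try:
            a, b = rec.pair()
        except ValueError:
            continue
        if a not in rec.tracks or b not in rec.tracks:
            raise FormatError(
                f"recording {rec.recording_id}: missing track for the dyad"
            )
        imd = np.linalg.norm(
            rec.tracks[a].positions - rec.tracks[b].positions, axis=1
        )
        pooled_imd.append(imd)
        per_rec.append((rec, imd))
    if not per_rec:
        raise FormatError("no dyadic recordings with paired tracks")
    pooled = np.concatenate(pooled_imd)
    edges = np.quantile(pooled, [0.25, 0.5, 0.75])
    if np.ptp(edges) == 0:
        raise FormatError("degenerate quartiles: inter-mouse distance constant")
    quartile_values = np.quantile(pooled, [0.25, 0.5, 0.75, 1.0])

    n_syll = dataset.n_syllables
    counts = np.zeros((4, n_syll))
    cells = []
    for rec, imd in per_rec:
        for aid, seq in rec.sequences.items():
            bouts = extract_bouts(seq)
            onsets = np.array([b.start for b in bouts])
            labs = np.array([b.syllable for b in bouts])
            q = np.searchsorted(edges, imd[onsets], side="right")
            for qi in range(4):
                sel = q == qi
                counts[qi] += np.bincount(labs[sel], minlength=n_syll)
                tot = max(sel.sum(), 1)
                sub = np.bincount(labs[sel], minlength=n_syll)
                for s in syllables:
                    cells.append(
                        {
                            "animal": f"{rec.recording_id}/{aid}",
                            "syllable": s,
                            "quartile": qi,
                            "proportion": sub[s] / tot,
                        }
                    )
    with np.errstate(invalid="ignore"):
        prop = counts / counts.sum(axis=1, keepdims=True)
    return {
        "quartile_edges": edges,
        "quartile_values": quartile_values,
        "proportions": pd.DataFrame(
            prop, index=[f"Q{i+1}" for i in range(4)]
        ),
        "anova": _two_way_anova(pd.DataFrame(cells), "quartile"),
    }
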