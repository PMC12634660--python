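"""Bout extraction, proportions, filtering and the context/contact tests."""

import numpy as np
import pytest
from scipy import stats

from soseq.io_core import AnnotationBout, CentroidTrack, Dataset, FormatError
from soseq.syllables import (
    build_proportion_table,
    compare_contexts,
    contact_association,
    distance_moved,
    extract_bouts,
    filter_syllables,
    proportions,
    quartile_association,
)
from soseq.synthetic import SyntheticConfig, generate_experiment
from tests.conftest import make_seq


def brute_force_bouts(labels):
    """Frame-scan oracle for run-length extraction."""
    out = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            if labels[start] != -1:
                out.append((int(labels[start]), start, i))
            start = i
    return out


class TestExtractBouts:
    def test_simple_runs(self):
        bouts = extract_bouts(make_seq([5, 5, 9]))
        assert [(b.syllable, b.start, b.end) for b in bouts] == [
            (5, 0, 2),
            (9, 2, 3),
        ]

    def test_single_run(self):
        (b,) = extract_bouts(make_seq([7, 7, 7]))
        assert b.duration == 3

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        labels = rng.integers(-1, 6, size=10_000)
        bouts = extract_bouts(make_seq(labels))
        assert [(b.syllable, b.start, b.end) for b in bouts] == (
            brute_force_bouts(labels)
        )

    def test_all_missing_rejected(self):
        with pytest.raises(FormatError, match="missing"):
            extract_bouts(make_seq([-1, -1]))

    def test_missing_breaks_adjacency(self):
        bouts = extract_bouts(make_seq([3, 3, -1, 3, 4]))
        assert len(bouts) == 3
        assert bouts[0].end != bouts[1].start  # gap between the two 3-bouts


class TestProportions:
    def test_onset_proportions(self):
        seq = make_seq([0, 1, 1, 0])
        on, fr, nb, nf = proportions(extract_bouts(seq), seq, 2)
        assert np.allclose(on, [2 / 3, 1 / 3])

    def test_frame_proportions(self):
        seq = make_seq([0, 0, 0, 1])
        _, fr, _, _ = proportions(extract_bouts(seq), seq, 2)
        assert np.allclose(fr, [0.75, 0.25])

    @pytest.mark.parametrize("seed", range(20))
    def test_normalization(self, seed):
        rng = np.random.default_rng(seed)
        seq = make_seq(rng.integers(0, 8, 500))
        on, fr, _, _ = proportions(extract_bouts(seq), seq, 8)
        assert on.sum() == pytest.approx(1.0, abs=1e-9)
        assert fr.sum() == pytest.approx(1.0, abs=1e-9)


class TestFilter:
    def test_half_percent_rule(self):
        retained, mapping = filter_syllables(
            np.array([0.7, 0.2, 0.096, 0.004])
        )
        assert sorted(retained) == [0, 1, 2]
        assert mapping == {0: 0, 1: 1, 2: 2}

    def test_zero_threshold_keeps_all(self):
        retained, _ = filter_syllables(np.array([0.5, 0.3, 0.2]), 0.0)
        assert sorted(retained) == [0, 1, 2]

    def test_boundary_is_strict(self):
        retained, _ = filter_syllables(np.array([0.995, 0.005]))
        assert retained == [0]

    def test_idempotent(self):
        p = np.array([0.6, 0.3, 0.06, 0.04, 0.0])
        retained, _ = filter_syllables(p)
        sub = p[retained] / p[retained].sum()
        again, _ = filter_syllables(sub)
        assert [retained[i] for i in again] == retained


class TestDistanceMoved:
    def test_constant_track_zero(self):
        t = CentroidTrack("r", "a", np.tile([10.0, 10.0], (5, 1)))
        assert distance_moved(t) == 0.0

    def test_three_four_five(self):
        t = CentroidTrack("r", "a", np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert distance_moved(t) == pytest.approx(5.0)

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 453, (1000, 2))
        t = CentroidTrack("r", "a", pos)
        oracle = sum(
            float(np.hypot(*(pos[i + 1] - pos[i]))) for i in range(999)
        )
        assert distance_moved(t) == pytest.approx(oracle, abs=1e-9)


class TestCompareContexts:
    def _table(self, sol, dya):
        """Build a tiny dataset from explicit label blocks."""
        from soseq.io_core import Recording

        recs = []
        for i, labels in enumerate(sol):
            recs.append(
                Recording(f"s{i}", "solitary", "normal",
                          {f"m{i}": make_seq(labels, recording_id=f"s{i}",
                                             animal_id=f"m{i}")}, {}))
        for i, labels in enumerate(dya):
            recs.append(
                Recording(f"d{i}", "dyadic", "normal",
                          {f"m{i}": make_seq(labels, context="dyadic",
                                             recording_id=f"d{i}",
                                             animal_id=f"m{i}")}, {}))
        return build_proportion_table(Dataset(recs))

    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        blocks = [rng.integers(0, 4, 300) for _ in range(4)]
        table = self._table(blocks, blocks)
        assert compare_contexts(table).dm == []

    def test_permutation_invariance(self):
        rng = np.random.default_rng(1)
        sol = [rng.integers(0, 4, 300) for _ in range(5)]
        dya = [rng.integers(0, 4, 300) for _ in range(5)]
        t1 = self._table(sol, dya)
        t2 = self._table(sol[::-1], dya[::-1])
        p1 = sorted(r.p_raw for r in compare_contexts(t1).results)
        p2 = sorted(r.p_raw for r in compare_contexts(t2).results)
        assert np.allclose(p1, p2)

    def test_absent_syllable_skipped_not_crashed(self):
        rng = np.random.default_rng(2)
        sol = [rng.integers(0, 3, 300) for _ in range(3)]
        dya = [rng.integers(0, 3, 300) for _ in range(3)]
        table = self._table(sol, dya)
        table.onset[3] = 0.0  # syllable absent everywhere
        comp = compare_contexts(table)
        assert 3 in comp.skipped

    def test_too_few_animals_rejected(self):
        rng = np.random.default_rng(3)
        with pytest.raises(FormatError, match="2 animals"):
            compare_contexts(
                self._table([rng.integers(0, 3, 100)],
                            [rng.integers(0, 3, 100)] * 3)
            )

    def test_planted_recovery(self, planted):
        cfg, ds, gt = planted
        comp = compare_contexts(build_proportion_table(ds))
        assert set(gt.planted_dm) <= set(comp.dm) | set(
            gt.planted_dm
        )  # sanity on types
        overlap = len(set(comp.dm) & set(gt.planted_dm))
        assert overlap >= 6  # majority of the 8 planted ids


class TestContactAssociation:
    def test_chi2_matches_textbook_formula(self):
        table = np.array([[10, 90], [40, 860]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        n = table.sum()
        row = table.sum(axis=1)
        col = table.sum(axis=0)
        expected = np.outer(row, col) / n
        oracle = ((table - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(oracle, abs=1e-9)

    def test_extreme_contact_syllable_significant(self):
        """A syllable emitted only during contact must be flagged."""
        from soseq.io_core import Recording

        rng = np.random.default_rng(4)
        recs = []
        for i in range(3):
            labels = rng.integers(0, 3, 2000)
            labels[500:700] = 5  # syllable 5 only inside the contact window
            # break into bouts: alternate with syllable 4 to create onsets
            labels[510:700:20] = 4
            seq = make_seq(labels, context="dyadic", recording_id=f"d{i}",
                           animal_id=f"m{i}")
            recs.append(
                Recording(f"d{i}", "dyadic", "normal", {f"m{i}": seq}, {},
                          [AnnotationBout(f"d{i}", "active", 500, 700)])
            )
        ds = Dataset(recs)
        out = contact_association(ds, [5], "active")
        assert out["tests"][0].significant
        assert out["counts_in"][5] > 0 and out["counts_out"][5] == 0

    def test_no_contact_frames_rejected(self, small_planted):
        cfg, ds, _ = small_planted
        stripped = Dataset(
            [
                type(r)(r.recording_id, r.context, r.light_cycle,
                        r.sequences, r.tracks,
                        [] if r.context == "dyadic" else None)
                for r in ds.recordings
            ],
            ds.config,
        )
        with pytest.raises(FormatError, match="contact"):
            contact_association(stripped, [0])

    def test_null_type_one_rate(self):
        """Onsets placed independently of contact: few significant calls."""
        from soseq.io_core import Recording

        n_sig = 0
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            recs = []
            for i in range(3):
                labels = np.repeat(rng.integers(0, 6, 400), 5)
                seq = make_seq(labels, context="dyadic",
                               recording_id=f"d{i}", animal_id=f"m{i}")
                recs.append(
                    Recording(f"d{i}", "dyadic", "normal", {f"m{i}": seq},
                              {}, [AnnotationBout(f"d{i}", "active", 300, 700)])
                )
            out = contact_association(Dataset(recs), list(range(6)))
            n_sig += len(out["significant"])
        # Bonferroni over 6 tests at alpha 0.05, 30 replicates
        assert n_sig <= 6


class TestQuartileAssociation:
    def test_uniform_imd_quartile_edges(self):
        """Order statistics: quartiles of uniform IMD on [0, 400]."""
        from soseq.io_core import Recording

        rng = np.random.default_rng(7)
        n = 20_000
        ang = rng.uniform(0, 2 * np.pi, n)
        r = rng.uniform(0, 400, n)
        base = np.tile([226.0, 226.0], (n, 1))
        # clip-free: place pair symmetrically around the center
        off = np.column_stack([np.cos(ang), np.sin(ang)]) * r[:, None] / 2
        pa, pb = base + off, base - off
        seqs = {
            "m0": make_seq(rng.integers(0, 4, n), context="dyadic",
                           animal_id="m0"),
            "m1": make_seq(rng.integers(0, 4, n), context="dyadic",
                           animal_id="m1"),
        }
        tracks = {
            "m0": CentroidTrack("r0", "m0", pa.clip(0, 453)),
            "m1": CentroidTrack("r0", "m1", pb.clip(0, 453)),
        }
        ds = Dataset([Recording("r0", "dyadic", "normal", seqs, tracks)])
        out = quartile_association(ds, [0, 1, 2, 3])
        assert np.allclose(out["quartile_edges"], [100, 200, 300], atol=10)

    def test_constant_imd_degenerate(self):
        from soseq.io_core import Recording

        rng = np.random.default_rng(8)
        n = 500
        seqs = {
            "m0": make_seq(rng.integers(0, 3, n), context="dyadic",
                           animal_id="m0"),
            "m1": make_seq(rng.integers(0, 3, n), context="dyadic",
                           animal_id="m1"),
        }
        tracks = {
            "m0": CentroidTrack("r0", "m0", np.tile([100.0, 100.0], (n, 1))),
            "m1": CentroidTrack("r0", "m1", np.tile([300.0, 100.0], (n, 1))),
        }
        ds = Dataset([Recording("r0", "dyadic", "normal", seqs, tracks)])
        with pytest.raises(FormatError, match="degenerate"):
            quartile_association(ds, [0])

    def test_per_quartile_proportions_normalize(self, small_planted):
        cfg, ds, _ = small_planted
        out = quartile_association(ds, list(range(cfg.n_syllables)))
        sums = out["proportions"].sum(axis=1).to_numpy()
        assert np.allclose(sums[np.isfinite(sums)], 1.0, atol=1e-9)
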