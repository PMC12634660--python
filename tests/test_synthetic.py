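"""Generator structure, calibration and determinism."""

import numpy as np
import pytest

from soseq.io_core import Dataset
from soseq.synthetic import (
    ConfigError,
    SyntheticConfig,
    generate_contacts,
    generate_experiment,
    generate_sequence,
    generate_tracks,
    generate_transition_matrices,
    geometric_p_for_median,
    plan_events,
    _rng,
)
from soseq.syllables import extract_bouts


SMALL = dict(n_animals_per_context=4, duration_s=240)


class TestTransitionMatrices:
    def test_rows_stochastic_zero_diagonal(self):
        cfg = SyntheticConfig(seed=2, **SMALL)
        for ctx in ("solitary", "dyadic"):
            out = generate_transition_matrices(cfg, ctx)
            for mat in [out["base"], *out["animals"]]:
                assert np.abs(mat.sum(axis=1) - 1).max() < 1e-12
                assert np.abs(np.diagonal(mat)).max() == 0.0

    def test_null_effects_identical_bases(self):
        cfg = SyntheticConfig(seed=3, **SMALL).null()
        sol = generate_transition_matrices(cfg, "solitary")["base"]
        dya = generate_transition_matrices(cfg, "dyadic")["base"]
        assert np.array_equal(sol, dya)

    def test_boost_raises_planted_incoming_mass(self):
        """Monte Carlo over seeds: up-modulated columns gain incoming mass
        in the dyadic base relative to solitary."""
        diffs = []
        for seed in range(50):
            cfg = SyntheticConfig(seed=seed, **SMALL)
            sol = generate_transition_matrices(cfg, "solitary")["base"]
            dya = generate_transition_matrices(cfg, "dyadic")["base"]
            up = list(cfg.planted_up)
            diffs.append(dya[:, up].mean() - sol[:, up].mean())
        assert np.mean(diffs) > 0
        assert np.min(diffs) > 0

    def test_too_few_syllables_rejected(self):
        with pytest.raises(ConfigError):
            SyntheticConfig(n_syllables=2)


class TestSequences:
    def test_forced_two_state_alternation(self):
        from tests.conftest import make_seq

        cfg = SyntheticConfig(seed=4, n_syllables=3, planted_dm=(), **SMALL)
        mat = np.array([[0, 1.0, 0], [1.0, 0, 0], [0.5, 0.5, 0]])
        seq = generate_sequence(mat, cfg, _rng(0, 9))
        bouts = [b.syllable for b in extract_bouts(make_seq(seq))]
        for a, b in zip(bouts, bouts[1:]):
            if a in (0, 1):
                assert b == 1 - a

    def test_median_bout_duration_calibrated(self):
        cfg = SyntheticConfig(seed=1, duration_s=1200)
        mat = generate_transition_matrices(cfg, "solitary")["base"]
        labels = generate_sequence(mat, cfg, (9, 0))
        from tests.conftest import make_seq

        durs = [b.duration for b in extract_bouts(make_seq(labels))]
        assert 9 <= np.median(durs) <= 11

    def test_transition_frequencies_match_matrix(self):
        """Law of large numbers: empirical bout transitions approach the
        generating matrix."""
        cfg = SyntheticConfig(seed=6, n_syllables=5, planted_dm=(),
                              duration_s=4000, n_animals_per_context=4)
        rng = np.random.default_rng(0)
        raw = rng.dirichlet(np.ones(4), size=5)
        mat = np.zeros((5, 5))
        for i in range(5):
            mat[i, np.arange(5) != i] = raw[i]
        labels = generate_sequence(mat, cfg, (0, 0))
        from tests.conftest import make_seq

        bouts = extract_bouts(make_seq(labels))
        assert len(bouts) >= 2000
        counts = np.zeros((5, 5))
        labs = [b.syllable for b in bouts]
        for a, b in zip(labs, labs[1:]):
            counts[a, b] += 1
        emp = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(emp - mat).max() < 0.05

    def test_geometric_median_formula(self):
        rng = np.random.default_rng(0)
        for m in (1, 5, 10, 20):
            draws = rng.geometric(geometric_p_for_median(m), size=200_000)
            assert np.median(draws) == m


class TestTracksAndContacts:
    def test_approach_ends_proximal(self):
        cfg = SyntheticConfig(seed=7, **SMALL)
        rng = _rng(cfg.seed, 40)
        plan = plan_events(cfg, _rng(cfg.seed, 41))
        la = generate_sequence(
            generate_transition_matrices(cfg, "dyadic")["animals"][0], cfg, (1, 0)
        )
        lb = generate_sequence(
            generate_transition_matrices(cfg, "dyadic")["animals"][1], cfg, (1, 1)
        )
        pa, pb, la2 = generate_tracks(cfg, rng, plan, la, lb)
        imd = np.linalg.norm(pa - pb, axis=1)
        for ep in plan:
            if ep.kind == "approach":
                assert imd[ep.end - 1] < cfg.contact_mm

    def test_corner_occupancy_exceeds_uniform(self, small_planted):
        cfg, ds, gt = small_planted
        w = cfg.arena_mm
        corners = np.array([[0, 0], [w, 0], [0, w], [w, w]])

        def corner_frac(pos):
            d = np.linalg.norm(pos[:, None, :] - corners[None], axis=2)
            return (d.min(axis=1) < 100).mean()

        obs = np.mean(
            [
                corner_frac(t.positions)
                for r in ds.recordings
                for t in r.tracks.values()
            ]
        )
        rng = np.random.default_rng(0)
        uniform = corner_frac(rng.uniform(0, w, size=(100_000, 2)))
        assert obs > uniform * 1.5

    def test_distant_tracks_give_no_contacts(self):
        cfg = SyntheticConfig(seed=8, **SMALL)
        n = 500
        a = np.tile([50.0, 50.0], (n, 1))
        b = np.tile([400.0, 400.0], (n, 1))
        bouts, _, _ = generate_contacts(a, b, cfg, _rng(0, 1))
        assert bouts == []

    def test_single_proximal_run_single_bout(self):
        cfg = SyntheticConfig(seed=8, **SMALL)
        n = 300
        a = np.tile([50.0, 50.0], (n, 1))
        b = np.tile([400.0, 400.0], (n, 1))
        b[100:150] = [60.0, 60.0]
        bouts, _, _ = generate_contacts(a, b, cfg, _rng(0, 2))
        assert len(bouts) == 1
        assert (bouts[0].start, bouts[0].end) == (100, 150)

    def test_zero_speed_profile_tracks_constant(self):
        cfg = SyntheticConfig(
            seed=9, base_step_mm=0.0, **SMALL
        )
        labels = np.zeros(cfg.n_frames, dtype=np.int64)
        from soseq.synthetic import generate_solitary_track

        pos = generate_solitary_track(cfg, _rng(0, 3), labels)
        # jitter-only walk: total drift stays within dwell noise
        assert np.linalg.norm(pos - pos.mean(axis=0), axis=1).max() < 150


class TestExperiment:
    def test_deterministic_regeneration(self):
        cfg = SyntheticConfig(seed=12, **SMALL)
        ds1, gt1 = generate_experiment(cfg)
        ds2, gt2 = generate_experiment(cfg)
        for r1, r2 in zip(ds1.recordings, ds2.recordings):
            for aid in r1.sequences:
                assert np.array_equal(
                    r1.sequences[aid].labels, r2.sequences[aid].labels
                )
                assert np.array_equal(
                    r1.tracks[aid].positions, r2.tracks[aid].positions
                )
            assert (r1.annotations or []) == (r2.annotations or [])
        assert np.array_equal(
            gt1.base_matrices["dyadic"], gt2.base_matrices["dyadic"]
        )

    def test_written_files_byte_identical(self, tmp_path):
        from soseq.synthetic import write_experiment

        cfg = SyntheticConfig(seed=13, n_animals_per_context=2, duration_s=120)
        for sub in ("x", "y"):
            ds, gt = generate_experiment(cfg)
            write_experiment(ds, gt, tmp_path / sub)
        for p1 in sorted((tmp_path / "x").rglob("*")):
            if p1.is_file():
                p2 = tmp_path / "y" / p1.relative_to(tmp_path / "x")
                assert p1.read_bytes() == p2.read_bytes(), p1.name

    def test_contact_bias_shifts_in_contact_composition(self, small_planted):
        """Planted contact composition: labels inside active contacts
        diverge from the overall distribution."""
        from soseq.composition import dkl, frame_distribution

        cfg, ds, gt = small_planted
        n = cfg.n_syllables
        overall = frame_distribution(ds.sequences("dyadic"), n)
        counts = np.zeros(n)
        for rec in ds.by_context("dyadic"):
            for b in rec.annotations or []:
                if b.contact_type != "active":
                    continue
                for seq in rec.sequences.values():
                    seg = seq.labels[b.start : b.end]
                    counts += np.bincount(seg, minlength=n)
        assert counts.sum() > 0
        assert dkl(counts / counts.sum(), overall) > 0.05
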