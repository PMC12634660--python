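"""(IMD, CID) behavior classes, distance controls and class composition."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from soseq.io_core import FormatError
from soseq.kinematics import (
    PRIMARY_CLASSES,
    classify,
    classify_points,
    class_dkl_matrix,
    class_family_association,
    imd_controls,
    imd_series,
    in_control_class,
    position_kde,
    syntax_kinematics,
)
from soseq.syntax import SyntaxOccurrence

# mean distance between two uniform points in a unit square
UNIT_SQUARE_MEAN_DISTANCE = 0.5214054331


class TestClassify:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            (50, 10, "contact"),        # 50 < 100, 60 < 100
            (250, -200, "approach"),    # 250 > 100, 50 < 100
            (50, 200, "leave"),         # 50 < 100, 250 > 100
            (300, 50, "far_stationary"),
        ],
    )
    def test_worked_examples(self, x, y, expected):
        assert classify((x, y)) == expected

    def test_negative_distance_rejected(self):
        with pytest.raises(FormatError):
            classify((-5.0, 0.0))

    def test_partition_of_the_plane(self):
        """Every non-boundary point gets exactly one primary class."""
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 700, 100_000)
        y = rng.uniform(-700, 700, 100_000)
        labels = classify_points(x, y)
        assert set(np.unique(labels)) <= set(PRIMARY_CLASSES)
        # scalar and vector paths agree
        idx = rng.choice(100_000, 200)
        for i in idx:
            assert classify((x[i], y[i])) == labels[i]

    def test_boundary_goes_stationary(self):
        assert classify((50.0, 50.0)) == "contact"       # x + y == 100
        assert classify((150.0, -50.0)) == "far_stationary"
        assert classify((100.0, -50.0)) == "contact"     # x == 100, closing
        assert classify((100.0, 50.0)) == "far_stationary"

    def test_control_classes(self):
        # approaching movement far from contact
        assert in_control_class(np.array([400.0]), np.array([-150.0]),
                                "approach_control")[0]
        # leaving movement starting far away
        assert in_control_class(np.array([300.0]), np.array([150.0]),
                                "leave_control")[0]
        assert not in_control_class(np.array([50.0]), np.array([150.0]),
                                    "leave_control")[0]


class TestImd:
    def test_three_four_five(self):
        a = np.tile([0.0, 0.0], (4, 1))
        b = np.tile([300.0, 400.0], (4, 1))
        assert np.allclose(imd_series(a, b), 500.0)

    def test_symmetric_in_tracks(self):
        rng = np.random.default_rng(1)
        a, b = rng.uniform(0, 453, (2, 50, 2))
        assert np.allclose(imd_series(a, b), imd_series(b, a))

    def test_length_mismatch_rejected(self):
        with pytest.raises(FormatError):
            imd_series(np.zeros((5, 2)), np.zeros((6, 2)))

    def test_random_control_mean_matches_uniform_square_constant(self):
        arena = 453.0
        out = imd_controls(
            [np.zeros((10, 2))], [np.zeros((10, 2))],
            arena_mm=arena, n_pairs=200_000, seed=4,
        )
        expect = UNIT_SQUARE_MEAN_DISTANCE * arena
        assert out["means"]["random"] == pytest.approx(expect, rel=0.01)

    def test_shuffled_mean_matches_observed_for_iid_positions(self):
        """With temporally i.i.d. positions, shuffling changes nothing in
        distribution: means agree within sampling error."""
        rng = np.random.default_rng(5)
        a = [rng.uniform(0, 453, (20_000, 2))]
        b = [rng.uniform(0, 453, (20_000, 2))]
        out = imd_controls(a, b, n_pairs=20_000, seed=6)
        assert out["means"]["shuffled"] == pytest.approx(
            out["means"]["observed"], rel=0.02
        )


class TestClassComposition:
    def _occ(self, triple, start=0):
        from soseq.kinematics import KinematicPoint

        return KinematicPoint(
            50.0, 10.0, SyntaxOccurrence(triple, start, start + 30)
        )

    def test_chi2_matches_textbook_formula(self):
        from scipy.stats import chi2_contingency

        table = np.array([[20, 5], [5, 20]])
        chi2, _, _, _ = chi2_contingency(table, correction=False)
        expected = np.outer(table.sum(1), table.sum(0)) / table.sum()
        oracle = ((table - expected) ** 2 / expected).sum()
        assert chi2 == pytest.approx(oracle, abs=1e-9)

    def test_family_concentrated_in_one_class_significant(self):
        rng = np.random.default_rng(2)
        n = 400
        labels = np.array(
            ["approach"] * 100 + ["leave"] * 100 + ["contact"] * 100
            + ["far_stationary"] * 100
        )
        fam_a = np.zeros(n, bool)
        fam_a[:80] = True       # family A almost only in approach
        fam_b = rng.random(n) < 0.25
        out = class_family_association(
            labels, {(9, 0, 5): fam_a, (11, 2, 8): fam_b}
        )
        res_a = next(r for r in out["tests"] if r.name == "(9, 0, 5)")
        res_b = next(r for r in out["tests"] if r.name == "(11, 2, 8)")
        assert res_a.significant and not res_b.significant
        assert out["residuals"].loc["(9, 0, 5)", "approach"] == (
            out["residuals"].loc["(9, 0, 5)"].max()
        )

    def test_uniform_families_type_one(self):
        n_sig = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            labels = rng.choice(PRIMARY_CLASSES, 400)
            flags = {
                (9, 0, 5): rng.random(400) < 0.3,
                (11, 2, 8): rng.random(400) < 0.3,
            }
            out = class_family_association(labels, flags)
            n_sig += sum(r.significant for r in out["tests"])
        assert n_sig <= 6

    def test_identical_compositions_zero_dkl(self):
        pts = [self._occ((1, 2, 3))] * 10
        labels = np.array(["approach"] * 5 + ["leave"] * 5)
        mat = class_dkl_matrix(labels, pts, 5)
        assert mat.loc["approach", "leave"] == pytest.approx(0.0, abs=1e-4)
        assert np.allclose(np.diagonal(mat)[np.isfinite(np.diagonal(mat))], 0)

    def test_shared_movement_core_structure(self):
        """Families sharing a movement-syllable core: approach and leave
        end up closer to each other than to the contact composition.  The
        planted families use the same three traversal syllables in
        opposite order (reorienting toward vs away), so their pooled
        syllable compositions coincide while the contact class carries the
        distinct contact repertoire."""
        from soseq.synthetic import SyntheticConfig, generate_experiment
        from soseq.syllables import extract_bouts
        from soseq.syntax import extract_syntaxes

        cfg = SyntheticConfig(
            seed=11,
            n_animals_per_context=8,
            duration_s=600,
            family_syntaxes=((9, 0, 5), (5, 0, 9)),
            # travel episodes short enough that the family triples cover
            # the whole approach/leave movement
            approach_s=1.44,
            leave_s=1.44,
        )
        ds, gt = generate_experiment(cfg)
        pts = []
        for rec in ds.by_context("dyadic"):
            a, b = rec.pair()
            imd = imd_series(rec.tracks[a], rec.tracks[b])
            for aid in (a, b):
                occs = extract_syntaxes(extract_bouts(rec.sequences[aid]))
                pts.extend(syntax_kinematics(occs, imd))
        x = np.array([p.x for p in pts])
        y = np.array([p.y for p in pts])
        labels = classify_points(x, y)
        mat = class_dkl_matrix(labels, pts, cfg.n_syllables)
        assert (
            mat.loc["approach", "leave"] < mat.loc["approach", "contact"]
        )


class TestPositionKde:
    def test_point_mass_concentrates(self):
        pos = np.tile([100.0, 300.0], (200, 1)) + np.random.default_rng(0).normal(
            0, 1.0, (200, 2)
        )
        out = position_kde(pos)
        dens = out["density"]
        i, j = np.unravel_index(np.argmax(dens), dens.shape)
        assert abs(out["grid"][i] - 100) < 15 and abs(out["grid"][j] - 300) < 15

    def test_uniform_corner_occupancy_matches_geometry(self):
        rng = np.random.default_rng(1)
        pos = rng.uniform(0, 453, (200_000, 2))
        out = position_kde(pos)
        # four quarter-discs of radius 100 inside the square
        expect = np.pi * 100**2 / 453**2
        assert out["corner_occupancy"] == pytest.approx(expect, rel=0.05)

    def test_density_integrates_to_one(self):
        rng = np.random.default_rng(2)
        pos = rng.uniform(50, 400, (5000, 2))
        out = position_kde(pos, grid_size=96)
        assert out["integral"] == pytest.approx(1.0, abs=0.05)

    def test_too_few_positions_rejected(self):
        with pytest.raises(FormatError):
            position_kde(np.zeros((10, 2)))


class TestPlantedEpisodes:
    def test_approach_episodes_classified_approach(self, planted):
        cfg, ds, gt = planted
        correct = total = 0
        for rec in ds.by_context("dyadic"):
            a, b = rec.pair()
            imd = imd_series(rec.tracks[a], rec.tracks[b])
            for ep in gt.episodes[rec.recording_id]:
                if ep.kind != "approach":
                    continue
                total += 1
                lab = classify(
                    (float(imd[ep.start]), float(imd[ep.end - 1] - imd[ep.start]))
                )
                correct += lab == "approach"
        assert total > 100
        assert correct / total >= 0.9
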