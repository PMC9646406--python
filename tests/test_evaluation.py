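import numpy as np
import pytest
from hypothesis import given, strategies as st

from longiseg.evaluation import (DetectionCounts, detection_metrics,
                                 dice_score, evaluate_case, evaluate_cohort,
                                 extract_lesions, hausdorff_distance,
                                 match_lesions, nlp_vlp)

from _oracles import (STENCIL_18, detection_counts_by_loop, dice_by_loop,
                      flood_fill_components, hausdorff_by_loop)


def _random_mask(rng, shape=(16, 16, 16), p=0.08):
    return (rng.random(shape) < p).astype(np.float32)


class TestDice:
    def test_identical_nonempty_masks_give_one(self):
        m = _random_mask(np.random.default_rng(0))
        m[0, 0, 0] = 1
        assert dice_score(m, m) == 1.0

    def test_disjoint_masks_give_zero(self):
        a = np.zeros((8, 8, 8)); a[:2] = 1
        b = np.zeros((8, 8, 8)); b[6:] = 1
        assert dice_score(a, b) == 0.0

    def test_shifted_cube_closed_form(self):
        # 4^3 cubes shifted by 2 along one axis: 2*32/(64+64) = 0.5
        g = np.zeros((12, 12, 12)); g[2:6, 4:8, 4:8] = 1
        y = np.zeros((12, 12, 12)); y[4:8, 4:8, 4:8] = 1
        assert dice_score(g, y) == pytest.approx(0.5)

    def test_empty_vs_empty_convention(self):
        z = np.zeros((4, 4, 4))
        assert dice_score(z, z) == 1.0

    def test_symmetry_and_oracle_agreement_random_masks(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            g, y = _random_mask(rng), _random_mask(rng)
            d = dice_score(g, y)
            assert d == pytest.approx(dice_score(y, g), abs=1e-12)
            assert d == pytest.approx(dice_by_loop(g, y), abs=1e-6)


class TestHausdorff:
    def test_identical_masks_give_zero(self):
        m = np.zeros((8, 8, 8)); m[2:5, 2:5, 2:5] = 1
        assert hausdorff_distance(m, m) == 0.0

    def test_two_single_voxels_five_apart(self):
        g = np.zeros((8, 8, 8)); g[1, 1, 1] = 1
        y = np.zeros((8, 8, 8)); y[6, 1, 1] = 1
        assert hausdorff_distance(g, y) == pytest.approx(5.0)

    def test_voxel_size_scales_distances(self):
        g = np.zeros((8, 8, 8)); g[1, 1, 1] = 1
        y = np.zeros((8, 8, 8)); y[3, 1, 1] = 1
        assert hausdorff_distance(g, y, (0.5, 1, 1)) == pytest.approx(1.0)

    def test_empty_mask_is_undefined(self):
        m = np.zeros((4, 4, 4)); m[1, 1, 1] = 1
        with pytest.raises(ValueError):
            hausdorff_distance(m, np.zeros((4, 4, 4)))

    def test_matches_brute_force_on_random_masks(self):
        rng = np.random.default_rng(2)
        for i in range(15):
            g = _random_mask(rng, (12, 12, 12), p=0.1)
            y = _random_mask(rng, (12, 12, 12), p=0.1)
            if not g.any() or not y.any():
                continue
            voxel = (0.6, 0.98, 0.98) if i % 2 else (1.0, 1.0, 1.0)
            assert hausdorff_distance(g, y, voxel) == pytest.approx(
                hausdorff_by_loop(g, y, voxel), abs=1e-6)


class TestExtractLesions:
    def test_corner_touching_cubes_are_separate_under_18_connectivity(self):
        m = np.zeros((8, 8, 8))
        m[2:4, 2:4, 2:4] = 1
        m[4:6, 4:6, 4:6] = 1  # touches only through the corner voxel diagonal
        lesions = extract_lesions(m, min_volume_mm3=0.0)
        assert lesions.n_lesions == 2

    def test_edge_touching_cubes_merge_under_18_connectivity(self):
        m = np.zeros((8, 8, 8))
        m[2:4, 2:4, 2:4] = 1
        m[4:6, 4:6, 2:4] = 1  # shares an edge
        assert extract_lesions(m, min_volume_mm3=0.0).n_lesions == 1

    def test_minimum_volume_filter_boundary(self):
        single = np.zeros((8, 8, 8)); single[3, 3, 3] = 1
        assert extract_lesions(single).n_lesions == 0  # 1 mm^3 < 3
        rod = np.zeros((8, 8, 8)); rod[3, 3, 2:5] = 1
        assert extract_lesions(rod).n_lesions == 1     # 3 mm^3 kept

    def test_volumes_use_voxel_volume(self):
        m = np.zeros((8, 8, 8)); m[2:4, 2:4, 2:4] = 1
        lesions = extract_lesions(m, voxel_size=(0.5, 0.5, 0.5),
                                  min_volume_mm3=0.0)
        assert lesions.volumes_mm3 == [pytest.approx(8 * 0.125)]

    def test_labels_match_flood_fill_oracle_on_random_masks(self):
        rng = np.random.default_rng(3)
        for _ in range(30):
            m = _random_mask(rng, p=0.15)
            ours = extract_lesions(m, min_volume_mm3=0.0)
            ref = flood_fill_components(m, STENCIL_18)
            assert ours.n_lesions == ref.max()
            # same partition up to label permutation
            for lbl in range(1, ours.n_lesions + 1):
                sel = ours.labels == lbl
                assert len(np.unique(ref[sel])) == 1


class TestDetection:
    def test_perfect_prediction_counts(self):
        rng = np.random.default_rng(4)
        m = np.zeros((12, 12, 12))
        m[1:4, 1:4, 1:4] = 1
        m[7:10, 7:10, 7:10] = 1
        g = extract_lesions(m)
        counts = match_lesions(g, extract_lesions(m.copy()))
        assert (counts.tp, counts.fp, counts.fn) == (2, 0, 0)

    def test_empty_prediction_all_missed(self):
        m = np.zeros((16, 16, 16))
        for c in [(2, 2, 2), (8, 8, 8), (13, 13, 2)]:
            m[c[0]:c[0] + 2, c[1]:c[1] + 2, c[2]:c[2] + 2] = 1
        counts = match_lesions(extract_lesions(m),
                               extract_lesions(np.zeros_like(m)))
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 3)

    def test_low_coverage_is_missed_but_not_false_positive(self):
        g = np.zeros((12, 12, 12)); g[1:6, 1:6, 1:5] = 1  # 100 voxels
        y = np.zeros((12, 12, 12)); y[1, 1, 1:6] = 1      # 5 inside truth
        counts = match_lesions(extract_lesions(g), extract_lesions(y),
                               overlap_fraction=0.1)
        assert (counts.tp, counts.fp, counts.fn) == (0, 0, 1)

    def test_matches_loop_oracle_on_random_masks(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            g = extract_lesions(_random_mask(rng, p=0.1), min_volume_mm3=0.0)
            y = extract_lesions(_random_mask(rng, p=0.1), min_volume_mm3=0.0)
            counts = match_lesions(g, y, overlap_fraction=0.1)
            ref = detection_counts_by_loop(g.labels, y.labels, 0.1)
            assert (counts.tp, counts.fp, counts.fn) == ref

    def test_detection_metric_arithmetic(self):
        sen, ppv, f1 = detection_metrics(DetectionCounts(tp=2, fp=1, fn=2))
        assert (sen, ppv) == (0.5, pytest.approx(2 / 3))
        assert f1 == pytest.approx(4 / 7)

    def test_nothing_to_detect_convention(self):
        assert detection_metrics(DetectionCounts(0, 0, 0)) == (1.0, 1.0, 1.0)

    @given(tp=st.integers(0, 5), fp=st.integers(0, 5), fn=st.integers(0, 5))
    def test_f1_is_harmonic_mean_of_sen_and_ppv(self, tp, fp, fn):
        sen, ppv, f1 = detection_metrics(DetectionCounts(tp, fp, fn))
        if tp and (sen + ppv):
            assert f1 == pytest.approx(2 * sen * ppv / (sen + ppv))


class TestNlpVlp:
    def test_empty_mask(self):
        assert nlp_vlp(np.zeros((8, 8, 8))) == (0, 0.0)

    def test_single_lesion_volume(self):
        m = np.zeros((8, 8, 8)); m[2:4, 2:4, 2:4] = 1; m[2, 2, 4] = 1; m[5, 5, 5] = 1
        nlp, vlp = nlp_vlp(m)
        assert nlp == 2  # no minimum-size filter on the count
        assert vlp == pytest.approx(10.0)

    def test_two_lesions_and_voxel_volume(self):
        m = np.zeros((10, 10, 10))
        m[1:3, 1:3, 1] = 1          # 4 voxels
        m[6:9, 6:8, 6] = 1          # 6 voxels
        nlp, vlp = nlp_vlp(m, voxel_size=(1, 1, 1))
        assert (nlp, vlp) == (2, pytest.approx(10.0))


class TestCohort:
    def _two_lesion_mask(self):
        m = np.zeros((16, 16, 16))
        m[2:5, 2:5, 2:5] = 1
        m[10:13, 10:13, 10:13] = 1
        return m

    def test_perfect_cohort_means(self):
        m = self._two_lesion_mask()
        per_case, summary = evaluate_cohort(
            ["a", "b"], [m, m], [m.copy(), m.copy()])
        row = summary[summary.stratum == "with_new_lesions"].iloc[0]
        assert row.dice_mean == 1.0 and row.dice_sd == 0.0
        assert row.f1_mean == 1.0

    def test_stratification_counts_sum_to_cohort_size(self):
        m = self._two_lesion_mask()
        z = np.zeros_like(m)
        per_case, summary = evaluate_cohort(
            ["a", "b", "c"], [m, z, m], [m.copy(), z.copy(), z.copy()])
        assert summary.n_cases.sum() == 3
        assert per_case.has_new_lesions.tolist() == [True, False, True]

    def test_summary_matches_hand_recomputation(self):
        rng = np.random.default_rng(6)
        truths, preds = [], []
        for _ in range(5):
            g = _random_mask(rng, p=0.05)
            y = np.logical_and(g, _random_mask(rng, p=0.9)).astype(np.float32)
            truths.append(g)
            preds.append(y)
        per_case, summary = evaluate_cohort(list("abcde"), truths, preds)
        with_l = per_case[per_case.has_new_lesions]
        row = summary[summary.stratum == "with_new_lesions"].iloc[0]
        assert row.dice_mean == pytest.approx(with_l.dice.mean())
        assert row.sen_sd == pytest.approx(with_l.sen.std(ddof=1))

    def test_no_lesion_case_reports_nlp_vlp_only(self):
        z = np.zeros((8, 8, 8))
        y = np.zeros((8, 8, 8)); y[2:4, 2:4, 2:4] = 1
        m = evaluate_case("x", z, y)
        assert not m.has_new_lesions
        assert m.nlp == 1 and m.vlp == pytest.approx(8.0)
        assert m.dice is None


def test_metrics_invariant_to_lesion_relabeling():
    rng = np.random.default_rng(7)
    m = _random_mask(rng, p=0.12)
    a = extract_lesions(m, min_volume_mm3=0.0)
    # relabel by permuting component ids
    perm = np.random.default_rng(1).permutation(a.n_lesions) + 1
    relabeled = np.zeros_like(a.labels)
    for old, new in enumerate(perm, start=1):
        relabeled[a.labels == old] = new
    b_labels = a.labels.copy()
    y = extract_lesions(_random_mask(rng, p=0.12), min_volume_mm3=0.0)
    from longiseg.evaluation import LesionSet
    b = LesionSet(relabeled, a.voxel_counts, a.volumes_mm3)
    ca = match_lesions(a, y, 0.1)
    cb = match_lesions(b, y, 0.1)
    assert (ca.tp, ca.fp, ca.fn) == (cb.tp, cb.fp, cb.fn)
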