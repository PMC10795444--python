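"""Evaluation metrics against independent brute-force oracles."""

import numpy as np
import pytest

from hnseg.metrics import (
    EmptyMaskError,
    batch_report,
    boundary_voxels,
    evaluate_case,
    hausdorff,
    overlap_metrics,
)


def counting_oracle(pred, ref):
    """Overlap metrics by explicit voxel counting."""
    tp = fp = fn = 0
    for a, b in zip(pred.ravel(), ref.ravel()):
        if a and b:
            tp += 1
        elif a and not b:
            fp += 1
        elif b and not a:
            fn += 1
    na, nb = tp + fp, tp + fn
    if na == 0 and nb == 0:
        return 1.0, 1.0, 1.0, 1.0
    dice = 2 * tp / (na + nb)
    jac = tp / (na + nb - tp) if (na + nb - tp) else 1.0
    return (dice, jac, tp / na if na else 0.0, tp / nb if nb else 0.0)


def hausdorff_oracle(a, b, spacing):
    """All-pairs maximum over boundary voxels, no spatial index."""
    pa = boundary_voxels(a) * np.asarray(spacing)
    pb = boundary_voxels(b) * np.asarray(spacing)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


def random_mask_pair(rng, shape=(6, 10, 10)):
    while True:
        a = rng.random(shape) > 0.7
        b = rng.random(shape) > 0.7
        if a.any() and b.any():
            return a, b


class TestOverlap:
    def test_identical_masks_are_perfect(self, rng):
        m = rng.random((4, 8, 8)) > 0.5
        assert overlap_metrics(m, m) == (1.0, 1.0, 1.0, 1.0)

    def test_disjoint_masks_are_zero(self):
        a = np.zeros((2, 4, 4), bool)
        b = np.zeros((2, 4, 4), bool)
        a[0, :2], b[1, 2:] = True, True
        assert overlap_metrics(a, b) == (0.0, 0.0, 0.0, 0.0)

    def test_half_contained_prediction(self):
        # |A| = 50 entirely inside |B| = 100
        b = np.zeros((1, 10, 10), bool)
        b[0] = True
        a = np.zeros_like(b)
        a[0, :5] = True
        dice, jac, prec, rec = overlap_metrics(a, b)
        assert dice == pytest.approx(2 / 3)
        assert jac == pytest.approx(0.5)
        assert prec == 1.0 and rec == 0.5

    def test_empty_mask_conventions(self):
        empty = np.zeros((2, 3, 3), bool)
        full = ~empty
        assert overlap_metrics(empty, empty) == (1.0, 1.0, 1.0, 1.0)
        assert overlap_metrics(full, empty) == (0.0, 0.0, 0.0, 0.0)
        assert overlap_metrics(empty, full) == (0.0, 0.0, 0.0, 0.0)

    def test_matches_counting_oracle_and_identities(self, rng):
        for _ in range(100):
            a, b = random_mask_pair(rng)
            got = overlap_metrics(a, b)
            expected = counting_oracle(a, b)
            assert got == pytest.approx(expected, abs=0)
            dice, jac, prec, rec = got
            assert dice == pytest.approx(2 * jac / (1 + jac), abs=1e-12)
            if prec + rec > 0:
                assert dice == pytest.approx(
                    2 * prec * rec / (prec + rec), abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            overlap_metrics(np.zeros((2, 2)), np.zeros((3, 3)))


class TestHausdorff:
    SPACING = (3.0, 1.0, 1.0)

    def test_identical_masks_give_zero(self, rng):
        m = rng.random((3, 6, 6)) > 0.5
        m[0, 0, 0] = True
        assert hausdorff(m, m, self.SPACING) == 0.0

    def test_single_voxels_euclidean_distance(self):
        a = np.zeros((1, 8, 8), bool)
        b = np.zeros_like(a)
        a[0, 2, 2] = True
        b[0, 2, 5] = True
        assert hausdorff(a, b, (1.0, 1.0, 1.0)) == pytest.approx(3.0)

    def test_spacing_scales_distances(self):
        a = np.zeros((4, 4, 4), bool)
        b = np.zeros_like(a)
        a[1, 1, 1] = True
        b[2, 1, 1] = True  # one slice apart at 3 mm thickness
        assert hausdorff(a, b, (3.0, 1.0, 1.0)) == pytest.approx(3.0)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            a, b = random_mask_pair(rng, shape=(4, 7, 7))
            got = hausdorff(a, b, self.SPACING)
            assert got == pytest.approx(
                hausdorff_oracle(a, b, self.SPACING), abs=1e-12)

    def test_symmetry(self, rng):
        a, b = random_mask_pair(rng)
        assert hausdorff(a, b, self.SPACING) == \
            hausdorff(b, a, self.SPACING)

    def test_empty_mask_is_an_error_not_zero(self):
        m = np.ones((2, 3, 3), bool)
        with pytest.raises(EmptyMaskError):
            hausdorff(m, np.zeros_like(m), self.SPACING)

    def test_translation_invariance(self, rng):
        a, b = random_mask_pair(rng, shape=(3, 6, 6))
        pad = [(1, 1)] * 3
        a2, b2 = np.pad(a, pad), np.pad(b, pad)
        assert hausdorff(a, b, self.SPACING) == pytest.approx(
            hausdorff(a2, b2, self.SPACING))
        assert overlap_metrics(a, b) == overlap_metrics(a2, b2)


class TestBatchReport:
    def test_single_case_aggregate_equals_case(self, rng):
        a, b = random_mask_pair(rng)
        df = batch_report([(a, b)], spacing=(3.0, 1.0, 1.0))
        case, mean = df.iloc[0], df[df.case_id == "mean"].iloc[0]
        assert mean.dice == case.dice
        assert mean.hausdorff_mm == case.hausdorff_mm

    def test_mean_of_two_cases(self):
        b = np.ones((1, 10, 10), bool)
        a8 = np.zeros_like(b); a8[0, :, :] = True; a8[0, 0, :5] = False
        # craft Dice 0.8 and 0.6 pairs via contained predictions:
        # |A| inside |B|=100 with dice 2a/(a+100)
        a_d08 = np.zeros_like(b); a_d08.ravel()[:round(100 * 0.8 / 1.2)] = True
        a_d06 = np.zeros_like(b); a_d06.ravel()[:round(100 * 0.6 / 1.4)] = True
        df = batch_report([(a_d08, b), (a_d06, b)])
        d1 = overlap_metrics(a_d08, b)[0]
        d2 = overlap_metrics(a_d06, b)[0]
        assert df[df.case_id == "mean"].dice.iloc[0] == \
            pytest.approx((d1 + d2) / 2)

    def test_csv_round_trip_preserves_aggregates(self, tmp_path, rng):
        import pandas as pd
        pairs = [random_mask_pair(rng) for _ in range(3)]
        df = batch_report(pairs, spacing=(3.0, 1.0, 1.0))
        path = tmp_path / "report.csv"
        df.to_csv(path, index=False)
        back = pd.read_csv(path)
        per_case = back[~back.case_id.isin(["mean", "sd"])]
        assert per_case.dice.mean() == pytest.approx(
            back[back.case_id == "mean"].dice.iloc[0])

    def test_empty_hd_recorded_as_missing(self):
        a = np.ones((1, 4, 4), bool)
        r = evaluate_case(a, np.zeros_like(a), spacing=(1.0, 1.0, 1.0))
        assert r.hausdorff_mm is None and r.dice == 0.0
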