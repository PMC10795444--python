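"""Uncertainty scoring chain and top-fraction candidate selection."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hnseg.selection import (
    SampleScore,
    case_score,
    edge_uncertainty,
    image_score,
    laplacian,
    pixel_uncertainty,
    score_case,
    select_top_fraction,
)


class TestPixelUncertainty:
    def test_branch_values(self):
        p = np.array([[0.0, 0.5, 1.0], [0.3, 0.7, 0.25]])
        u = pixel_uncertainty(p).values
        np.testing.assert_allclose(u, [[0.0, 0.5, 0.0], [0.3, 0.3, 0.25]])

    @given(st.floats(0.0, 1.0, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_symmetry_and_range(self, p):
        arr = np.full((3, 3), p)
        u = pixel_uncertainty(arr).values
        u_flip = pixel_uncertainty(1.0 - arr).values
        np.testing.assert_allclose(u, u_flip, atol=1e-15)
        assert 0.0 <= u.max() <= 0.5

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pixel_uncertainty(np.array([[1.5]]))


class TestLaplacian:
    def test_constant_image_maps_to_zero_everywhere(self):
        np.testing.assert_array_equal(laplacian(np.full((5, 7), 3.2)),
                                      np.zeros((5, 7)))

    def test_unit_impulse_gives_stencil(self):
        img = np.zeros((5, 5))
        img[2, 2] = 1.0
        out = laplacian(img)
        assert out[2, 2] == -4.0
        for r, c in [(1, 2), (3, 2), (2, 1), (2, 3)]:
            assert out[r, c] == 1.0
        assert np.count_nonzero(out) == 5

    def test_linear_ramp_zero_in_interior(self):
        x = np.arange(6, dtype=float)[:, None] * np.ones(8)
        out = laplacian(x)
        np.testing.assert_array_equal(out[1:-1, 1:-1], 0.0)

    def test_small_image_rejected(self):
        with pytest.raises(ValueError):
            laplacian(np.zeros((2, 5)))


class TestEdgeUncertainty:
    def test_uniform_map_has_no_edges(self):
        g = edge_uncertainty(pixel_uncertainty(np.full((6, 6), 0.4))).values
        np.testing.assert_array_equal(g, 0.0)

    def test_step_edge_support_is_one_pixel_wide(self):
        u = np.zeros((12, 12))
        u[3:9, 4:10] = 0.5
        g = edge_uncertainty(u).values
        inside = np.zeros_like(u, bool)
        inside[3:9, 4:10] = True
        boundary_band = np.zeros_like(u, bool)
        boundary_band[2:10, 3:11] = True
        boundary_band[4:8, 5:9] = False
        assert (g[~boundary_band] == 0).all()
        assert g[boundary_band].max() > 0

    def test_doubling_u_doubles_g(self, rng):
        u = rng.random((8, 8)) * 0.25
        np.testing.assert_allclose(edge_uncertainty(2 * u).values,
                                   2 * edge_uncertainty(u).values)

    def test_magnitude_is_non_negative(self, rng):
        g = edge_uncertainty(rng.random((6, 6)) * 0.5).values
        assert (g >= 0).all()


class TestScores:
    def test_mean_of_constant_map(self):
        assert image_score(np.full((4, 4), 0.125)) == pytest.approx(0.125)

    def test_single_entry_average(self):
        g = np.zeros((4, 4))
        g[1, 2] = 8.0
        assert image_score(g) == pytest.approx(0.5)

    def test_zero_map_scores_zero(self):
        assert image_score(np.zeros((4, 4))) == 0.0

    def test_confident_probability_map_scores_zero(self):
        p = np.zeros((8, 8))  # hard background everywhere
        assert score_case(p).un == 0.0

    def test_case_aggregation(self):
        assert case_score([0.1, 0.3]) == pytest.approx(0.2)
        assert case_score([0.1, 0.3], aggregate="max") == pytest.approx(0.3)
        assert case_score([0.7]) == 0.7
        assert case_score([0.3, 0.1]) == case_score([0.1, 0.3])
        with pytest.raises(ValueError):
            case_score([])


def make_scores(values):
    return [SampleScore(case_id=f"c{i:02d}", un=v, per_slice=[(0, v)], m=16)
            for i, v in enumerate(values)]


class TestSelectTopFraction:
    def test_ten_samples_pick_three_largest(self, rng):
        vals = list(rng.random(10))
        rnd = select_top_fraction(make_scores(vals), fraction=0.3)
        assert len(rnd.selected_ids) == 3
        top3 = sorted(vals, reverse=True)[:3]
        got = [s.un for s in rnd.ranked_scores[:3]]
        assert sorted(got, reverse=True) == sorted(top3, reverse=True)
        assert min(got) >= max(s.un for s in rnd.ranked_scores[3:])

    def test_fraction_one_selects_all(self):
        rnd = select_top_fraction(make_scores([0.1, 0.2]), fraction=1.0)
        assert sorted(rnd.selected_ids) == ["c00", "c01"]

    def test_floor_rounding_on_thirty(self):
        rnd = select_top_fraction(make_scores(np.linspace(0, 1, 30)))
        assert len(rnd.selected_ids) == math.floor(0.3 * 30) == 9

    def test_minimum_one_selected(self):
        rnd = select_top_fraction(make_scores([0.5, 0.4]), fraction=0.3)
        assert rnd.selected_ids == ["c00"]

    def test_ties_broken_by_case_id(self):
        rnd = select_top_fraction(make_scores([0.5, 0.5, 0.5]), fraction=0.34)
        assert rnd.selected_ids == ["c00"]

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            select_top_fraction([])


@pytest.fixture(scope="module")
def small_setup():
    from hnseg.model import ModelConfig, build_model
    from hnseg.phantom import (PhantomSpec, generate_phantom_pool,
                               pool_to_cases, pool_to_dataset)
    spec = PhantomSpec(image_size=16, n_slices=2,
                       organ_axes_inplane=(3.0, 5.0),
                       organ_axes_slices=(1.0, 1.5))
    local = pool_to_dataset(generate_phantom_pool(spec, 2, seed=1))
    pool = pool_to_cases(generate_phantom_pool(spec, 10, seed=2,
                                               shifted=True,
                                               id_prefix="pub"))
    model = build_model(ModelConfig(input_size=16, depth=2,
                                    base_channels=2, seed=0))
    return model, local, pool


class TestWorkflow:
    def test_two_rounds_select_disjoint_cases(self, small_setup):
        from hnseg.selection import run_selection_workflow
        from hnseg.training import TrainConfig
        model, local, pool = small_setup
        _, rounds = run_selection_workflow(
            model, local, pool, TrainConfig(epochs=1, seed=0, batch_size=4))
        assert [len(r.selected_ids) for r in rounds] == [3, 2]
        assert not set(rounds[0].selected_ids) & set(rounds[1].selected_ids)
        # round-2 ranking never re-lists round-1 picks
        assert not set(rounds[0].selected_ids) & set(rounds[1].pool_ids)
        # audit trail reconstructs pool membership exactly
        assert sorted(rounds[0].pool_ids) == sorted(pool.keys())

    def test_zero_iterations_is_a_no_op(self, small_setup):
        from hnseg.selection import run_selection_workflow
        from hnseg.training import TrainConfig
        model, local, pool = small_setup
        before = {k: v.copy() for k, v in model.state_dict().items()}
        out, rounds = run_selection_workflow(
            model, local, pool, TrainConfig(epochs=1, seed=0),
            iterations=0)
        assert rounds == []
        after = out.state_dict()
        assert all(np.array_equal(before[k], after[k]) for k in before)
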