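"""NCC core: definition, fast-path agreement, invariances, error handling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import ncc_brute
from nccount import (
    InvalidTemplateError,
    RangeError,
    SampleImage,
    SizeError,
    Template,
    max_over_library,
    ncc_at_point,
    ncc_surface,
    preset_pattern,
)
from nccount.errors import ConfigurationError


def _random_pair(rng, sample_shape=(12, 12), tpl_shape=(3, 3)):
    sample = SampleImage(rng.uniform(0, 255, sample_shape))
    tpl = Template("t", rng.uniform(0, 255, tpl_shape))
    return sample, tpl


def test_identical_window_scores_one():
    rng = np.random.default_rng(0)
    sample, _ = _random_pair(rng, (10, 10))
    tpl = Template("w", sample.pixels[2:6, 3:7])
    assert ncc_at_point(sample, tpl, 2, 3) == pytest.approx(1.0, abs=1e-12)


def test_negative_affine_window_scores_minus_one():
    rng = np.random.default_rng(1)
    tpl_px = rng.uniform(0, 50, (4, 4))
    sample = SampleImage(-2.0 * tpl_px + 10.0)
    assert ncc_at_point(sample, Template("t", tpl_px), 0, 0) == pytest.approx(-1.0, abs=1e-12)


def test_point_matches_brute_force_oracle_at_all_offsets():
    rng = np.random.default_rng(2)
    sample, tpl = _random_pair(rng)
    for i in range(sample.M - tpl.K + 1):
        for j in range(sample.N - tpl.L + 1):
            expected = ncc_brute(sample.pixels, tpl.pixels, i, j)
            assert ncc_at_point(sample, tpl, i, j) == pytest.approx(expected, abs=1e-9)


def test_zero_variance_window_scores_zero():
    sample = SampleImage(np.full((6, 6), 9.0))
    tpl = Template("t", np.arange(9.0).reshape(3, 3))
    assert ncc_at_point(sample, tpl, 1, 1) == 0.0


def test_offset_out_of_range_raises():
    rng = np.random.default_rng(3)
    sample, tpl = _random_pair(rng)
    with pytest.raises(RangeError):
        ncc_at_point(sample, tpl, sample.M - tpl.K + 1, 0)
    with pytest.raises(RangeError):
        ncc_at_point(sample, tpl, 0, -1)


def test_constant_template_rejected():
    with pytest.raises(InvalidTemplateError):
        Template("flat", np.full((3, 3), 5.0))


def test_template_larger_than_sample_raises():
    rng = np.random.default_rng(4)
    sample = SampleImage(rng.uniform(0, 1, (4, 4)))
    tpl = Template("big", rng.uniform(0, 1, (6, 6)))
    with pytest.raises(SizeError):
        ncc_surface(sample, tpl)


def test_surface_shape_and_range():
    rows = np.linspace(0, 1, 10)[:, None] * np.ones(10)
    sample = SampleImage(rows * 100 + np.arange(10))
    tpl = Template("g", np.outer(np.arange(3.0), np.ones(3)) + np.arange(3))
    surf = ncc_surface(sample, tpl)
    assert surf.shape == (8, 8)
    assert surf.evaluated.all()
    assert np.all(surf.values >= -1 - 1e-9) and np.all(surf.values <= 1 + 1e-9)


@pytest.mark.parametrize("pair_seed", range(10))
def test_fast_surface_matches_point_reference(pair_seed):
    rng = np.random.default_rng(100 + pair_seed)
    shape = tuple(rng.integers(8, 33, 2))
    tshape = tuple(rng.integers(2, 8, 2))
    sample, tpl = _random_pair(rng, shape, tshape)
    surf = ncc_surface(sample, tpl)
    for i in range(surf.shape[0]):
        for j in range(surf.shape[1]):
            assert surf.values[i, j] == pytest.approx(
                ncc_at_point(sample, tpl, i, j), abs=1e-6
            )


def test_fast_surface_matches_skimage_reference():
    """Independent library cross-check of the whole surface."""
    skimage_feature = pytest.importorskip("skimage.feature")
    rng = np.random.default_rng(11)
    sample, tpl = _random_pair(rng, (25, 30), (5, 4))
    ours = ncc_surface(sample, tpl).values
    theirs = skimage_feature.match_template(sample.pixels, tpl.pixels, pad_input=False)
    np.testing.assert_allclose(ours, theirs, atol=1e-6)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(a=st.floats(0.1, 50), b=st.floats(-100, 100), seed=st.integers(0, 100))
def test_affine_invariance_of_sample(a, b, seed):
    rng = np.random.default_rng(seed)
    sample, tpl = _random_pair(rng, (10, 10))
    base = ncc_surface(sample, tpl).values
    scaled = ncc_surface(SampleImage(a * sample.pixels + b), tpl).values
    np.testing.assert_allclose(base, scaled, atol=1e-6)


def test_symmetry_when_shapes_match():
    rng = np.random.default_rng(12)
    a = rng.uniform(0, 10, (5, 5))
    b = rng.uniform(0, 10, (5, 5))
    r1 = ncc_at_point(SampleImage(a), Template("b", b), 0, 0)
    r2 = ncc_at_point(SampleImage(b), Template("a", a), 0, 0)
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_pattern_suppresses_exactly_off_lattice_offsets():
    rng = np.random.default_rng(13)
    sample, tpl = _random_pair(rng, (20, 20))
    pattern = preset_pattern(3)  # stride 2 in both axes
    full = ncc_surface(sample, tpl)
    sparse = ncc_surface(sample, tpl, pattern=pattern)
    rows, cols = np.indices(sparse.shape)
    lattice = (rows % 2 == 0) & (cols % 2 == 0)
    assert np.array_equal(sparse.evaluated, lattice)
    np.testing.assert_allclose(sparse.values[lattice], full.values[lattice], atol=1e-12)


def test_full_mask_pattern_is_identity():
    from nccount import SkipPattern

    rng = np.random.default_rng(14)
    sample, tpl = _random_pair(rng, (15, 15))
    full_pattern = SkipPattern("full", np.ones((1, 1), dtype=bool))
    a = ncc_surface(sample, tpl)
    b = ncc_surface(sample, tpl, pattern=full_pattern)
    assert np.array_equal(a.evaluated, b.evaluated)
    np.testing.assert_allclose(a.values, b.values)


class TestMaxOverLibrary:
    def test_single_template_equals_its_surface(self):
        rng = np.random.default_rng(15)
        sample, tpl = _random_pair(rng, (15, 15))
        solo = ncc_surface(sample, tpl)
        combined = max_over_library(sample, [tpl])
        np.testing.assert_allclose(combined.values, solo.values, atol=1e-12)

    def test_duplicate_template_is_idempotent(self):
        rng = np.random.default_rng(16)
        sample, tpl = _random_pair(rng, (15, 15))
        dup = Template("t2", tpl.pixels.copy())
        one = max_over_library(sample, [tpl])
        two = max_over_library(sample, [tpl, dup])
        np.testing.assert_allclose(one.values, two.values, atol=1e-12)

    def test_three_templates_match_naive_pointwise_max(self):
        rng = np.random.default_rng(17)
        sample = SampleImage(rng.uniform(0, 255, (15, 15)))
        tpls = [Template(f"t{k}", rng.uniform(0, 255, (3, 3))) for k in range(3)]
        combined = max_over_library(sample, tpls)
        for i in range(combined.shape[0]):
            for j in range(combined.shape[1]):
                vals = [ncc_brute(sample.pixels, t.pixels, i, j) for t in tpls]
                assert combined.values[i, j] == pytest.approx(max(vals), abs=1e-6)
                assert combined.template_ids[combined.best_template[i, j]] == tpls[
                    int(np.argmax(vals))
                ].id

    def test_empty_and_mixed_shape_libraries_rejected(self):
        rng = np.random.default_rng(18)
        sample = SampleImage(rng.uniform(0, 1, (10, 10)))
        with pytest.raises(ConfigurationError):
            max_over_library(sample, [])
        mixed = [
            Template("a", rng.uniform(0, 1, (3, 3))),
            Template("b", rng.uniform(0, 1, (4, 4))),
        ]
        with pytest.raises(ConfigurationError):
            max_over_library(sample, mixed)
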