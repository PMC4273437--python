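"""Registration cascade: metrics, tile search, affine, demons, gating."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mbatlas.registration import (
    SimilarityScore,
    SpatialTransform,
    align_before_after,
    blended_similarity,
    gate_specimens,
    locate_tile,
    mutual_information,
    normalized_cross_correlation,
    register_affine,
    register_deformable,
)
from mbatlas.phantom import smooth_random_field
from mbatlas.volume import Volume


def test_metric_identities(rng):
    a = rng.normal(size=(16, 16, 16))
    assert normalized_cross_correlation(a, a) == pytest.approx(1.0)
    assert mutual_information(a, a) == pytest.approx(1.0, abs=1e-6)
    assert mutual_information(a, a[::-1]) == pytest.approx(
        mutual_information(a[::-1], a), abs=1e-9
    )
    s = blended_similarity(a, a)
    assert s.blended == pytest.approx(1.0, abs=1e-6)


def test_locate_tile_exact_crop(std):
    tile = Volume(std.reference.data[10:42, 20:84, 30:94], std.reference.spacing)
    offset, peak = locate_tile(tile, std.reference)
    assert peak == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(offset, [10, 20, 30], atol=1e-9)


def test_locate_tile_degenerate_and_size_errors(std):
    flat = Volume(np.ones((8, 8, 8)), std.reference.spacing)
    with pytest.raises(ValueError, match="constant"):
        locate_tile(flat, std.reference)
    big = Volume(np.zeros((200, 200, 200)), std.reference.spacing)
    with pytest.raises(ValueError, match="larger"):
        locate_tile(big, std.reference)


def test_register_affine_identity_pair(small_std):
    fixed = small_std.reference
    t, score = register_affine(fixed, fixed, maxiter=15)
    assert score.ncc >= 0.99
    # near-identity: displacement of the center stays well below a voxel
    c = np.array(fixed.physical_extent()) / 2
    assert np.linalg.norm(t.map_points(c[None])[0] - c) < 0.76


def test_register_affine_disjoint_extents(small_std):
    far = Volume(small_std.reference.data.copy(), small_std.reference.spacing,
                 origin=(1e5, 1e5, 1e5))
    with pytest.raises(ValueError, match="overlap"):
        register_affine(far, small_std.reference, maxiter=2)


def test_register_deformable_zero_pair(small_std):
    fixed = small_std.reference
    t, score = register_deformable(fixed, fixed, SpatialTransform(),
                                   iterations=(8, 4), pyramid=(4, 2))
    max_u_vox = 0.0 if t.field is None else float(np.abs(t.field).max()) / 0.76
    assert max_u_vox < 0.25


def test_register_deformable_recovers_smooth_field(std):
    """Warp by a known smooth field (max 4 voxels); residual p90 < 1 voxel."""
    fixed = std.reference
    p90s = []
    for seed in range(5):
        rng = np.random.default_rng(seed)
        field = smooth_random_field(fixed.shape, fixed.spacing, 4.0, 8.0, rng)
        t_true = SpatialTransform(np.eye(3), np.zeros(3), field, fixed.spacing)
        moving = t_true.apply(fixed, fixed)
        t_hat, score = register_deformable(moving, fixed, SpatialTransform(),
                                           iterations=(25, 15, 5))
        assert t_hat.min_jacobian_det() > 0
        pts = np.indices(fixed.shape, dtype=float).reshape(3, -1).T * 0.76
        resid = np.linalg.norm(
            t_true.map_points(t_hat.map_points(pts)) - pts, axis=1
        ) / 0.76
        p90s.append(np.percentile(resid[std.lobe_mask.ravel()], 90))
    assert max(p90s) < 1.0, p90s


def test_register_deformable_pathological_pair_flagged_not_crashed():
    """A checker vs its 180° rotation: score fails to improve, no crash."""
    checker = np.indices((24, 24, 24)).sum(axis=0) % 8 < 4
    fixed = Volume(checker.astype(float), (1.0, 1.0, 1.0))
    moving = Volume(checker[::-1, ::-1, ::-1].astype(float), (1.0, 1.0, 1.0))
    t, score = register_deformable(moving, fixed, SpatialTransform(),
                                   iterations=(5, 3), pyramid=(4, 2))
    assert np.isfinite(score.blended)   # flagged by its low score, not a crash


def test_transform_inverse_roundtrip(std):
    rng = np.random.default_rng(7)
    field = smooth_random_field(std.reference.shape, std.reference.spacing,
                                3.0, 8.0, rng)
    t = SpatialTransform(np.eye(3) * 1.03, np.array([1.0, -2.0, 0.5]),
                         field, std.reference.spacing)
    pts = np.indices((20, 20, 20), dtype=float).reshape(3, -1).T * 2.0 + 10.0
    back = t.numerical_inverse(t.map_points(pts))
    assert np.linalg.norm(back - pts, axis=1).mean() / 0.76 < 0.25


def test_align_before_after_subvoxel_shift(small_std):
    from scipy import ndimage

    pre = small_std.reference
    shift = np.array([0.4, -1.2, 0.0])
    shifted = np.fft.ifftn(
        ndimage.fourier_shift(np.fft.fftn(pre.data), shift)
    ).real
    post = Volume(shifted, pre.spacing)
    est, aligned, low = align_before_after(pre, post, upsample_factor=50)
    assert not low
    np.testing.assert_allclose(est, shift, atol=0.1)
    assert normalized_cross_correlation(pre.data, aligned.data) > 0.99


def test_align_before_after_identical_and_degenerate(small_std):
    pre = small_std.reference
    est, aligned, low = align_before_after(pre, pre)
    np.testing.assert_allclose(est, [0, 0, 0], atol=1e-9)
    flat = Volume(np.zeros_like(pre.data), pre.spacing)
    with pytest.raises(ValueError):
        align_before_after(pre, flat)


def test_align_before_after_uncorrelated_noise_low_confidence():
    flagged = 0
    for seed in range(20):
        rng = np.random.default_rng(seed)
        a = Volume(rng.normal(size=(24, 24, 24)), (1, 1, 1))
        b = Volume(rng.normal(size=(24, 24, 24)), (1, 1, 1))
        _s, _a, low = align_before_after(a, b)
        flagged += low
    assert flagged == 20


def test_gate_specimens_rules():
    scores = [SimilarityScore(0, 0, b) for b in (0.2, 0.9, 0.5, 0.7)]
    assert gate_specimens(scores, 0.25) == [1]
    assert gate_specimens(scores, 1.0) == [1, 3, 2, 0]
    assert gate_specimens([], 0.5) == []
    with pytest.raises(ValueError):
        gate_specimens(scores, 0.0)


@settings(max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40),
       st.floats(0.05, 1.0))
def test_gate_specimens_properties(blended, keep):
    sel = gate_specimens(blended, keep)
    assert len(sel) == int(np.ceil(keep * len(blended)))
    # selected scores dominate the unselected ones
    rest = [b for i, b in enumerate(blended) if i not in sel]
    if rest:
        assert min(blended[i] for i in sel) >= max(rest) - 1e-12
    # ties keep input order
    assert sel == sorted(sel, key=lambda i: (-blended[i], i))
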