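"""Alignment cascade for partial-tile → whole-brain → standard-brain mapping.

The cascade has three stages, each strictly more flexible than the last:

1. :func:`locate_tile` — place a high-resolution tile inside the whole-brain
   image by exhaustive translation search, maximizing normalized
   cross-correlation (NCC) computed via FFT;
2. :func:`register_affine` — 12-parameter global alignment of the whole
   brain to the standard brain, optimizing a blended similarity
   ``w·MI + (1−w)·NCC`` over a 3-level multi-resolution pyramid;
3. :func:`register_deformable` — local refinement with a symmetric
   demons-style diffeomorphic scheme (Gaussian-regularized displacement
   field with an explicit positive-Jacobian guard).

Specimens are then quality-gated on the final blended score
(:func:`gate_specimens`), keeping only the best-aligned fraction.

Conventions: transforms map **fixed** physical (z, y, x) µm coordinates to
**moving** coordinates (pull-back resampling); the displacement field acts in
fixed space before the affine, ``T(x) = A(x + u(x)) + b``.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage, optimize
from skimage.feature import match_template
from skimage.registration import phase_cross_correlation

from .volume import Volume

__all__ = [
    "SpatialTransform",
    "SimilarityScore",
    "resample_isotropic",
    "locate_tile",
    "register_affine",
    "register_deformable",
    "gate_specimens",
    "align_before_after",
    "blended_similarity",
    "normalized_cross_correlation",
    "mutual_information",
]


# ---------------------------------------------------------------------------
# transforms


@dataclass
class SpatialTransform:
    """Affine (+ optional dense displacement field) in physical µm.

    ``T(x) = matrix @ (x + u(x)) + offset`` with ``u`` interpolated from
    ``field`` (shape ``(3, z, y, x)``, µm, on the fixed grid).
    """

    matrix: np.ndarray = dc_field(default_factory=lambda: np.eye(3))
    offset: np.ndarray = dc_field(default_factory=lambda: np.zeros(3))
    field: np.ndarray | None = None
    field_spacing: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, float).reshape(3, 3)
        self.offset = np.asarray(self.offset, float).reshape(3)
        if abs(np.linalg.det(self.matrix)) < 1e-12:
            raise ValueError("affine matrix is singular")

    @classmethod
    def translation(cls, shift_um) -> "SpatialTransform":
        return cls(np.eye(3), np.asarray(shift_um, float))

    def map_points(self, pts: np.ndarray) -> np.ndarray:
        """Apply to (N, 3) physical points."""
        pts = np.asarray(pts, float)
        if self.field is not None:
            idx = pts / np.array(self.field_spacing)
            u = np.stack(
                [
                    ndimage.map_coordinates(self.field[c], idx.T, order=1, mode="nearest")
                    for c in range(3)
                ],
                axis=-1,
            )
            pts = pts + u
        return pts @ self.matrix.T + self.offset

    def apply(self, moving: Volume, fixed_like: Volume, order: int = 1) -> Volume:
        """Resample ``moving`` onto the grid of ``fixed_like`` (pull-back)."""
        grid = np.indices(fixed_like.shape, dtype=float)
        pts = grid.reshape(3, -1).T * np.array(fixed_like.spacing) + np.array(
            fixed_like.origin
        )
        mapped = self.map_points(pts)
        idx = (mapped - np.array(moving.origin)) / np.array(moving.spacing)
        out = ndimage.map_coordinates(
            moving.data.astype(float), idx.T.reshape(3, *fixed_like.shape),
            order=order, mode="constant", cval=0.0,
        )
        return fixed_like.with_data(out, channel_tag=moving.channel_tag)

    def min_jacobian_det(self) -> float:
        """Minimum Jacobian determinant of the total map at interior voxels."""
        det_a = float(np.linalg.det(self.matrix))
        if self.field is None:
            return det_a
        sp = np.array(self.field_spacing)
        grads = [
            [np.gradient(self.field[c], sp[ax], axis=ax) for ax in range(3)]
            for c in range(3)
        ]
        jac = np.empty(self.field.shape[1:] + (3, 3))
        for c in range(3):
            for ax in range(3):
                jac[..., c, ax] = grads[c][ax]
        jac += np.eye(3)
        dets = np.linalg.det(jac[1:-1, 1:-1, 1:-1])
        return det_a * float(dets.min())

    def compose_field(self, field: np.ndarray, spacing) -> "SpatialTransform":
        return SpatialTransform(
            self.matrix.copy(), self.offset.copy(), field, tuple(spacing)
        )

    def numerical_inverse(self, pts: np.ndarray, iterations: int = 20) -> np.ndarray:
        """Map points through the inverse transform (fixed-point iteration).

        Exact for pure affines; for smooth displacement fields the iteration
        ``y_{k+1} = y_k − (T(y_k) − x)`` converges quickly when the field's
        gradient is bounded below 1.
        """
        pts = np.asarray(pts, float)
        y = np.linalg.solve(self.matrix, (pts - self.offset).T).T
        if self.field is None:
            return y
        for _ in range(iterations):
            y = y - (self.map_points(y) - pts) @ np.linalg.inv(self.matrix).T
        return y


@dataclass(frozen=True)
class SimilarityScore:
    ncc: float
    mi: float          # normalized mutual information in [0, 1]
    blended: float

    def __lt__(self, other: "SimilarityScore") -> bool:
        return self.blended < other.blended


# ---------------------------------------------------------------------------
# similarity metrics


def normalized_cross_correlation(a: np.ndarray, b: np.ndarray) -> float:
    a = np.ravel(a).astype(float)
    b = np.ravel(b).astype(float)
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        return 0.0
    return float(np.clip((a @ b) / denom, -1.0, 1.0))


def mutual_information(a: np.ndarray, b: np.ndarray, bins: int = 32) -> float:
    """MI normalized by the smaller marginal entropy (→ [0, 1])."""
    a = np.ravel(a).astype(float)
    b = np.ravel(b).astype(float)
    hist, _, _ = np.histogram2d(a, b, bins=bins)
    p = hist / hist.sum()
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    nz = p > 0
    mi = float((p[nz] * np.log(p[nz] / np.outer(pa, pb)[nz])).sum())
    ha = -float((pa[pa > 0] * np.log(pa[pa > 0])).sum())
    hb = -float((pb[pb > 0] * np.log(pb[pb > 0])).sum())
    denom = min(ha, hb)
    if denom <= 0:
        return 0.0
    return min(mi / denom, 1.0)


def blended_similarity(
    fixed: np.ndarray, warped: np.ndarray, weight: float = 0.5
) -> SimilarityScore:
    """``w·MI + (1−w)·NCC`` on the overlap of two sampled arrays."""
    ncc = normalized_cross_correlation(fixed, warped)
    mi = mutual_information(fixed, warped)
    return SimilarityScore(ncc=ncc, mi=mi, blended=weight * mi + (1 - weight) * ncc)


# ---------------------------------------------------------------------------
# operations


def resample_isotropic(vol: Volume, target_spacing: float) -> Volume:
    """Trilinear resample to isotropic voxels, preserving physical extent."""
    if target_spacing <= 0:
        raise ValueError("target_spacing must be positive")
    if vol.data.size == 0:
        raise ValueError("cannot resample an empty volume")
    new_shape = tuple(
        max(1, round(n * s / target_spacing)) for n, s in zip(vol.shape, vol.spacing)
    )
    if new_shape == vol.shape and vol.is_isotropic:
        return Volume(vol.data.copy(), (target_spacing,) * 3, vol.origin, vol.channel_tag)
    zoom = [ns / n for ns, n in zip(new_shape, vol.shape)]
    out = ndimage.zoom(vol.data.astype(float), zoom, order=1, grid_mode=True,
                       mode="nearest")
    return Volume(out, (target_spacing,) * 3, vol.origin, vol.channel_tag)


def _quadratic_peak_offset(values: np.ndarray) -> float:
    """Subvoxel offset of the extremum of a 3-sample quadratic fit."""
    denom = values[0] - 2 * values[1] + values[2]
    if denom == 0:
        return 0.0
    return float(np.clip(0.5 * (values[0] - values[2]) / denom, -0.5, 0.5))


def locate_tile(tile: Volume, whole: Volume) -> tuple[np.ndarray, float]:
    """Find the translation placing ``tile`` inside ``whole`` by FFT NCC.

    Returns ``(offset, peak_ncc)`` with the offset in (z, y, x) voxels of the
    whole image (subvoxel-refined by a quadratic fit around the NCC peak).
    Both volumes must share isotropic spacing; a constant-intensity tile has
    no defined NCC peak and raises ``ValueError``.
    """
    if any(ts > ws for ts, ws in zip(tile.shape, whole.shape)):
        raise ValueError(f"tile {tile.shape} larger than whole {whole.shape}")
    if not np.allclose(tile.spacing, whole.spacing, rtol=1e-4):
        raise ValueError("tile and whole must share voxel spacing")
    if float(np.std(tile.data)) == 0:
        raise ValueError("constant-intensity tile: NCC peak undefined")
    ncc = match_template(whole.data.astype(float), tile.data.astype(float))
    peak = np.unravel_index(np.argmax(ncc), ncc.shape)
    offset = np.array(peak, float)
    if ncc[peak] >= 1.0 - 1e-9:   # exact match: the integer offset is the answer
        return offset, float(ncc[peak])
    for ax in range(3):
        if 0 < peak[ax] < ncc.shape[ax] - 1:
            sl = list(peak)
            sl[ax] = slice(peak[ax] - 1, peak[ax] + 2)
            offset[ax] += _quadratic_peak_offset(ncc[tuple(sl)])
    return offset, float(ncc[peak])


def _affine_from_params(p: np.ndarray, center: np.ndarray) -> SpatialTransform:
    """12 parameters: translation (3), rotation rad (3), log-scale (3), shear (3)."""
    tz, ty, tx, rz, ry, rx, lsz, lsy, lsx, shy, shx, shz = p
    cz, sz_ = np.cos(rz), np.sin(rz)
    cy, sy_ = np.cos(ry), np.sin(ry)
    cx, sx_ = np.cos(rx), np.sin(rx)
    rot_z = np.array([[1, 0, 0], [0, cz, -sz_], [0, sz_, cz]])
    rot_y = np.array([[cy, 0, -sy_], [0, 1, 0], [sy_, 0, cy]])
    rot_x = np.array([[cx, -sx_, 0], [sx_, cx, 0], [0, 0, 1]])
    scale = np.diag(np.exp([lsz, lsy, lsx]))
    shear = np.array([[1, shy, shx], [0, 1, shz], [0, 0, 1]])
    m = rot_z @ rot_y @ rot_x @ scale @ shear
    offset = np.array([tz, ty, tx]) + center - m @ center
    return SpatialTransform(m, offset)


def _sample_grid(fixed: Volume, max_samples: int = 30000) -> np.ndarray:
    """Deterministic strided subset of fixed-grid physical points."""
    n = np.prod(fixed.shape)
    stride = max(1, int(np.ceil((n / max_samples) ** (1 / 3))))
    grid = np.indices(fixed.shape, dtype=float)[:, ::stride, ::stride, ::stride]
    return grid.reshape(3, -1).T * np.array(fixed.spacing) + np.array(fixed.origin)


def _metric_at(
    transform: SpatialTransform, moving: Volume, fixed: Volume,
    pts: np.ndarray, fixed_vals: np.ndarray, weight: float,
) -> SimilarityScore:
    mapped = transform.map_points(pts)
    idx = (mapped - np.array(moving.origin)) / np.array(moving.spacing)
    vals = ndimage.map_coordinates(
        moving.data.astype(float), idx.T, order=1, mode="constant", cval=np.nan
    )
    ok = np.isfinite(vals)
    if ok.sum() < 100:
        raise ValueError("empty overlap between fixed and moving extents")
    return blended_similarity(fixed_vals[ok], vals[ok], weight)


def _downsample(vol: Volume, factor: int) -> Volume:
    if factor == 1:
        return vol
    sm = ndimage.gaussian_filter(vol.data.astype(float), sigma=0.5 * factor)
    return Volume(
        sm[::factor, ::factor, ::factor],
        tuple(s * factor for s in vol.spacing),
        vol.origin,
        vol.channel_tag,
    )


def register_affine(
    moving: Volume,
    fixed: Volume,
    init: SpatialTransform | None = None,
    *,
    metric_weight: float = 0.5,
    pyramid: tuple[int, ...] = (4, 2, 1),
    maxiter: int = 60,
) -> tuple[SpatialTransform, SimilarityScore]:
    """Global 12-parameter alignment maximizing the blended metric.

    Multi-resolution (downsampling factors ``pyramid``), Powell optimization,
    deterministic.  The returned transform never scores below the initial one
    on the finest level.
    """
    init = init or SpatialTransform()
    center = np.array(fixed.physical_extent()) / 2 + np.array(fixed.origin)
    p = np.zeros(12)
    # seed the translation from the initial transform
    p[:3] = init.offset + init.matrix @ center - center
    scales = np.array([5.0, 5.0, 5.0, 0.1, 0.1, 0.1, 0.05, 0.05, 0.05, 0.05, 0.05, 0.05])

    for factor in pyramid:
        fx = _downsample(fixed, factor)
        pts = _sample_grid(fx)
        fixed_vals = ndimage.map_coordinates(
            fx.data.astype(float),
            ((pts - np.array(fx.origin)) / np.array(fx.spacing)).T,
            order=1,
        )

        def neg(q):
            t = _affine_from_params(q * scales, center)
            try:
                return -_metric_at(t, moving, fx, pts, fixed_vals, metric_weight).blended
            except ValueError:
                return 1.0

        res = optimize.minimize(
            neg, p / scales, method="Powell",
            options={"maxiter": maxiter, "xtol": 1e-3, "ftol": 1e-5},
        )
        p = res.x * scales

    best = _affine_from_params(p, center)
    pts = _sample_grid(fixed)
    fixed_vals = ndimage.map_coordinates(
        fixed.data.astype(float),
        ((pts - np.array(fixed.origin)) / np.array(fixed.spacing)).T, order=1,
    )
    score = _metric_at(best, moving, fixed, pts, fixed_vals, metric_weight)
    init_score = _metric_at(init, moving, fixed, pts, fixed_vals, metric_weight)
    if init_score.blended > score.blended:
        return init, init_score
    return best, score


def register_deformable(
    moving: Volume,
    fixed: Volume,
    affine_init: SpatialTransform,
    *,
    metric_weight: float = 0.5,
    sigma_field: float = 1.5,
    sigma_fluid: float = 1.0,
    iterations: tuple[int, ...] = (30, 30, 10),
    pyramid: tuple[int, ...] = (4, 2, 1),
    step: float = 2.0,
    min_jacobian: float = 0.05,
) -> tuple[SpatialTransform, SimilarityScore]:
    """Demons-style diffeomorphic refinement on top of an affine alignment.

    A Gaussian-regularized displacement field is grown greedily from the
    symmetric demons force; each multi-resolution level enforces the positive-
    Jacobian contract by shrinking the update step until
    ``min det J > min_jacobian`` (aborts if impossible at any step size).
    The result never scores below the affine-only initialization.
    """
    warped_affine = affine_init.apply(moving, fixed)
    base_score = blended_similarity(fixed.data, warped_affine.data, metric_weight)

    field_vox = None  # displacement in voxels of the current level grid
    for level, (factor, iters) in enumerate(zip(pyramid, iterations)):
        fx = _downsample(fixed, factor)
        mv = _downsample(warped_affine, factor)
        f = fx.data.astype(float)
        m = mv.data.astype(float)
        if field_vox is None:
            field_vox = np.zeros((3,) + f.shape)
        else:
            prev_shape = field_vox.shape[1:]
            zoom = [fs / ps for fs, ps in zip(f.shape, prev_shape)]
            scale = np.array([zoom[c] for c in range(3)])
            field_vox = np.stack(
                [ndimage.zoom(field_vox[c], zoom, order=1) * scale[c] for c in range(3)]
            )
        grad_f = np.stack(np.gradient(f))
        norm = float(np.percentile(np.abs(f), 99)) or 1.0
        for _ in range(iters):
            coords = np.indices(f.shape, dtype=float) + field_vox
            mw = ndimage.map_coordinates(m, coords, order=1, mode="nearest")
            grad_m = np.stack(np.gradient(mw))
            grad = 0.5 * (grad_f + grad_m)  # symmetric force
            diff = f - mw
            denom = (grad ** 2).sum(axis=0) + (diff / norm) ** 2
            force = grad * (diff / np.where(denom < 1e-9, np.inf, denom))
            force = np.stack(
                [ndimage.gaussian_filter(force[c], sigma_fluid) for c in range(3)]
            )
            s = step
            for _try in range(8):
                cand = field_vox + s * force
                cand = np.stack(
                    [ndimage.gaussian_filter(cand[c], sigma_field) for c in range(3)]
                )
                if _min_jac_vox(cand) > min_jacobian:
                    field_vox = cand
                    break
                s *= 0.5
            else:
                raise RuntimeError(
                    "deformable registration: positive-Jacobian guard failed "
                    "at every step size"
                )

    # upsample the field to the fixed grid and convert voxels -> µm
    if field_vox.shape[1:] != fixed.shape:
        zoom = [fs / ps for fs, ps in zip(fixed.shape, field_vox.shape[1:])]
        field_vox = np.stack(
            [ndimage.zoom(field_vox[c], zoom, order=1) * zoom[c] for c in range(3)]
        )
    field_um = field_vox * np.array(fixed.spacing).reshape(3, 1, 1, 1)

    # total transform: demons field (fixed space) then the affine
    total = SpatialTransform(
        affine_init.matrix.copy(), affine_init.offset.copy(),
        _compose_field_with_affine(field_um, affine_init),
        tuple(fixed.spacing),
    )
    warped = total.apply(moving, fixed)
    score = blended_similarity(fixed.data, warped.data, metric_weight)
    if score.blended < base_score.blended:
        return affine_init, base_score
    return total, score


def _compose_field_with_affine(field_um: np.ndarray, affine: SpatialTransform):
    # the demons field u was estimated between fixed and affine-warped moving:
    # warped(x) = moving(A(x) + b) evaluated at x + u(x)  =>  total displacement
    # in fixed space is exactly u (the affine is applied afterwards).
    del affine
    return field_um


def _min_jac_vox(field_vox: np.ndarray) -> float:
    grads = [
        [np.gradient(field_vox[c], axis=ax) for ax in range(3)] for c in range(3)
    ]
    jac = np.empty(field_vox.shape[1:] + (3, 3))
    for c in range(3):
        for ax in range(3):
            jac[..., c, ax] = grads[c][ax]
    jac += np.eye(3)
    core = jac[1:-1, 1:-1, 1:-1] if min(field_vox.shape[1:]) > 2 else jac
    return float(np.linalg.det(core).min())


def gate_specimens(scores, keep_fraction: float) -> list[int]:
    """Indices of the best-aligned ``ceil(keep_fraction·n)`` specimens.

    Ranking is by blended score, descending; ties keep input order
    (deterministic).  An empty score list yields an empty selection.
    """
    if not 0 < keep_fraction <= 1:
        raise ValueError("keep_fraction must be in (0, 1]")
    scores = list(scores)
    if not scores:
        return []
    k = int(np.ceil(keep_fraction * len(scores)))
    blended = [s.blended if isinstance(s, SimilarityScore) else float(s) for s in scores]
    order = sorted(range(len(blended)), key=lambda i: (-blended[i], i))
    return order[:k]


def align_before_after(
    pre: Volume, post: Volume, *, upsample_factor: int = 20,
    min_confidence_ncc: float = 0.2,
) -> tuple[np.ndarray, Volume, bool]:
    """Subpixel translation-only alignment of a before/after image pair.

    Phase correlation with Fourier upsampling; returns ``(shift_voxels,
    aligned_post, low_confidence)``.  ``shift_voxels`` is the displacement of
    ``post`` relative to ``pre`` (the drift the specimen underwent); the
    aligned image is ``post`` translated by its negative.  ``low_confidence``
    is set when the aligned pair correlates below ``min_confidence_ncc``
    (e.g. uncorrelated noise).  Zero-variance inputs are an error.
    """
    if pre.shape != post.shape:
        raise ValueError("pre and post must share a grid")
    if float(np.std(pre.data)) == 0 or float(np.std(post.data)) == 0:
        raise ValueError("zero-variance input: phase correlation undefined")
    correction, _err, _phase = phase_cross_correlation(
        pre.data.astype(float), post.data.astype(float),
        upsample_factor=upsample_factor,
    )
    aligned = np.fft.ifftn(
        ndimage.fourier_shift(np.fft.fftn(post.data.astype(float)), correction)
    ).real
    ncc = normalized_cross_correlation(pre.data, aligned)
    return (
        -np.asarray(correction, float),
        post.with_data(aligned),
        ncc < min_confidence_ncc,
    )
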