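"""Random specimen deformations: affine + band-limited displacement field."""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from ..registration import SpatialTransform
from .specs import DeformationSpec

__all__ = ["random_specimen_transform", "smooth_random_field"]


def smooth_random_field(
    shape, spacing_um, amplitude_vox, sigma_vox, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random displacement field (3, z, y, x) in µm, max |u| bounded."""
    field = rng.standard_normal((3, *shape))
    field = np.stack([ndimage.gaussian_filter(field[c], sigma_vox) for c in range(3)])
    mag = np.sqrt((field ** 2).sum(axis=0)).max()
    if mag > 0:
        field *= amplitude_vox / mag
    return field * np.asarray(spacing_um).reshape(3, 1, 1, 1)


def random_specimen_transform(
    shape,
    spacing_um: float,
    seed: int,
    spec: DeformationSpec | None = None,
) -> SpatialTransform:
    """Specimen-specific deformation with a guaranteed positive Jacobian.

    Uniform draws within ±``rotation_max_deg``, ±``scale_max`` (per axis),
    ±``translation_max_vox``, composed with a smooth displacement field of
    bounded amplitude.  The field amplitude is halved (rarely needed) until
    the total map's minimum Jacobian determinant is positive.
    """
    spec = spec or DeformationSpec()
    rng = np.random.default_rng(seed)
    ang = np.deg2rad(rng.uniform(-spec.rotation_max_deg, spec.rotation_max_deg, 3))
    scales = np.exp(rng.uniform(np.log(1 - spec.scale_max), np.log(1 + spec.scale_max), 3))
    trans = rng.uniform(-spec.translation_max_vox, spec.translation_max_vox, 3) * spacing_um

    cz, sz = np.cos(ang[0]), np.sin(ang[0])
    cy, sy = np.cos(ang[1]), np.sin(ang[1])
    cx, sx = np.cos(ang[2]), np.sin(ang[2])
    rot = (
        np.array([[1, 0, 0], [0, cz, -sz], [0, sz, cz]])
        @ np.array([[cy, 0, -sy], [0, 1, 0], [sy, 0, cy]])
        @ np.array([[cx, -sx, 0], [sx, cx, 0], [0, 0, 1]])
    )
    matrix = rot @ np.diag(scales)
    center = np.array(shape) * spacing_um / 2
    offset = trans + center - matrix @ center

    amplitude = spec.field_amplitude_vox
    spacing = (spacing_um,) * 3
    for _ in range(6):
        field = smooth_random_field(shape, spacing, amplitude, spec.field_sigma_vox,
                                    np.random.default_rng(seed + 1))
        t = SpatialTransform(matrix, offset, field, spacing)
        if t.min_jacobian_det() > 0:
            return t
        amplitude *= 0.5
    raise RuntimeError("could not build a diffeomorphic specimen transform")
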