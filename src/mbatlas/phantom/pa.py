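"""Photoactivatable-GFP tracing phantom: before/after volume pairs.

Photoactivation of a target region raises the fluorescence of activatable
molecules within it; the activated molecules then diffuse through the whole
cytoplasm of every cell whose processes intersect the region, revealing the
cell body.  Cells with a large cytoplasmic volume relative to the activated
part dilute the label and may stay below detection — emulated here by
attenuating the soma gain when the intersecting arbor fraction falls below a
dilution threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..volume import Volume
from .specimen import _ball, _paste, _stamp_tube

__all__ = ["PaCell", "PhotoactivationPair", "default_pa_cells",
           "make_photoactivation_pair"]


@dataclass
class PaCell:
    """One PA-GFP-expressing cell: a soma sphere plus an arbor tube."""

    soma_center_vox: tuple[float, float, float]
    waypoints_vox: tuple[tuple[float, float, float], ...]
    soma_radius_vox: float = 3.0
    arbor_radius_vox: float = 1.2
    mask: np.ndarray | None = field(default=None, repr=False)

    def render(self, shape) -> np.ndarray:
        m = np.zeros(shape, bool)
        pts = [self.soma_center_vox, *self.waypoints_vox]
        for a, b in zip(pts[:-1], pts[1:]):
            _stamp_tube(m, a, b, self.arbor_radius_vox)
        _paste(m, _ball(self.soma_radius_vox),
               np.round(self.soma_center_vox).astype(int),
               int(np.ceil(self.soma_radius_vox)))
        self.mask = m
        return m

    def soma_mask(self, shape) -> np.ndarray:
        m = np.zeros(shape, bool)
        _paste(m, _ball(self.soma_radius_vox),
               np.round(self.soma_center_vox).astype(int),
               int(np.ceil(self.soma_radius_vox)))
        return m


@dataclass
class PhotoactivationPair:
    pre: Volume
    post: Volume
    roi_mask: np.ndarray            # known-positive reference region
    cells: tuple[PaCell, ...]
    activated_truth: tuple[bool, ...]   # which cells should be detectable


def default_pa_cells(
    shape=(64, 96, 96), n_intersecting: int = 10, n_other: int = 10, seed: int = 0
) -> tuple[list[PaCell], np.ndarray]:
    """Cells on a soma ring; half send an arbor through a central target box."""
    rng = np.random.default_rng(seed)
    region = np.zeros(shape, bool)
    c = np.array(shape) / 2
    region[int(c[0] - 6):int(c[0] + 6), int(c[1] - 10):int(c[1] + 10),
           int(c[2] - 10):int(c[2] + 10)] = True
    cells = []
    n = n_intersecting + n_other
    for i in range(n):
        theta = 2 * np.pi * i / max(n, 1)
        soma = (
            shape[0] * 0.5 + 0.36 * shape[0] * np.sin(theta),
            shape[1] * 0.5 + 0.42 * shape[1] * np.cos(theta),
            shape[2] * (0.12 if i % 2 else 0.88),
        )
        if i < n_intersecting:
            target = c + rng.uniform(-4, 4, 3)
        else:
            # aim at a corner region well away from the target box
            target = np.array(shape) * rng.choice([0.12, 0.88], 3)
        cells.append(PaCell(soma, (tuple(target),)))
    return cells, region


def make_photoactivation_pair(
    activated_region: np.ndarray,
    cells: list[PaCell],
    brightness: float = 10.0,
    seed: int = 0,
    *,
    spacing_um: float = 0.76,
    baseline: float = 1.0,
    background: float = 0.1,
    noise_sd: float = 0.05,
    dilution_threshold: float | None = 0.05,
) -> PhotoactivationPair:
    """Render a before/after pair for a set of PA-GFP-expressing cells.

    ``post`` adds full ``brightness`` inside the activated region of each
    intersecting arbor; the gain over the remaining cytoplasm (including the
    soma) is scaled by ``min(1, fraction_intersecting / dilution_threshold)``
    when dilution is enabled, so cells with a tiny intersecting fraction stay
    near baseline.  Ground truth marks a cell detectable when its soma gain
    is at least half of ``brightness``.
    """
    shape = activated_region.shape
    rng = np.random.default_rng(seed)
    pre = np.full(shape, background)
    gain = np.zeros(shape)
    roi = np.zeros(shape, bool)
    truth = []
    for cell in cells:
        mask = cell.render(shape)
        pre[mask] = baseline
        inter = mask & activated_region
        frac = inter.sum() / mask.sum()
        if frac == 0:
            truth.append(False)
            continue
        atten = 1.0
        if dilution_threshold is not None:
            atten = min(1.0, frac / dilution_threshold)
        gain[inter] = brightness
        gain[mask & ~activated_region] = np.maximum(
            gain[mask & ~activated_region], atten * brightness
        )
        roi |= inter
        truth.append(atten * brightness >= 0.5 * brightness)
    post = pre + gain
    pre = pre + rng.normal(0, noise_sd, shape)
    post = post + rng.normal(0, noise_sd, shape)
    spacing = (spacing_um,) * 3
    return PhotoactivationPair(
        Volume(pre, spacing, channel_tag="pa-pre"),
        Volume(post, spacing, channel_tag="pa-post"),
        roi,
        tuple(cells),
        tuple(truth),
    )
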