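"""Object-detection procedures: nucleus counting, photoactivated-cell
detection, dopaminergic classification, and terminal/dendrite splitting.

The nucleus counter follows a two-pass scheme: after regressing the membrane
channel out of the nuclear channel, nucleus-sized connected components
(volume inside a mean ± 2 SD sphere-volume gate) are counted at a low
threshold and their voxels deleted; the remainder — typically mutually
touching nuclei that merged into over-sized components — is re-thresholded
at a higher level, where the merged blobs split into gate-passing cores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .volume import Volume

__all__ = [
    "NucleusSizeGate",
    "DetectedObject",
    "DetectionResult",
    "count_nuclei_two_pass",
    "detect_photoactivated",
    "classify_dan",
    "split_terminals_dendrites",
]

_CONN26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class NucleusSizeGate:
    """Accepted component volumes: spheres with diameter in mean ± 2 SD."""

    mean_diameter_um: float
    sd_um: float

    def volume_interval_um3(self) -> tuple[float, float]:
        lo_d = self.mean_diameter_um - 2 * self.sd_um
        hi_d = self.mean_diameter_um + 2 * self.sd_um
        if lo_d <= 0:
            raise ValueError("size gate lower bound must be positive")
        v = lambda d: np.pi / 6 * d ** 3
        return float(v(lo_d)), float(v(hi_d))

    def accepts(self, volume_um3: float) -> bool:
        lo, hi = self.volume_interval_um3()
        return lo <= volume_um3 <= hi


@dataclass(frozen=True)
class DetectedObject:
    label: int
    voxels: int
    volume_um3: float
    centroid_um: tuple[float, float, float]
    pass_id: int    # 1 = low-threshold pass, 2 = high-threshold pass


@dataclass
class DetectionResult:
    objects: tuple[DetectedObject, ...]
    labels: np.ndarray      # per-object labels, disjoint across passes
    total: int
    qc_seed: int = 0

    @property
    def pass_counts(self) -> tuple[int, int]:
        p1 = sum(1 for o in self.objects if o.pass_id == 1)
        p2 = sum(1 for o in self.objects if o.pass_id == 2)
        return p1, p2

    def qc_rendering(self, seed: int | None = None):
        """Random colors and numbers per counted object (seeded, for review)."""
        rng = np.random.default_rng(self.qc_seed if seed is None else seed)
        colors = {o.label: tuple(rng.integers(64, 256, 3).tolist()) for o in self.objects}
        numbers = dict(
            zip((o.label for o in self.objects),
                rng.permutation(len(self.objects)) + 1)
        )
        return colors, numbers


def _fit_membrane_scale(nuclear: np.ndarray, membrane: np.ndarray) -> float:
    """Least-squares bleed-through coefficient over membrane-dominated voxels."""
    m = membrane > 0.5 * membrane.max() if membrane.max() > 0 else np.zeros_like(
        membrane, bool
    )
    if m.sum() < 10:
        return 0.0
    x = membrane[m]
    y = nuclear[m]
    denom = float(x @ x)
    return max(0.0, float(x @ y) / denom) if denom > 0 else 0.0


def _gated_components(
    bw: np.ndarray, gate: NucleusSizeGate, voxel_um3: float, spacing, pass_id: int,
    label_offset: int,
) -> tuple[list[DetectedObject], np.ndarray]:
    labels, n = ndimage.label(bw, structure=_CONN26)
    objects = []
    keep = np.zeros_like(labels)
    if n == 0:
        return objects, keep
    counts = np.bincount(labels.ravel())
    centroids = ndimage.center_of_mass(bw, labels, range(1, n + 1))
    for lab in range(1, n + 1):
        vol = counts[lab] * voxel_um3
        if gate.accepts(vol):
            new_label = label_offset + len(objects) + 1
            keep[labels == lab] = new_label
            objects.append(
                DetectedObject(
                    label=new_label,
                    voxels=int(counts[lab]),
                    volume_um3=float(vol),
                    centroid_um=tuple(
                        float(c * s) for c, s in zip(centroids[lab - 1], spacing)
                    ),
                    pass_id=pass_id,
                )
            )
    return objects, keep


def count_nuclei_two_pass(
    nuclear: Volume,
    membrane: Volume | None,
    gate: NucleusSizeGate,
    t_low: float | None = None,
    t_high: float | None = None,
    qc_seed: int = 0,
) -> DetectionResult:
    """Count nucleus-sized objects with the low/high two-pass procedure.

    Default thresholds, when not given, are Otsu (``t_low``) and Otsu plus
    1.5× the inter-class spread (``t_high``); the procedure itself imposes no
    intensity floor beyond ``t_low`` — all detectable objects are counted.
    """
    data = nuclear.data.astype(float)
    if membrane is not None:
        if membrane.shape != nuclear.shape:
            raise ValueError("nuclear and membrane channels must be co-registered")
        scale = _fit_membrane_scale(data, membrane.data.astype(float))
        data = np.clip(data - scale * membrane.data, 0, None)
    if t_low is None or t_high is None:
        if data.max() > data.min():
            otsu = float(threshold_otsu(data))
            spread = float(data[data >= otsu].mean() - data[data < otsu].mean())
        else:
            otsu, spread = 0.5, 0.1
        t_low = otsu if t_low is None else t_low
        t_high = otsu + 1.5 * spread if t_high is None else t_high
    if t_low >= t_high:
        raise ValueError(f"t_low ({t_low}) must be below t_high ({t_high})")
    gate.volume_interval_um3()  # validates the gate

    voxel_um3 = nuclear.voxel_volume()
    pass1, keep1 = _gated_components(
        data >= t_low, gate, voxel_um3, nuclear.spacing, pass_id=1, label_offset=0
    )
    remainder = data.copy()
    remainder[keep1 > 0] = 0.0
    pass2, keep2 = _gated_components(
        remainder >= t_high, gate, voxel_um3, nuclear.spacing, pass_id=2,
        label_offset=len(pass1),
    )
    labels = keep1 + keep2
    objects = tuple(pass1 + pass2)
    return DetectionResult(objects, labels, total=len(objects), qc_seed=qc_seed)


def detect_photoactivated(
    pre_aligned: Volume,
    post: Volume,
    roi_mask: np.ndarray,
    candidates: dict[str, np.ndarray],
    majority_fraction: float = 0.5,
) -> dict[str, bool]:
    """Photoactivated-cell calls from a before/after pair.

    The detection threshold is ``mean − 2·SD`` of the post image over the
    known-positive reference regions (``roi_mask``); a candidate (soma mask)
    is called activated when more than ``majority_fraction`` of its voxels
    exceed that threshold.  The rule is invariant to adding a constant to
    both images.  An empty ROI is an error.
    """
    if roi_mask.sum() == 0:
        raise ValueError("empty ROI set: cannot derive a detection threshold")
    if pre_aligned.shape != post.shape:
        raise ValueError("pre and post must be aligned on one grid")
    roi_vals = post.data[roi_mask]
    tau = float(roi_vals.mean() - 2 * roi_vals.std())
    out = {}
    for name, mask in candidates.items():
        vals = post.data[mask]
        out[name] = bool((vals > tau).mean() > majority_fraction)
    return out


def classify_dan(
    candidates: dict[str, np.ndarray],
    marker: Volume,
    marker_threshold: float,
) -> dict[str, bool]:
    """Dopaminergic iff the median marker intensity over the soma exceeds
    the threshold (marker-negative somata are MBON-like)."""
    return {
        name: bool(np.median(marker.data[mask]) > marker_threshold)
        for name, mask in candidates.items()
    }


def split_terminals_dendrites(
    membrane: Volume,
    presynaptic: Volume,
    enrichment_min: float = 5.0,
    *,
    local_radius_vox: int = 3,
    membrane_mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Split an arbor into terminal and dendritic voxels by local enrichment.

    Within the membrane mask, a voxel is terminal when the ratio of local
    mean presynaptic to local mean membrane signal is at least
    ``enrichment_min`` (means over a ``local_radius_vox``-radius
    neighborhood).  Returns ``(terminal, dendrite)`` — disjoint masks whose
    union is exactly the membrane mask.
    """
    if membrane.shape != presynaptic.shape:
        raise ValueError("membrane and presynaptic channels must be co-registered")
    if membrane_mask is None:
        membrane_mask = membrane.data > 0.5 * float(np.max(membrane.data))
    if membrane_mask.sum() == 0:
        raise ValueError("empty membrane mask")
    size = 2 * local_radius_vox + 1
    lm_pre = ndimage.uniform_filter(presynaptic.data.astype(float), size)
    lm_mem = ndimage.uniform_filter(membrane.data.astype(float), size)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(lm_mem > 1e-9, lm_pre / np.maximum(lm_mem, 1e-9), 0.0)
    terminal = membrane_mask & (ratio >= enrichment_min)
    dendrite = membrane_mask & ~terminal
    return terminal, dendrite
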