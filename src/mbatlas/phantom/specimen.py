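"""Synthetic split-GAL4-style specimens: labeled arbors on a deformed brain.

A specimen expresses one or more atlas cell types.  Each expressed type gets
a ground-truth arbor in standard space: dendrites (or DAN terminals) fill
their fixture-assigned compartment spans, an axon shaft runs to the type's
extralobe projection zones, and presynaptic terminals form bright bouton
blobs (in the zones for MBON axons, inside the target compartments for DAN
terminals and for the feedforward MBONs' in-lobe collaterals).  The
presynaptic reporter channel is strongly enriched (10×) in terminal voxels
relative to the rest of the arbor, emulating a presynaptically targeted
reporter with >5-fold bouton enrichment.  All channels are warped by one
specimen transform and corrupted by Poisson–Gaussian noise.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..atlas.records import Atlas, load_atlas
from ..registration import SpatialTransform
from ..volume import Volume
from .brain import StandardBrain, ZONES
from .specs import NoiseSpec

__all__ = ["GroundTruth", "Specimen", "make_specimen", "PRESYN_TERMINAL",
           "PRESYN_DENDRITE"]

PRESYN_TERMINAL = 10.0   # presynaptic reporter level in bouton voxels
PRESYN_DENDRITE = 0.3    # ... elsewhere in the arbor
_SHAFT_RADIUS_VOX = 1.4
_BOUTON_RADIUS_VOX = 3.5


@dataclass
class GroundTruth:
    """Standard-space and specimen-space truth for one synthetic specimen."""

    arbor_masks: dict[str, np.ndarray]       # per expressed type, standard space
    terminal_mask: np.ndarray                # union over types, standard space
    dendrite_mask: np.ndarray
    membrane_mask: np.ndarray
    transform: SpatialTransform              # specimen grid -> standard space
    specimen_compartment_labels: Volume      # warped labels (nearest neighbor)
    specimen_membrane_mask: np.ndarray
    expressed_types: tuple[str, ...]


@dataclass
class Specimen:
    reference: Volume
    membrane: Volume
    presynaptic: Volume
    nuclear: Volume
    ground_truth: GroundTruth


def _stamp_tube(mask: np.ndarray, p0, p1, radius: float) -> None:
    """Rasterize a cylinder segment between two voxel points."""
    p0 = np.asarray(p0, float)
    p1 = np.asarray(p1, float)
    n = max(2, int(np.ceil(np.linalg.norm(p1 - p0))))
    r = int(np.ceil(radius))
    ball = _ball(radius)
    for t in np.linspace(0, 1, n):
        c = np.round(p0 + t * (p1 - p0)).astype(int)
        _paste(mask, ball, c, r)


def _ball(radius: float) -> np.ndarray:
    r = int(np.ceil(radius))
    g = np.indices((2 * r + 1,) * 3) - r
    return (g ** 2).sum(axis=0) <= radius ** 2


def _paste(mask: np.ndarray, ball: np.ndarray, center, r: int) -> None:
    sl_m, sl_b = [], []
    for ax in range(3):
        lo = center[ax] - r
        hi = center[ax] + r + 1
        blo = max(0, -lo)
        bhi = ball.shape[ax] - max(0, hi - mask.shape[ax])
        sl_m.append(slice(max(0, lo), min(mask.shape[ax], hi)))
        sl_b.append(slice(blo, bhi))
    region = mask[tuple(sl_m)]
    region |= ball[tuple(sl_b)]


def _centroid(mask: np.ndarray) -> np.ndarray:
    return np.array(ndimage.center_of_mass(mask))


def build_arbor(
    std: StandardBrain, atlas: Atlas, type_name: str
) -> tuple[np.ndarray, np.ndarray]:
    """Ground-truth (arbor_mask, terminal_mask) for one cell type, std space."""
    rec = atlas[type_name]
    cat = atlas.catalog
    shape = std.reference.shape
    arbor = np.zeros(shape, bool)
    terminal = np.zeros(shape, bool)

    dend_comps = sorted(cat.compartments_of(rec.dendrite_regions))
    term_comps = sorted(cat.compartments_of(rec.axon_regions_in_lobes))
    # MBON dendrites / DAN terminals fill their compartment spans
    fill_comps = dend_comps if rec.cell_class == "MBON" else term_comps
    for comp in fill_comps:
        arbor |= std.compartment_mask(comp)
    if rec.cell_class.startswith("DAN"):
        for comp in term_comps:
            terminal |= std.compartment_mask(comp)
        for comp in dend_comps:   # in-lobe dendrites (one PAM type)
            arbor |= std.compartment_mask(comp)
    else:
        # feedforward MBONs: in-lobe terminal collaterals fill target spans
        for comp in term_comps:
            arbor |= std.compartment_mask(comp)
            terminal |= std.compartment_mask(comp)

    # axon shaft from the innervated lobe region to each projection zone,
    # ending in a terminal bouton blob (MBON axons) or dendritic tuft (DANs)
    anchor = _centroid(std.compartment_mask(fill_comps[0]))
    for zone in sorted(rec.extralobe_projection_zones):
        if zone not in ZONES:
            continue
        zc = _centroid(std.zone_mask(zone))
        _stamp_tube(arbor, anchor, zc, _SHAFT_RADIUS_VOX)
        blob = np.zeros(shape, bool)
        _paste(blob, _ball(_BOUTON_RADIUS_VOX), np.round(zc).astype(int),
               int(np.ceil(_BOUTON_RADIUS_VOX)))
        arbor |= blob
        if rec.cell_class == "MBON":
            terminal |= blob
    return arbor, terminal & arbor


def make_specimen(
    std: StandardBrain,
    transform: SpatialTransform,
    expressed_types: tuple[str, ...] = ("MBON-a2sc", "PPL1-ap2a2"),
    noise: NoiseSpec | None = None,
    seed: int = 0,
    atlas: Atlas | None = None,
) -> Specimen:
    """Render a deformed, noisy specimen expressing the given cell types.

    The ground truth (arbor/terminal/dendrite masks, warped compartment
    labels, the transform itself) is a deterministic function of the inputs;
    the seed drives only the noise realization.  The transform must be
    invertibility-safe (positive Jacobian), as produced by
    :func:`mbatlas.phantom.deform.random_specimen_transform`.
    """
    atlas = atlas or load_atlas()
    noise = noise or NoiseSpec()
    if transform.min_jacobian_det() <= 0:
        raise ValueError("specimen transform is not invertible (Jacobian <= 0)")
    unknown = [t for t in expressed_types if t not in {r.name for r in atlas.records}]
    if unknown:
        raise KeyError(f"expressed types not in atlas: {unknown}")

    shape = std.reference.shape
    membrane = np.zeros(shape, bool)
    terminal = np.zeros(shape, bool)
    arbors: dict[str, np.ndarray] = {}
    for t in expressed_types:
        arbor, term = build_arbor(std, atlas, t)
        arbors[t] = arbor
        membrane |= arbor
        terminal |= term
    dendrite = membrane & ~terminal

    presyn = np.where(terminal, PRESYN_TERMINAL,
                      np.where(membrane, PRESYN_DENDRITE, 0.0))
    rng = np.random.default_rng(seed)
    # somata: one blob per cell near the brain surface
    nuclear = np.zeros(shape, float)
    soma_rng = np.random.default_rng(
        zlib.crc32("|".join(expressed_types).encode()) % (2 ** 31)
    )
    for t in expressed_types:
        n_cells = atlas[t].cells_per_hemisphere[0]
        for _ in range(n_cells):
            c = (soma_rng.uniform(0.82, 0.92) * shape[0],
                 soma_rng.uniform(0.1, 0.9) * shape[1],
                 soma_rng.uniform(0.1, 0.9) * shape[2])
            blob = np.zeros(shape, bool)
            _paste(blob, _ball(2.5), np.round(c).astype(int), 3)
            nuclear[blob] = 1.0

    def warp(data, order=1, tag=""):
        vol = Volume(data.astype(float), std.reference.spacing,
                     std.reference.origin, tag)
        return transform.apply(vol, std.reference, order=order)

    def noisy(vol: Volume) -> Volume:
        d = np.clip(vol.data, 0, None)
        if noise.poisson_gain:
            d = rng.poisson(d * noise.poisson_gain) / noise.poisson_gain
        d = d + rng.normal(0, noise.gaussian_sd, d.shape)
        return vol.with_data(d)

    warped_labels = warp(std.compartment_labels.data, order=0,
                         tag="compartment-labels")
    warped_labels.data = warped_labels.data.astype(np.int16)
    warped_membrane = warp(membrane, order=0).data > 0.5

    gt = GroundTruth(
        arbor_masks=arbors,
        terminal_mask=terminal,
        dendrite_mask=dendrite,
        membrane_mask=membrane,
        transform=transform,
        specimen_compartment_labels=warped_labels,
        specimen_membrane_mask=warped_membrane,
        expressed_types=tuple(expressed_types),
    )
    return Specimen(
        reference=noisy(warp(std.reference.data, tag="reference")),
        membrane=noisy(warp(membrane.astype(float), tag="membrane")),
        presynaptic=noisy(warp(presyn, tag="presynaptic")),
        nuclear=noisy(warp(nuclear, tag="nuclear")),
        ground_truth=gt,
    )
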