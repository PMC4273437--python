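"""Synthetic standard brain: lobe tubes, compartment tiling, reference channel.

The three anatomical lobes are rendered as straight tubes along the y-axis
(a "straightened" mushroom body), each divided into five ordered compartment
spans; the α/β tube additionally carries the pedunculus core (``pedc``)
between α1 and β1.  Five ellipsoidal projection zones (CRE, SMP, SIP, SLP,
LH) provide extralobe geometry.  The reference channel emulates a pan-
synaptic density stain: uniform inside neuropils with multiplicative dips at
designated compartment borders.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ..atlas.catalog import COMPARTMENTS
from ..volume import Volume
from .specs import PhantomSpec

__all__ = ["StandardBrain", "make_standard_brain", "COMPARTMENT_IDS", "ZONES"]

#: integer label per compartment (canonical order; pedc = 16)
COMPARTMENT_IDS = {c: i + 1 for i, c in enumerate(COMPARTMENTS)}
COMPARTMENT_IDS["pedc"] = 16

#: ellipsoidal extralobe zones: name -> (center_frac (z,y,x), radii_vox)
ZONES = {
    "CRE": ((0.68, 0.25, 0.32), (9.0, 11.0, 10.0)),
    "SMP": ((0.68, 0.42, 0.48), (9.0, 11.0, 10.0)),
    "SIP": ((0.68, 0.60, 0.63), (9.0, 11.0, 10.0)),
    "SLP": ((0.68, 0.78, 0.76), (9.0, 11.0, 10.0)),
    "LH":  ((0.68, 0.32, 0.82), (8.0, 10.0, 9.0)),
}

#: tube definitions: lobe -> (x_frac, ordered compartment spans)
_TUBES = {
    "gamma": (0.33, ("g1", "g2", "g3", "g4", "g5")),
    "alpha_beta_prime": (0.50, ("ap3", "ap2", "ap1", "bp1", "bp2")),
    "alpha_beta": (0.67, ("a3", "a2", "a1", "pedc", "b1", "b2")),
}
#: neuropils outside the MBON projection zones (geometry so that stray signal
#: has somewhere to land; MBON terminals should avoid these)
OTHER_NEUROPILS = {
    "AL":   ((0.20, 0.15, 0.15), (7.0, 8.0, 7.0)),
    "AVLP": ((0.20, 0.15, 0.85), (7.0, 8.0, 7.0)),
    "PLP":  ((0.20, 0.85, 0.85), (7.0, 8.0, 7.0)),
}
_TUBE_Z_FRAC = 0.30
_TUBE_Y_FRAC = (0.12, 0.88)


@dataclass
class StandardBrain:
    """Outputs of :func:`make_standard_brain`, plus layout bookkeeping."""

    reference: Volume
    neuropil_labels: Volume       # integer codes into ``neuropil_id_map``
    compartment_labels: Volume    # COMPARTMENT_IDS codes, 0 outside lobes
    neuropil_id_map: dict[str, int]
    spec: PhantomSpec
    flagged_borders: tuple[tuple[str, str], ...]
    compartment_spans: dict[str, tuple[str, ...]]

    @property
    def lobe_mask(self) -> np.ndarray:
        return self.compartment_labels.data > 0

    def compartment_mask(self, comp: str) -> np.ndarray:
        return self.compartment_labels.data == COMPARTMENT_IDS[comp]

    def zone_mask(self, zone: str) -> np.ndarray:
        return self.neuropil_labels.data == self.neuropil_id_map[zone]


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grid = np.indices(shape, dtype=float)
    d = sum(((grid[i] - center[i]) / radii[i]) ** 2 for i in range(3))
    return d <= 1.0


def _neuropil_of(comp: str) -> str:
    if comp == "pedc":
        return "MB-PED"
    if comp.startswith(("a", "ap")) and not comp.startswith("ab"):
        # vertical lobes: α and α′ compartments
        return "MB-VL" if comp[0] == "a" and comp[1] in "p123" else "MB-ML"
    return "MB-ML"


def make_standard_brain(spec: PhantomSpec | None = None) -> StandardBrain:
    """Deterministic synthetic standard brain (pure function of the spec).

    The compartment label volume exactly partitions the lobe tubes: spans
    within a tube are disjoint by construction and their union is the tube
    mask.  Flagged borders get a multiplicative intensity dip of
    ``spec.border_dip_factor`` in the reference channel over a band of
    ``±border_halfwidth_vox`` voxels around the border plane.
    """
    spec = spec or PhantomSpec()
    shape = spec.shape
    sp = spec.spacing_um

    zz, yy, xx = np.indices(shape, dtype=float)
    comp_labels = np.zeros(shape, dtype=np.int16)
    neuro_labels = np.zeros(shape, dtype=np.int16)

    from ..atlas.records import load_atlas

    regions = load_atlas().neuropil_regions
    neuropil_id_map = {name: i + 1 for i, name in enumerate(regions)}

    y0 = int(_TUBE_Y_FRAC[0] * shape[1])
    y1 = int(_TUBE_Y_FRAC[1] * shape[1])
    zc = _TUBE_Z_FRAC * shape[0]
    spans_by_lobe: dict[str, tuple[str, ...]] = {}
    border_bands: dict[tuple[str, str], np.ndarray] = {}

    for lobe, (x_frac, comps) in _TUBES.items():
        spans_by_lobe[lobe] = comps
        xc = x_frac * shape[2]
        tube = ((zz - zc) ** 2 + (xx - xc) ** 2) <= spec.tube_radius_vox ** 2
        tube &= (yy >= y0) & (yy < y1)
        # split the y-range into spans; pedc gets a short fixed-length span
        names = list(comps)
        length = y1 - y0
        if "pedc" in names:
            pedc_len = spec.pedc_length_vox
            regular = (length - pedc_len) // (len(names) - 1)
        else:
            pedc_len = 0
            regular = length // len(names)
        edges = [y0]
        for name in names:
            edges.append(edges[-1] + (pedc_len if name == "pedc" else regular))
        edges[-1] = y1
        for i, name in enumerate(names):
            span = tube & (yy >= edges[i]) & (yy < edges[i + 1])
            comp_labels[span] = COMPARTMENT_IDS[name]
            neuro_labels[span] = neuropil_id_map[_neuropil_of(name)]
        for i in range(len(names) - 1):
            pair = tuple(sorted((names[i], names[i + 1])))
            hw = spec.border_halfwidth_vox
            band = tube & (np.abs(yy - edges[i + 1] + 0.5) <= hw)
            border_bands[pair] = band

    for zone, (cfrac, radii) in {**ZONES, **OTHER_NEUROPILS}.items():
        center = tuple(f * s for f, s in zip(cfrac, shape))
        mask = _ellipsoid_mask(shape, center, radii)
        neuro_labels[mask & (neuro_labels == 0)] = neuropil_id_map[zone]

    reference = (neuro_labels > 0).astype(float)
    flagged = tuple(tuple(sorted(b)) for b in spec.dimmed_borders)
    for pair in flagged:
        if pair not in border_bands:
            raise ValueError(f"dimmed border {pair} is not an adjacent pair")
        reference[border_bands[pair]] *= spec.border_dip_factor
    reference = ndimage.gaussian_filter(reference, spec.reference_blur_sigma)

    spacing = (sp, sp, sp)
    return StandardBrain(
        reference=Volume(reference, spacing, channel_tag="reference"),
        neuropil_labels=Volume(neuro_labels, spacing, channel_tag="neuropil-labels"),
        compartment_labels=Volume(comp_labels, spacing, channel_tag="compartment-labels"),
        neuropil_id_map=neuropil_id_map,
        spec=spec,
        flagged_borders=flagged,
        compartment_spans=spans_by_lobe,
    )
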