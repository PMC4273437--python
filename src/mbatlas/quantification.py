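"""Atlas quantifications on registered volumes.

* compartment-mask construction from averaged per-compartment intensities
  (Gaussian blur σ=2, then deterministic argmax tiling of the lobes);
* tiling metrics: cross-compartment arbor fractions and border-gap flags;
* per-neuropil projection fractions over the 38-region catalog;
* density-cube heat maps (10×10×10-voxel means on an 8-bit scale);
* pairwise arbor-overlap matrices with Ward clustering.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .atlas.catalog import COMPARTMENTS
from .volume import Volume

__all__ = [
    "build_compartment_masks",
    "tiling_metrics",
    "neuropil_fractions",
    "density_grid",
    "DensityGrid",
    "overlap_score",
    "OverlapMatrix",
    "build_overlap_matrix",
    "cluster_matrix",
]

_COMPARTMENT_ORDER = tuple(COMPARTMENTS) + ("pedc",)


def build_compartment_masks(
    per_compartment: dict[str, list[Volume]],
    lobe_mask: np.ndarray,
    sigma_blur: float = 2.0,
) -> tuple[np.ndarray, dict[str, int]]:
    """Compartment label volume from registered per-type intensity images.

    Images of neurons projecting to the same compartment are averaged,
    blurred in 3D (σ = ``sigma_blur`` voxels), and every lobe voxel is
    assigned to the argmax compartment — a deterministic, automated stand-in
    for manual border tracing.  Ties break by canonical compartment order.
    Returns ``(labels, id_map)``; labels partition ``lobe_mask`` exactly.
    """
    comps = [c for c in _COMPARTMENT_ORDER if c in per_compartment]
    missing = set(per_compartment) - set(comps)
    if missing:
        raise KeyError(f"unknown compartment ids: {sorted(missing)}")
    if not comps:
        raise ValueError("no compartment images given")
    stacks = []
    for comp in comps:
        vols = per_compartment[comp]
        if not vols:
            raise ValueError(f"compartment {comp!r} has no input volumes")
        mean = np.mean([v.data.astype(float) for v in vols], axis=0)
        stacks.append(ndimage.gaussian_filter(mean, sigma_blur))
    stack = np.stack(stacks)
    # argmax returns the first maximum, i.e. the canonical-order tie-break
    arg = np.argmax(stack, axis=0)
    labels = np.zeros(lobe_mask.shape, np.int16)
    labels[lobe_mask] = arg[lobe_mask] + 1
    id_map = {comp: i + 1 for i, comp in enumerate(comps)}
    return labels, id_map


def _border_shell(labels: np.ndarray, ia: int, ib: int) -> np.ndarray:
    """2-voxel shell around the a|b border: voxels of either compartment
    adjacent (6-connectivity) to the other."""
    a = labels == ia
    b = labels == ib
    da = ndimage.binary_dilation(a)
    db = ndimage.binary_dilation(b)
    return (a & db) | (b & da)


def tiling_metrics(
    dendrite_masks: dict[str, np.ndarray],
    assigned_compartments: dict[str, set[str]],
    compartment_labels: np.ndarray,
    id_map: dict[str, int],
    coverage: np.ndarray | None = None,
    gap_threshold: float = 0.5,
) -> dict:
    """Tiling quality: per-type cross-compartment fractions and border gaps.

    ``cross_compartment_fraction`` is the fraction of a type's dendrite
    voxels lying outside its assigned compartments.  When a ``coverage``
    volume (summed arbor or reference intensity) is given, every adjacent
    compartment border is flagged as a gap when the mean coverage in its
    2-voxel shell falls below ``gap_threshold`` × the mean over the two
    compartment interiors.
    """
    inv = {v: k for k, v in id_map.items()}
    fractions = {}
    for name, mask in dendrite_masks.items():
        total = int(mask.sum())
        if total == 0:
            fractions[name] = 0.0
            continue
        own = np.zeros_like(mask)
        for comp in assigned_compartments[name]:
            if comp in id_map:
                own |= compartment_labels == id_map[comp]
        fractions[name] = float((mask & ~own).sum() / total)

    gaps = {}
    if coverage is not None:
        present = sorted(inv)
        for i, ia in enumerate(present):
            for ib in present[i + 1:]:
                shell = _border_shell(compartment_labels, ia, ib)
                if shell.sum() < 8:
                    continue  # not an adjacent pair
                interior = ((compartment_labels == ia) | (compartment_labels == ib)) & ~shell
                shell_mean = float(coverage[shell].mean())
                interior_mean = float(coverage[interior].mean()) if interior.any() else 0.0
                pair = tuple(sorted((inv[ia], inv[ib])))
                gaps[pair] = bool(
                    interior_mean > 0 and shell_mean < gap_threshold * interior_mean
                )
    return {"cross_compartment_fraction": fractions, "border_gap": gaps}


def neuropil_fractions(
    group_volumes: dict[str, list[Volume]],
    neuropil_labels: Volume,
    id_map: dict[str, int],
    region_order: tuple[str, ...] | None = None,
) -> pd.DataFrame:
    """Fraction of each group's signal in every cataloged neuropil.

    Each cell-type volume is normalized to unit total signal before group
    summation (so bright and dim reporters weigh equally); each group row is
    then divided by its total signal over all neuropils, so rows sum to 1.
    """
    regions = tuple(region_order or sorted(id_map))
    rows = {}
    labels = neuropil_labels.data
    for group, vols in group_volumes.items():
        acc = None
        for v in vols:
            d = v.data.astype(float)
            total = d.sum()
            if total <= 0:
                raise ValueError(f"group {group!r}: volume with zero total signal")
            acc = d / total if acc is None else acc + d / total
        if acc is None:
            raise ValueError(f"group {group!r} has no volumes")
        sums = ndimage.sum_labels(
            acc, labels, [id_map.get(r, -1) for r in regions]
        )
        total_in_neuropils = float(sums.sum())
        if total_in_neuropils <= 0:
            raise ValueError(f"group {group!r}: no signal inside any neuropil")
        rows[group] = sums / total_in_neuropils
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(regions))


@dataclass
class DensityGrid:
    """Per-cube mean intensities on an 8-bit scale, sorted by total density."""

    values: np.ndarray                 # (n_cubes, n_groups) uint8
    cube_indices: tuple[tuple[int, int, int], ...]  # block origins, sorted order
    groups: tuple[str, ...]
    cube_edge_um: tuple[float, float, float]

    def to_frame(self) -> pd.DataFrame:
        idx = [f"{z}_{y}_{x}" for z, y, x in self.cube_indices]
        return pd.DataFrame(self.values, index=idx, columns=list(self.groups))


def density_grid(
    group_volumes: dict[str, Volume],
    cube_voxels: int = 10,
) -> DensityGrid:
    """Heat-map grid of mean intensities in ``cube_voxels``³ blocks.

    Trailing partial cubes are averaged over their actual voxels.  Each group
    column is scaled linearly to 0–255 by its own maximum (an all-zero input
    yields an all-zero column, not an error).  Rows are ordered by the
    cross-group sum, descending, with ties broken by cube index.
    """
    names = tuple(group_volumes)
    first = group_volumes[names[0]]
    shape = first.shape
    for v in group_volumes.values():
        if v.shape != shape:
            raise ValueError("group volumes must share a grid")
    nblocks = [int(np.ceil(s / cube_voxels)) for s in shape]
    cols = []
    for name in names:
        d = group_volumes[name].data.astype(float)
        means = np.empty(nblocks)
        for iz in range(nblocks[0]):
            for iy in range(nblocks[1]):
                for ix in range(nblocks[2]):
                    block = d[
                        iz * cube_voxels:(iz + 1) * cube_voxels,
                        iy * cube_voxels:(iy + 1) * cube_voxels,
                        ix * cube_voxels:(ix + 1) * cube_voxels,
                    ]
                    means[iz, iy, ix] = block.mean()
        mx = means.max()
        scaled = np.zeros_like(means) if mx <= 0 else means / mx * 255
        cols.append(np.rint(scaled).astype(np.uint8).ravel())
    values = np.stack(cols, axis=1)
    origins = [
        (iz * cube_voxels, iy * cube_voxels, ix * cube_voxels)
        for iz in range(nblocks[0])
        for iy in range(nblocks[1])
        for ix in range(nblocks[2])
    ]
    totals = values.astype(int).sum(axis=1)
    order = sorted(range(len(origins)), key=lambda i: (-totals[i], i))
    return DensityGrid(
        values=values[order],
        cube_indices=tuple(origins[i] for i in order),
        groups=names,
        cube_edge_um=tuple(cube_voxels * s for s in first.spacing),
    )


def overlap_score(
    mask_a: np.ndarray,
    mask_b: np.ndarray,
    tolerance_radius_vox: float = 1.0,
) -> float:
    """Symmetrized directional coverage of two masks.

    ``|A within tolerance of B| / |A|`` averaged with the reverse direction.
    Identical masks score 1; masks separated by more than the tolerance
    score 0.  Empty masks score 0 (with a warning).
    """
    na, nb = int(mask_a.sum()), int(mask_b.sum())
    if na == 0 or nb == 0:
        warnings.warn("overlap_score: empty mask, score 0", stacklevel=2)
        return 0.0

    def directional(a, b, nb_count):
        if tolerance_radius_vox == 0:
            near_b = b
        else:
            dist = ndimage.distance_transform_edt(~b)
            near_b = dist <= tolerance_radius_vox
        return float((a & near_b).sum() / a.sum())

    return 0.5 * (directional(mask_a, mask_b, nb) + directional(mask_b, mask_a, na))


@dataclass
class OverlapMatrix:
    scores: pd.DataFrame       # symmetric type × type mean scores
    pair_counts: pd.DataFrame  # image pairs averaged per entry

    @property
    def mean_pairs(self) -> float:
        n = self.pair_counts.to_numpy()
        return float(n.sum() / n.size)


def build_overlap_matrix(
    masks_by_type: dict[str, list[np.ndarray]],
    tolerance_radius_vox: float = 1.0,
) -> OverlapMatrix:
    """Mean pairwise overlap over all image pairs, per cell-type pair.

    Each registered image (hemispheres treated as independent samples) in
    one type's list is paired with each image of the other type; scores are
    computed per image pair and averaged.
    """
    names = list(masks_by_type)
    n = len(names)
    scores = np.zeros((n, n))
    counts = np.zeros((n, n), int)
    for i, a in enumerate(names):
        for j in range(i, n):
            b = names[j]
            if i == j:
                imgs = masks_by_type[a]
                pairs = [
                    (imgs[p], imgs[q])
                    for p in range(len(imgs))
                    for q in range(p, len(imgs))
                ]
            else:
                pairs = [(ma, mb) for ma in masks_by_type[a] for mb in masks_by_type[b]]
            vals = [overlap_score(x, y, tolerance_radius_vox) for x, y in pairs]
            scores[i, j] = scores[j, i] = float(np.mean(vals)) if vals else 0.0
            counts[i, j] = counts[j, i] = len(pairs)
    return OverlapMatrix(
        pd.DataFrame(scores, index=names, columns=names),
        pd.DataFrame(counts, index=names, columns=names),
    )


def cluster_matrix(matrix: OverlapMatrix | pd.DataFrame, k: int = 3) -> dict[str, int]:
    """Ward clustering of the overlap matrix rows into ``k`` groups.

    Distance is ``1 − score / max(score)``; the result maps each cell type
    to a group id (1..k), deterministically.
    """
    scores = matrix.scores if isinstance(matrix, OverlapMatrix) else matrix
    s = scores.to_numpy(dtype=float)
    if not np.allclose(s, s.T, atol=1e-9):
        raise ValueError("overlap matrix must be symmetric")
    if not np.all(np.isfinite(s)):
        raise ValueError("overlap matrix must be finite")
    if k > len(scores):
        raise ValueError(f"k={k} exceeds the number of rows ({len(scores)})")
    mx = s.max()
    d = 1 - s / mx if mx > 0 else np.ones_like(s)
    np.fill_diagonal(d, 0.0)
    condensed = squareform(d, checks=False)
    z = linkage(condensed, method="ward")
    assign = fcluster(z, t=k, criterion="maxclust")
    return dict(zip(scores.index, (int(a) for a in assign)))
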