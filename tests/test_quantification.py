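"""Compartment tiling, projection fractions, density cubes, overlap matrices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mbatlas.phantom.brain import COMPARTMENT_IDS
from mbatlas.quantification import (
    build_compartment_masks,
    build_overlap_matrix,
    cluster_matrix,
    density_grid,
    neuropil_fractions,
    overlap_score,
    tiling_metrics,
)
from mbatlas.volume import Volume


def _vols(std, comps):
    return {c: [Volume(std.compartment_mask(c).astype(float),
                       std.reference.spacing)] for c in comps}


def test_compartment_masks_recover_ground_truth(std):
    comps = [c for c in COMPARTMENT_IDS]
    labels, id_map = build_compartment_masks(_vols(std, comps), std.lobe_mask)
    gt = std.compartment_labels.data
    mism = 0
    for c, i in id_map.items():
        mism += ((labels == i) != (gt == COMPARTMENT_IDS[c]))[std.lobe_mask].sum()
    # ground-truth inputs: agreement everywhere except <= a 1-voxel border band
    assert mism / std.lobe_mask.sum() < 0.02
    # labels partition the lobe mask
    assert (labels > 0).sum() == std.lobe_mask.sum()
    assert ((labels > 0) == std.lobe_mask).all()


def test_compartment_masks_tie_break_deterministic(std):
    same = Volume(std.lobe_mask.astype(float), std.reference.spacing)
    labels, id_map = build_compartment_masks(
        {"g1": [same], "g2": [same]}, std.lobe_mask
    )
    # identical inputs for adjacent compartments: fixed order wins everywhere
    assert set(np.unique(labels[std.lobe_mask])) == {id_map["g1"]}
    with pytest.raises(ValueError):
        build_compartment_masks({"g1": []}, std.lobe_mask)
    with pytest.raises(KeyError):
        build_compartment_masks({"zz": [same]}, std.lobe_mask)


def test_tiling_cross_compartment_fraction_monotone(std):
    from scipy import ndimage

    gt = std.compartment_labels.data
    mask = std.compartment_mask("g3")
    dilated = ndimage.binary_dilation(mask, iterations=2)
    out = tiling_metrics(
        {"t": mask, "t_dil": dilated},
        {"t": {"g3"}, "t_dil": {"g3"}},
        gt, COMPARTMENT_IDS,
    )
    f = out["cross_compartment_fraction"]
    assert f["t"] == 0.0
    assert f["t_dil"] > f["t"]


def test_tiling_border_gaps_exactly_flagged(std):
    out = tiling_metrics({}, {}, std.compartment_labels.data, COMPARTMENT_IDS,
                         coverage=std.reference.data)
    flagged = {p for p, f in out["border_gap"].items() if f}
    assert flagged == set(std.flagged_borders)


def test_neuropil_fractions_rows_and_invariance(std):
    zone = std.zone_mask("CRE").astype(float)
    labels = std.neuropil_labels
    table = neuropil_fractions(
        {"g": [Volume(zone, labels.spacing)]}, labels, std.neuropil_id_map
    )
    assert table.loc["g"].sum() == pytest.approx(1.0, abs=1e-6)
    assert table.loc["g", "CRE"] == pytest.approx(1.0)
    # 10× gain on a second cell type of identical shape changes nothing
    t2 = neuropil_fractions(
        {"g": [Volume(zone, labels.spacing), Volume(zone * 10, labels.spacing)]},
        labels, std.neuropil_id_map,
    )
    pd.testing.assert_frame_equal(table, t2)
    with pytest.raises(ValueError):
        neuropil_fractions({"g": [Volume(np.zeros_like(zone), labels.spacing)]},
                           labels, std.neuropil_id_map)


def test_density_grid_scaling_and_order():
    uniform = Volume(np.ones((20, 20, 20)), (0.38, 0.38, 0.38))
    g = density_grid({"u": uniform}, cube_voxels=10)
    assert (g.values == 255).all()
    # at the working resolution the physical cube edge is 3.8 µm
    assert g.cube_edge_um == (3.8, 3.8, 3.8)

    single = np.zeros((20, 20, 20))
    single[2:8, 2:8, 2:8] = 7.0
    g2 = density_grid({"u": Volume(single, (0.38,) * 3)}, cube_voxels=10)
    assert (g2.values[0] > 0).all() or g2.values[0, 0] > 0
    assert (g2.values[1:] == 0).all()
    assert g2.cube_indices[0] == (0, 0, 0)

    # trailing partial cubes are averaged over their actual voxels
    odd = Volume(np.ones((15, 15, 15)), (1.0, 1.0, 1.0))
    g3 = density_grid({"u": odd}, cube_voxels=10)
    assert (g3.values == 255).all()

    empty = density_grid({"u": Volume(np.zeros((10, 10, 10)), (1, 1, 1))}, 10)
    assert (empty.values == 0).all()


def test_overlap_score_identities():
    a = np.zeros((10, 10, 10), bool)
    a[2:5, 2:5, 2:5] = True
    assert overlap_score(a, a, 0) == 1.0
    b = np.zeros_like(a)
    b[7:9, 7:9, 7:9] = True
    assert overlap_score(a, b, 0) == 0.0
    with pytest.warns(UserWarning):
        assert overlap_score(a, np.zeros_like(a)) == 0.0


def test_overlap_half_containment_oracle():
    """A equals one of B's two far-apart halves: directional 1.0 and 0.5."""
    b = np.zeros((10, 10, 10), bool)
    b[1:3, 1:3, 1:3] = True
    b[7:9, 7:9, 7:9] = True
    a = np.zeros_like(b)
    a[1:3, 1:3, 1:3] = True
    # brute-force voxel-count oracle
    d_ab = (a & b).sum() / a.sum()
    d_ba = (b & a).sum() / b.sum()
    assert 0.5 * (d_ab + d_ba) == 0.75
    assert overlap_score(a, b, 0) == pytest.approx(0.75)


@settings(max_examples=30, derandomize=True)
@given(st.integers(0, 10 ** 9))
def test_overlap_score_symmetric_bounded(seed):
    rng = np.random.default_rng(seed)
    a = rng.random((8, 8, 8)) < 0.2
    b = rng.random((8, 8, 8)) < 0.2
    if not (a.any() and b.any()):
        return
    s = overlap_score(a, b, 1.0)
    assert 0.0 <= s <= 1.0
    assert s == pytest.approx(overlap_score(b, a, 1.0))


def test_overlap_matrix_and_ward_clusters():
    rng = np.random.default_rng(1)
    masks = {}
    centers = [(3, 3, 3), (4, 4, 4), (3, 4, 3),
               (12, 12, 3), (13, 12, 3), (12, 13, 4),
               (3, 12, 12), (4, 13, 12), (3, 12, 13)]
    for i, c in enumerate(centers):
        m = np.zeros((18, 18, 18), bool)
        m[c[0] - 2:c[0] + 2, c[1] - 2:c[1] + 2, c[2] - 2:c[2] + 2] = True
        masks[f"t{i}"] = [m]
    om = build_overlap_matrix(masks, tolerance_radius_vox=1.0)
    s = om.scores.to_numpy()
    assert np.allclose(s, s.T)
    assert np.all(np.diag(s) >= s.max(axis=1) - 1e-9)
    cl = cluster_matrix(om, 3)
    groups = [frozenset(n for n, g in cl.items() if g == k) for k in (1, 2, 3)]
    assert frozenset({"t0", "t1", "t2"}) in groups
    assert frozenset({"t3", "t4", "t5"}) in groups
    assert frozenset({"t6", "t7", "t8"}) in groups
    # permutation invariance up to relabeling
    perm = list(om.scores.index)[::-1]
    cl2 = cluster_matrix(om.scores.loc[perm, perm], 3)
    part2 = {frozenset(n for n, g in cl2.items() if g == k) for k in set(cl2.values())}
    assert part2 == set(groups)


def test_cluster_matrix_edges():
    df = pd.DataFrame(np.eye(4), index=list("abcd"), columns=list("abcd"))
    singletons = cluster_matrix(df, 4)
    assert sorted(singletons.values()) == [1, 2, 3, 4]
    with pytest.raises(ValueError):
        cluster_matrix(df, 5)
    asym = df.copy()
    asym.iloc[0, 1] = 0.5
    with pytest.raises(ValueError):
        cluster_matrix(asym, 2)
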