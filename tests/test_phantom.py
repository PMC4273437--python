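"""Synthetic-brain generators: tiling, determinism, ground-truth contracts."""

import numpy as np
import pytest

from mbatlas.phantom import (
    DeformationSpec,
    NoiseSpec,
    NucleiSpec,
    PhantomSpec,
    default_pa_cells,
    make_nucleus_field,
    make_photoactivation_pair,
    make_specimen,
    make_standard_brain,
    random_specimen_transform,
)
from mbatlas.phantom.brain import COMPARTMENT_IDS
from mbatlas.registration import SpatialTransform

NO_NOISE = NoiseSpec(gaussian_sd=0.0, poisson_gain=None)


def test_compartments_partition_lobes(std):
    labels = std.compartment_labels.data
    lobe = std.lobe_mask
    # union of compartment masks is the lobe mask, pairwise disjoint by
    # construction of a single label volume
    total = 0
    for comp, code in COMPARTMENT_IDS.items():
        total += (labels == code).sum()
    assert total == lobe.sum()
    assert set(np.unique(labels)) == set(range(0, 17))


def test_standard_brain_deterministic():
    a = make_standard_brain(PhantomSpec(shape=(32, 48, 48)))
    b = make_standard_brain(PhantomSpec(shape=(32, 48, 48)))
    np.testing.assert_array_equal(a.reference.data, b.reference.data)
    np.testing.assert_array_equal(a.compartment_labels.data, b.compartment_labels.data)


def test_border_dip_intensity():
    """Dip factor 0.5 -> border-shell reference intensity <= 0.6× interiors."""
    std = make_standard_brain(PhantomSpec(border_dip_factor=0.5))
    ref = std.reference.data
    labels = std.compartment_labels.data
    for a, b in std.flagged_borders:
        ia, ib = COMPARTMENT_IDS[a], COMPARTMENT_IDS[b]
        from scipy import ndimage

        am, bm = labels == ia, labels == ib
        shell = (am & ndimage.binary_dilation(bm)) | (bm & ndimage.binary_dilation(am))
        interior = (am | bm) & ~ndimage.binary_dilation(shell, iterations=2)
        assert ref[shell].mean() <= 0.6 * ref[interior].mean(), (a, b)


def test_overlapping_dimmed_border_must_be_adjacent():
    with pytest.raises(ValueError):
        make_standard_brain(PhantomSpec(dimmed_borders=(("g1", "g5"),)))


def test_specimen_identity_no_noise_matches_ground_truth(std):
    sp = make_specimen(std, SpatialTransform(), ("MBON-a2sc",), NO_NOISE, seed=0)
    gt = sp.ground_truth
    assert np.array_equal(sp.membrane.data > 0.5, gt.membrane_mask)
    assert np.array_equal(gt.membrane_mask, gt.terminal_mask | gt.dendrite_mask)
    assert not (gt.terminal_mask & gt.dendrite_mask).any()


def test_specimen_presynaptic_enrichment(std):
    """Presynaptic/membrane ratio over terminals >= 5× the dendritic ratio."""
    sp = make_specimen(std, SpatialTransform(), ("MBON-b1>a",), NO_NOISE, seed=0)
    gt = sp.ground_truth
    r_term = (sp.presynaptic.data[gt.terminal_mask].mean()
              / sp.membrane.data[gt.terminal_mask].mean())
    r_dend = (sp.presynaptic.data[gt.dendrite_mask].mean()
              / sp.membrane.data[gt.dendrite_mask].mean())
    assert r_term / r_dend >= 5


def test_specimen_seed_changes_noise_not_truth(std):
    t = random_specimen_transform(std.reference.shape, 0.76, seed=3)
    a = make_specimen(std, t, ("MBON-a2sc",), NoiseSpec(0.02, 100.0), seed=1)
    b = make_specimen(std, t, ("MBON-a2sc",), NoiseSpec(0.02, 100.0), seed=2)
    np.testing.assert_array_equal(
        a.ground_truth.membrane_mask, b.ground_truth.membrane_mask
    )
    np.testing.assert_array_equal(
        a.ground_truth.specimen_compartment_labels.data,
        b.ground_truth.specimen_compartment_labels.data,
    )
    assert not np.array_equal(a.reference.data, b.reference.data)


def test_specimen_rejects_noninvertible_transform(std):
    bad = SpatialTransform(np.diag([1.0, 1.0, 1.0]))
    # a field folding space onto itself: huge opposing displacements
    field = np.zeros((3,) + std.reference.shape)
    field[1, :, : std.reference.shape[1] // 2, :] = 50.0
    field[1, :, std.reference.shape[1] // 2:, :] = -50.0
    bad.field = field
    bad.field_spacing = std.reference.spacing
    assert bad.min_jacobian_det() <= 0
    with pytest.raises(ValueError):
        make_specimen(std, bad, ("MBON-a2sc",), NO_NOISE, seed=0)


def test_specimen_unknown_type(std):
    with pytest.raises(KeyError):
        make_specimen(std, SpatialTransform(), ("MBON-zz",), NO_NOISE, seed=0)


@pytest.mark.parametrize("seed", range(3))
def test_random_transform_is_diffeomorphic(seed):
    t = random_specimen_transform((32, 48, 48), 0.76, seed=seed,
                                  spec=DeformationSpec())
    assert t.min_jacobian_det() > 0


def test_nucleus_field_empty():
    nf = make_nucleus_field(NucleiSpec(n=0), seed=0)
    assert nf.true_count == 0
    assert nf.nuclear.data.max() == 0


def test_nucleus_field_component_oracle():
    """Non-touching: labeling the half-max ground truth gives exactly n."""
    from scipy import ndimage

    nf = make_nucleus_field(NucleiSpec(n=50, touching_fraction=0.0), seed=4)
    _lab, n = ndimage.label(nf.nuclear.data >= 0.5, structure=np.ones((3, 3, 3)))
    assert n == 50
    assert len(nf.touching_pairs) == 0


def test_nucleus_field_touching_merges_components():
    from scipy import ndimage

    nf = make_nucleus_field(NucleiSpec(n=50, touching_fraction=0.2), seed=4)
    assert len(nf.touching_pairs) == 5
    _lab, n = ndimage.label(nf.nuclear.data >= 0.3, structure=np.ones((3, 3, 3)))
    assert n <= 50


def test_nucleus_field_density_error():
    with pytest.raises(RuntimeError):
        make_nucleus_field(NucleiSpec(n=500), seed=0, shape=(24, 32, 32))


def test_pa_pair_no_intersection_is_noise_only():
    cells, region = default_pa_cells(n_intersecting=0, n_other=4, seed=1)
    pair = make_photoactivation_pair(region, cells, seed=1, noise_sd=0.01)
    assert pair.activated_truth == (False,) * 4
    assert np.abs(pair.post.data - pair.pre.data).max() < 0.1


def test_pa_pair_small_cell_brightens_above_threshold():
    cells, region = default_pa_cells(n_intersecting=1, n_other=0, seed=2)
    pair = make_photoactivation_pair(region, cells, brightness=10, seed=2)
    soma = pair.cells[0].soma_mask(region.shape)
    roi_vals = pair.pre.data[pair.roi_mask]
    assert pair.post.data[soma].mean() > roi_vals.mean() + 2 * roi_vals.std()


def test_pa_pair_dilution_attenuates_large_cell():
    from mbatlas.phantom import PaCell

    _cells, region = default_pa_cells(seed=3)
    big = PaCell((10, 10, 10), ((10, 80, 10), (50, 90, 50), (32, 48, 38)),
                 soma_radius_vox=5, arbor_radius_vox=4)
    pair = make_photoactivation_pair(region, [big], brightness=10, seed=3,
                                     dilution_threshold=0.5)
    frac = (big.mask & region).sum() / big.mask.sum()
    assert frac < 0.5
    soma = big.soma_mask(region.shape)
    gain = pair.post.data[soma].mean() - pair.pre.data[soma].mean()
    assert gain < 10 * frac / 0.5 + 1.0
    assert pair.activated_truth == (False,)
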