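import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import ndimage

from mptissue.signatures import (
    TissueSignatureSet,
    auto_seeds,
    extract_signatures,
    multiparametric_roi,
    region_grow,
    sample_balanced,
    signature_sets_from_labels,
)


def bfs_oracle(volume, seed, tol=0.05):
    """Independent re-implementation of the acceptance rule: frontier kept
    as a sorted list, running-mean band max(tol*|mu|, 0)."""
    vol = np.asarray(volume, dtype=float)
    if vol.ndim == 2:
        vol = vol[:, :, None]
        seed = (*seed, 0)
    offs = [(dx, dy, dz) for dx in (-1, 0, 1) for dy in (-1, 0, 1)
            for dz in (-1, 0, 1) if (dx, dy, dz) != (0, 0, 0)]
    accepted = {seed}
    total = float(vol[seed])
    seen = {seed}
    frontier = []
    for o in offs:
        nb = tuple(np.add(seed, o))
        if all(0 <= nb[i] < vol.shape[i] for i in range(3)) and nb not in seen:
            seen.add(nb)
            frontier.append(nb)
    while frontier:
        frontier.sort()
        v = frontier.pop(0)
        mu = total / len(accepted)
        if abs(vol[v] - mu) <= tol * abs(mu):
            accepted.add(v)
            total += float(vol[v])
            for o in offs:
                nb = tuple(np.add(v, o))
                if all(0 <= nb[i] < vol.shape[i] for i in range(3)) \
                        and nb not in seen:
                    seen.add(nb)
                    frontier.append(nb)
    mask = np.zeros(vol.shape, dtype=bool)
    for v in accepted:
        mask[v] = True
    return mask if np.asarray(volume).ndim == 3 else mask[:, :, 0]


class TestRegionGrow:
    def test_block_example(self):
        img = np.full((5, 5), 200.0)
        img[1:4, 1:4] = 100.0
        mask = region_grow(img, (2, 2))
        expected = np.zeros((5, 5), dtype=bool)
        expected[1:4, 1:4] = True
        np.testing.assert_array_equal(mask, expected)

    def test_constant_volume_fills_grid(self):
        vol = np.full((4, 4, 3), 7.0)
        assert region_grow(vol, (0, 0, 0)).all()

    def test_four_percent_merges_six_percent_does_not(self):
        img = np.full((4, 8), 100.0)
        img[:, 4:] = 104.0
        assert region_grow(img, (1, 1)).all()
        img[:, 4:] = 106.0
        mask = region_grow(img, (1, 1))
        expected = np.zeros((4, 8), dtype=bool)
        expected[:, :4] = True
        np.testing.assert_array_equal(mask, expected)

    @pytest.mark.parametrize("seed_rng", range(4))
    def test_matches_bfs_oracle(self, seed_rng):
        rng = np.random.default_rng(seed_rng)
        vol = rng.choice([1.0, 1.03, 1.3], size=(4, 4, 3),
                         p=[0.5, 0.3, 0.2]) * 100
        seed = tuple(rng.integers(0, s) for s in vol.shape)
        np.testing.assert_array_equal(region_grow(vol, seed),
                                      bfs_oracle(vol, seed))

    def test_single_connected_component_containing_seed(self):
        rng = np.random.default_rng(3)
        vol = rng.normal(100, 3, size=(6, 6, 4))
        seed = (2, 3, 1)
        mask = region_grow(vol, seed)
        assert mask[seed]
        lab, n = ndimage.label(mask, structure=np.ones((3, 3, 3)))
        assert n == 1

    def test_2d_mode_stays_in_slice(self):
        vol = np.full((4, 4, 3), 5.0)
        mask = region_grow(vol, (1, 1, 1), mode="2d")
        assert mask[:, :, 1].all()
        assert not mask[:, :, 0].any() and not mask[:, :, 2].any()

    def test_seed_outside_grid(self):
        with pytest.raises(ValueError, match="outside"):
            region_grow(np.zeros((3, 3, 3)), (5, 0, 0))

    def test_nonfinite_seed(self):
        vol = np.zeros((3, 3, 3))
        vol[1, 1, 1] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            region_grow(vol, (1, 1, 1))

    def test_global_sd_mode(self):
        img = np.full((4, 8), 100.0)
        img[:, 4:] = 200.0
        mask = region_grow(img, (0, 0), tolerance_reference="global_sd")
        assert mask[:, :4].all() and not mask[:, 4:].any()


class TestMultiparametricRoi:
    def test_idempotence(self):
        rng = np.random.default_rng(0)
        a = rng.random((4, 4)) > 0.5
        np.testing.assert_array_equal(multiparametric_roi([a, a]), a)

    def test_disjoint_warns_empty(self):
        a = np.zeros((3, 3), dtype=bool)
        b = np.zeros((3, 3), dtype=bool)
        a[0, 0] = b[2, 2] = True
        with pytest.warns(UserWarning, match="empty"):
            out = multiparametric_roi([a, b])
        assert not out.any()

    def test_equals_elementwise_product(self):
        rng = np.random.default_rng(1)
        masks = [rng.random((4, 4)) > 0.4 for _ in range(3)]
        expected = masks[0].astype(int) * masks[1] * masks[2]
        np.testing.assert_array_equal(multiparametric_roi(masks),
                                      expected.astype(bool))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            multiparametric_roi([])

    @given(st.integers(0, 2 ** 16 - 1), st.integers(0, 2 ** 16 - 1),
           st.integers(0, 2 ** 16 - 1))
    @settings(max_examples=30, deadline=None)
    def test_inclusion_property(self, b0, b1, b2):
        masks = [np.array([(b >> i) & 1 for i in range(16)],
                          dtype=bool).reshape(4, 4) for b in (b0, b1, b2)]
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = multiparametric_roi(masks)
        for m in masks:
            assert np.all(out <= m)


class TestExtractSignatures:
    def test_single_voxel(self, small_phantom):
        roi = np.zeros(small_phantom.study.grid_shape, dtype=bool)
        roi[4, 5, 2] = True
        out = extract_signatures(small_phantom.study, roi, 3)
        assert out.signatures.shape == (1, small_phantom.study.n_channels)
        np.testing.assert_array_equal(
            out.signatures[0], small_phantom.study.signature_at((4, 5, 2)))

    def test_row_count(self, small_phantom):
        roi = small_phantom.truth_labels.mask(2)
        out = extract_signatures(small_phantom.study, roi, 2)
        assert len(out) == int(roi.sum())
        assert np.all(out.labels == 2)

    def test_noiseless_lesion_rows_identical(self, noiseless_phantom):
        roi = noiseless_phantom.truth_labels.mask(3)
        out = extract_signatures(noiseless_phantom.study, roi, 3)
        assert np.ptp(out.signatures, axis=0).max() == 0.0

    def test_empty_roi_rejected(self, small_phantom):
        roi = np.zeros(small_phantom.study.grid_shape, dtype=bool)
        with pytest.raises(ValueError, match="empty"):
            extract_signatures(small_phantom.study, roi, 0)


def _toy_sets(counts, d=3, seed=0):
    rng = np.random.default_rng(seed)
    sets = []
    for cid, n in enumerate(counts):
        sets.append(TissueSignatureSet(
            signatures=rng.random((n, d)),
            labels=np.full(n, cid),
            provenance=[("s", (i, 0, 0)) for i in range(n)],
        ))
    return sets


class TestSampleBalanced:
    def test_min_count_rule(self):
        out = sample_balanced(_toy_sets([2000, 1500, 1200, 900]),
                              cap_per_class=1000, seed=0)
        assert len(out) == 3600
        assert all(int((out.labels == c).sum()) == 900 for c in range(4))

    def test_cap_applies(self):
        out = sample_balanced(_toy_sets([50, 40, 30, 20]), cap_per_class=10,
                              seed=0)
        assert all(int((out.labels == c).sum()) == 10 for c in range(4))

    def test_determinism(self):
        sets = _toy_sets([40, 40, 40, 40])
        a = sample_balanced(sets, cap_per_class=20, seed=5)
        b = sample_balanced(sets, cap_per_class=20, seed=5)
        np.testing.assert_array_equal(a.signatures, b.signatures)

    def test_rows_exist_in_pool(self):
        sets = _toy_sets([30, 30, 30, 30])
        pool = np.vstack([s.signatures for s in sets])
        out = sample_balanced(sets, cap_per_class=15, seed=2)
        for row in out.signatures:
            assert (pool == row).all(axis=1).any()

    def test_empty_class_rejected(self):
        sets = _toy_sets([10, 10, 10, 10])[:3]
        with pytest.raises(ValueError, match="zero"):
            sample_balanced(sets, cap_per_class=5, seed=0)


class TestHelpers:
    def test_auto_seeds_on_class_voxels(self, small_phantom):
        seeds = auto_seeds(small_phantom.truth_labels, n_per_class=2, seed=0)
        for cid, pts in seeds.items():
            for p in pts:
                assert small_phantom.truth_labels.labels[p] == cid

    def test_signature_sets_from_labels_balancedable(self, small_phantom):
        sets = signature_sets_from_labels(small_phantom.study,
                                          small_phantom.truth_labels,
                                          max_per_class=50, seed=0)
        assert len(sets) == 4
        assert all(len(s) <= 50 for s in sets)
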