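"""Region extraction and contour-property computation/filtering."""

import numpy as np
import pytest
from skimage.draw import disk, ellipse

from cytonuclei.contours import (
    Region,
    compute_features,
    extract_regions,
    features_table,
    filter_regions,
    inertia_ratio,
    solidity,
)
from cytonuclei.params import ParameterSet

from oracles import flood_fill_8, inertia_ratio_bruteforce, solidity_bruteforce


def _region_from_coords(coords) -> Region:
    return Region(label=1, pixels=np.array(sorted(coords)))


class TestExtractRegions:
    def test_empty_mask(self):
        assert extract_regions(np.zeros((5, 5), bool)) == []

    def test_two_disjoint_blocks(self):
        mask = np.zeros((10, 10), bool)
        mask[1:4, 1:4] = True
        mask[6:9, 6:9] = True
        regions = extract_regions(mask)
        assert [r.area for r in regions] == [9, 9]
        assert [r.label for r in regions] == [1, 2]

    def test_diagonal_pixels_are_one_region(self):
        mask = np.zeros((4, 4), bool)
        mask[1, 1] = mask[2, 2] = True
        regions = extract_regions(mask)
        assert len(regions) == 1
        assert regions[0].area == 2

    def test_matches_flood_fill_oracle(self, rng):
        for _ in range(20):
            mask = rng.random((12, 14)) > 0.6
            regions = extract_regions(mask)
            comps = flood_fill_8(mask)
            assert len(regions) == len(comps)
            for reg, comp in zip(regions, comps):
                # extraction fills holes, so the component is a subset
                got = set(map(tuple, reg.pixels))
                assert comp <= got

    def test_labels_in_raster_order_of_first_pixel(self, rng):
        mask = rng.random((15, 15)) > 0.65
        regions = extract_regions(mask)
        firsts = [tuple(r.pixels[0]) for r in regions]
        assert firsts == sorted(firsts)

    def test_holes_are_filled(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True
        mask[4, 4] = False
        regions = extract_regions(mask)
        assert len(regions) == 1
        assert regions[0].area == 25

    def test_nested_component_not_swallowed(self):
        # a ring with an isolated blob inside its hole: the ring's fill must
        # not claim the blob's pixels, keeping the regions disjoint
        mask = np.zeros((11, 11), bool)
        mask[1:10, 1:10] = True
        mask[3:8, 3:8] = False
        mask[5, 5] = True
        regions = extract_regions(mask)
        assert len(regions) == 2
        sets = [set(map(tuple, r.pixels)) for r in regions]
        assert not (sets[0] & sets[1])

    def test_boundary_is_subset_with_exterior_neighbour(self):
        mask = np.zeros((8, 8), bool)
        mask[2:6, 2:6] = True
        region = extract_regions(mask)[0]
        boundary = set(map(tuple, region.boundary))
        assert boundary == {(r, c) for r in range(2, 6) for c in range(2, 6)
                            if r in (2, 5) or c in (2, 5)}


class TestSolidity:
    def test_filled_rectangle_is_one(self):
        coords = [(r, c) for r in range(3, 9) for c in range(2, 6)]
        assert solidity(_region_from_coords(coords)) == 1.0

    def test_single_pixel_and_collinear_convention(self):
        assert solidity(_region_from_coords([(4, 4)])) == 1.0
        assert solidity(_region_from_coords([(1, c) for c in range(6)])) == 1.0

    def test_l_shape_matches_enumeration(self):
        # L-shape of 9 pixels; hull is the triangle r+c <= 4 holding 15
        # pixel centres -> solidity 9/15
        coords = [(r, 0) for r in range(5)] + [(0, c) for c in range(1, 5)]
        region = _region_from_coords(coords)
        assert solidity(region) == pytest.approx(
            solidity_bruteforce(region.pixels), abs=1e-9)
        assert solidity(region) == pytest.approx(9 / 15, abs=1e-9)

    def test_matches_bruteforce_on_random_blobs(self, rng):
        for _ in range(15):
            mask = np.zeros((18, 18), bool)
            rr, cc = disk((rng.uniform(6, 12), rng.uniform(6, 12)),
                          rng.uniform(3, 5), shape=mask.shape)
            mask[rr, cc] = True
            mask[rng.integers(0, 18, 8), rng.integers(0, 18, 8)] = True
            for region in extract_regions(mask):
                assert solidity(region) == pytest.approx(
                    solidity_bruteforce(region.pixels), abs=1e-9)


class TestInertiaRatio:
    def test_disc_is_nearly_one(self):
        mask = np.zeros((41, 41), bool)
        rr, cc = disk((20, 20), 15, shape=mask.shape)
        mask[rr, cc] = True
        region = extract_regions(mask)[0]
        assert inertia_ratio(region) == pytest.approx(1.0, abs=0.05)

    def test_thin_line_is_nearly_zero(self):
        coords = [(10, c) for c in range(50)]
        assert inertia_ratio(_region_from_coords(coords)) < 0.1

    def test_ellipse_axis_ratio(self):
        mask = np.zeros((60, 80), bool)
        rr, cc = ellipse(30, 40, 10, 20, shape=mask.shape)
        mask[rr, cc] = True
        region = extract_regions(mask)[0]
        assert inertia_ratio(region) == pytest.approx(0.5, abs=0.05)

    def test_single_pixel_convention(self):
        assert inertia_ratio(_region_from_coords([(3, 3)])) == 1.0

    def test_matches_bruteforce_moments(self, rng):
        for _ in range(15):
            n = int(rng.integers(2, 60))
            coords = {(int(r), int(c))
                      for r, c in zip(rng.integers(0, 25, n), rng.integers(0, 25, n))}
            region = _region_from_coords(coords)
            assert inertia_ratio(region) == pytest.approx(
                inertia_ratio_bruteforce(region.pixels), abs=1e-9)


class TestFilterRegions:
    @pytest.fixture
    def img(self):
        return np.full((40, 40), 100, dtype=np.uint8)

    def test_low_solidity_rejected(self, img):
        # thin L-shape: solidity well below 0.8
        coords = [(5, c) for c in range(5, 20)] + [(r, 5) for r in range(6, 20)]
        region = _region_from_coords(coords)
        assert solidity(region) < 0.5
        params = ParameterSet(MinSolid=0.8, MinSize=2, MaxSize=500, MinInertia=0.0)
        assert filter_regions([region], img, params) == []

    def test_size_window(self, img):
        params = ParameterSet(MinSolid=0.1, MinSize=5, MaxSize=70, MinInertia=0.0,
                              size_measure="area")
        sizes = [4, 30, 500]
        regions = []
        for i, s in enumerate(sizes):
            rows = int(np.ceil(s / 10)) or 1
            coords = [(i * 12 + r, c) for r in range(rows) for c in range(10)][:s]
            regions.append(Region(label=i + 1, pixels=np.array(coords)))
        kept = filter_regions(regions, img, params)
        assert [r.area for r in kept] == [30]

    def test_empty_input(self, img, default_params):
        assert filter_regions([], img, default_params) == []

    def test_elongated_region_rejected_by_inertia(self, img):
        coords = [(10, c) for c in range(5, 35)] + [(11, c) for c in range(5, 35)]
        region = _region_from_coords(coords)
        params = ParameterSet(MinSolid=0.1, MinSize=1, MaxSize=500, MinInertia=0.3,
                              size_measure="area")
        assert filter_regions([region], img, params) == []

    def test_acceptance_anti_monotone(self, rng, img):
        # tightening any filter bound never adds a region
        masks = rng.random((30, 40, 40)) > 0.72
        base = ParameterSet(MinSolid=0.5, MinSize=3, MaxSize=200, MinInertia=0.1,
                            size_measure="area")
        tighter = [
            base.replace(MinSolid=0.8),
            base.replace(MinInertia=0.4),
            base.replace(MinSize=10),
            base.replace(MaxSize=60),
        ]
        for mask in masks:
            regions = extract_regions(mask)
            kept = {r.label for r in filter_regions(regions, img, base)}
            for p in tighter:
                sub = {r.label for r in filter_regions(regions, img, p)}
                assert sub <= kept

    def test_kept_regions_satisfy_predicate(self, rng, img):
        from cytonuclei.contours import region_size

        mask = rng.random((40, 40)) > 0.7
        params = ParameterSet(MinSolid=0.6, MinSize=2, MaxSize=50, MinInertia=0.2)
        for r in filter_regions(extract_regions(mask), img, params):
            assert params.MinSize <= region_size(r, params.size_measure) <= params.MaxSize
            assert solidity(r) >= params.MinSolid
            assert inertia_ratio(r) >= params.MinInertia


def test_features_table_columns(clean_fixture):
    img, gt, _ = clean_fixture
    regions = extract_regions(gt > 0)
    table = features_table(regions, img)
    assert list(table.columns) == [
        "label", "size", "area", "solidity", "inertia_ratio", "mean_intensity"]
    assert len(table) == len(regions)
    assert (table["solidity"] > 0).all() and (table["solidity"] <= 1).all()


def test_feature_invariants_on_fixture(clean_fixture):
    img, gt, manifest = clean_fixture
    regions = [Region(label=rec["label"],
                      pixels=np.argwhere(gt == rec["label"]))
               for rec in manifest]
    for region, rec in zip(regions, manifest):
        f = compute_features(region, img)
        assert 0 < f.solidity <= 1
        assert 0 <= f.inertia_ratio <= 1
        assert 0 <= f.mean_intensity <= 255
        assert f.inertia_ratio == pytest.approx(rec["axis_ratio"], abs=0.07)
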