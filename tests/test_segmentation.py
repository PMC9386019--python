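import numpy as np
import pytest
from scipy import ndimage

from wingmorph import segmentation as seg
from wingmorph.errors import InvalidSeedError, NoWingFoundError, TracingError

FOUR = ndimage.generate_binary_structure(2, 1)


def oracle_component(img, seed):
    """4-connected component of the seed (brute-force labelling oracle)."""
    lab, _ = ndimage.label(img, structure=FOUR)
    return lab == lab[seed]


class TestFloodDomain:
    def test_square_block_interior_and_ring(self):
        img = np.zeros((10, 10), bool)
        img[3:7, 3:7] = True
        r = seg.flood_domain(img, (4, 4))
        assert r.area == 16
        # ring rows 2-7 x cols 2-7 minus the block: 36 - 16 = 20 pixels
        assert len(r.boundary_pixels) == 20
        assert len(r.boundary_chain) == 20

    def test_single_white_pixel(self):
        img = np.zeros((5, 5), bool)
        img[2, 2] = True
        r = seg.flood_domain(img, (2, 2))
        assert r.area == 1
        assert len(r.boundary_pixels) == 8

    def test_one_pixel_vein_separates_cells(self):
        img = np.zeros((5, 9), bool)
        img[1:4, 1:4] = True
        img[1:4, 5:8] = True
        r = seg.flood_domain(img, (2, 2))
        assert r.area == 9
        assert r.interior[:, 1].max() <= 3

    def test_diagonal_one_pixel_vein_never_percolates(self):
        # white growth is 4-connected: a 1-px diagonal black line is tight
        img = np.ones((12, 12), bool)
        for i in range(12):
            img[i, i] = False
        r = seg.flood_domain(img, (0, 5))
        upper = {(i, j) for i in range(12) for j in range(12) if j > i}
        assert set(map(tuple, r.interior)) == upper

    def test_black_seed_rejected(self):
        img = np.zeros((4, 4), bool)
        with pytest.raises(InvalidSeedError):
            seg.flood_domain(img, (1, 1))

    def test_matches_component_labelling_oracle_on_random_images(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            img = rng.random((64, 64)) < 0.55
            whites = np.argwhere(img)
            if len(whites) == 0:
                continue
            s = tuple(whites[rng.integers(len(whites))])
            r = seg.flood_domain(img, s, trace=False)
            comp = oracle_component(img, s)
            np.testing.assert_array_equal(r.interior_mask(img.shape), comp)
            ring = ndimage.binary_dilation(comp, np.ones((3, 3))) & ~img
            got = np.zeros_like(img)
            got[r.boundary_pixels[:, 0], r.boundary_pixels[:, 1]] = True
            np.testing.assert_array_equal(got, ring)

    def test_seed_invariant_within_component(self):
        rng = np.random.default_rng(8)
        img = rng.random((40, 40)) < 0.6
        whites = np.argwhere(img)
        s0 = tuple(whites[0])
        base = seg.flood_domain(img, s0, trace=False)
        members = [tuple(p) for p in base.interior]
        for s in (members[len(members) // 2], members[-1]):
            other = seg.flood_domain(img, s, trace=False)
            np.testing.assert_array_equal(base.interior, other.interior)


class TestMainDomain:
    def test_circle_outline_main_is_disc(self):
        img = np.ones((60, 60), bool)
        rr, cc = np.meshgrid(np.arange(60), np.arange(60), indexing="ij")
        d = np.hypot(rr - 30, cc - 30)
        img[(d >= 20) & (d <= 22)] = False
        main = seg.detect_main_domain(img)
        # silhouette = everything not reachable from the border
        expected = d <= 22
        got = main.interior_mask(img.shape)
        assert (got == expected).mean() > 0.995  # rasterised circle edge wobble
        assert len(main.boundary_chain) > 100

    def test_fixture_silhouette_area(self, wing10, seg10):
        # silhouette = ellipse dilated by the outline stroke half-width
        from wingmorph.fixtures import _poly_xy

        w = wing10.params["vein_width"]
        analytic = _poly_xy(wing10.silhouette).buffer(w / 2.0).area
        assert seg10.main.area == pytest.approx(analytic, rel=0.005)

    @pytest.mark.parametrize("value", [True, False])
    def test_uniform_image_has_no_wing(self, value):
        with pytest.raises(NoWingFoundError):
            seg.detect_main_domain(np.full((10, 10), value))

    def test_black_frame_makes_whole_image_main(self):
        img = np.zeros((10, 10), bool)
        img[1:-1, 1:-1] = True
        img[4, 1:-1] = False
        main = seg.detect_main_domain(img)
        assert main.area == 100


class TestSubdomains:
    def test_fixture_recovers_every_cell(self, wing10, seg10):
        assert len(seg10.subdomains) == len(wing10.cells)

    def test_solid_silhouette_has_no_cells(self):
        img = np.ones((30, 30), bool)
        rr, cc = np.meshgrid(np.arange(30), np.arange(30), indexing="ij")
        img[np.hypot(rr - 15, cc - 15) <= 10] = False
        main = seg.detect_main_domain(img)
        assert seg.detect_subdomains(img, main) == []

    def test_minimum_area_discards_specks(self):
        img = np.ones((20, 20), bool)
        rr, cc = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        disc = np.hypot(rr - 10, cc - 10) <= 8
        img[disc] = False
        img[10, 10] = True  # 1-px speck inside the solid disc
        main = seg.detect_main_domain(img)
        assert seg.detect_subdomains(img, main, min_area=4) == []
        assert len(seg.detect_subdomains(img, main, min_area=1)) == 1

    def test_interiors_pairwise_disjoint_and_conserved(self, wing10, seg10):
        img = wing10.image
        total = np.zeros(img.shape, dtype=int)
        for r in seg10.subdomains:
            total[r.interior[:, 0], r.interior[:, 1]] += 1
        assert total.max() == 1
        # cells + veins + background account for every pixel
        background = ~seg10.main.interior_mask(img.shape)
        veins = seg10.main.interior_mask(img.shape) & ~img
        covered = (total > 0) | background | veins
        assert covered.all()


class TestDiscontinuities:
    def test_seeded_cell_reclassified(self, seg10):
        import copy

        result = copy.deepcopy(seg10)
        target = result.subdomains[3]
        s = tuple(target.interior[0])
        n = len(result.subdomains)
        out = seg.mark_discontinuities(result, [s])
        assert len(out.subdomains) == n - 1
        assert out.discontinuities[0].id == target.id
        assert out.discontinuities[0].kind == "discontinuity"

    def test_empty_seed_list_is_identity(self, seg10):
        import copy

        result = copy.deepcopy(seg10)
        out = seg.mark_discontinuities(result, [])
        assert len(out.subdomains) == len(seg10.subdomains)
        assert out.discontinuities == []

    def test_seed_outside_any_cell_rejected(self, seg10):
        import copy

        with pytest.raises(InvalidSeedError):
            seg.mark_discontinuities(copy.deepcopy(seg10), [(0, 0)])

    def test_damaged_fixture_hole_detected_and_marked(self, damaged_wing, wing10):
        dmg, hole_seed = damaged_wing
        result = seg.segment(dmg.image, hole_seeds=[hole_seed])
        assert len(result.discontinuities) == 1
        assert len(result.subdomains) == len(dmg.cells)
        assert len(dmg.cells) < len(wing10.cells)


class TestTraceBoundary:
    def test_square_ring_ordered_chain(self):
        img = np.zeros((10, 10), bool)
        img[3:7, 3:7] = True
        r = seg.flood_domain(img, (4, 4))
        chain = seg.trace_boundary(r.boundary_pixels)
        assert len(chain) == 20
        closed = np.vstack([chain, chain[:1]])
        steps = np.abs(np.diff(closed, axis=0)).max(axis=1)
        assert (steps == 1).all()

    def test_eight_neighbourhood_ring(self):
        pts = [(r, c) for r in range(3) for c in range(3) if (r, c) != (1, 1)]
        chain = seg.trace_boundary(np.array(pts))
        assert len(chain) == 8

    def test_disconnected_set_lists_components(self):
        pts = np.array([(0, 0), (0, 1), (5, 5), (5, 6)])
        with pytest.raises(TracingError) as err:
            seg.trace_boundary(pts)
        assert len(err.value.components) == 2

    def test_cell_chain_encloses_exactly_its_interior(self, seg10):
        from matplotlib.path import Path

        region = seg10.subdomains[0]
        chain = region.boundary_chain
        path = Path(chain[:, ::-1])  # (col, row) vertices
        inside = path.contains_points(region.interior[:, ::-1])
        assert inside.all()


class TestSerialization:
    def test_json_contains_all_regions(self, seg10, tmp_path):
        import json

        p = tmp_path / "seg.json"
        seg.write_result_json(seg10, p)
        doc = json.loads(p.read_text())
        assert len(doc["subdomains"]) == len(seg10.subdomains)
        assert doc["main"]["area"] == seg10.main.area
        ids = [r["id"] for r in doc["subdomains"]]
        assert len(set(ids)) == len(ids)

    def test_label_map_written(self, seg10, tmp_path):
        from PIL import Image

        p = tmp_path / "labels.png"
        seg.write_label_map(seg10, p)
        with Image.open(p) as im:
            assert im.size == (seg10.shape[1], seg10.shape[0])
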