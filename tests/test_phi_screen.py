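"""Dark-region detection and WSI screening."""

import numpy as np
import pytest

from pathbroker import image_deid, phi_screen
from pathbroker.phi_screen import (
    DarkRegionParams,
    detect_dark_regions,
    luminance,
    screen_wsi,
)


def white(h=100, w=100):
    return np.full((h, w, 3), 255, dtype=np.uint8)


def brute_force_components(mask, connectivity=8):
    """Independent BFS flood-fill labeling (oracle for small images)."""
    h, w = mask.shape
    seen = np.zeros_like(mask, dtype=bool)
    if connectivity == 8:
        nbrs = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    comps = []
    for i in range(h):
        for j in range(w):
            if mask[i, j] and not seen[i, j]:
                stack, comp = [(i, j)], []
                seen[i, j] = True
                while stack:
                    y, x = stack.pop()
                    comp.append((y, x))
                    for dy, dx in nbrs:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] \
                                and not seen[ny, nx]:
                            seen[ny, nx] = True
                            stack.append((ny, nx))
                comps.append(comp)
    return comps


class TestDetect:
    def test_all_white_no_regions(self):
        assert detect_dark_regions(white()) == []

    def test_planted_black_rectangle_fraction(self):
        """20% planted block -> one region at exactly that fraction."""
        img = white(100, 100)
        img[10:50, 20:70] = 0  # 40x50 = 2000 px = 20%
        regions = detect_dark_regions(img)
        assert len(regions) == 1
        assert regions[0].area_fraction == pytest.approx(0.20)
        assert regions[0].bbox == (10, 20, 50, 70)

    def test_two_small_blocks_found_but_not_qualifying(self):
        img = white(100, 100)
        img[0:10, 0:50] = 0   # 5%
        img[50:60, 50:100] = 0  # 5%, separated
        params = DarkRegionParams(min_area_fraction=0.08)
        regions = detect_dark_regions(img, params)
        assert len(regions) == 2
        assert all(r.area_fraction < params.min_area_fraction for r in regions)

    def test_empty_image_errors(self):
        with pytest.raises(ValueError):
            detect_dark_regions(np.zeros((0, 0, 3), dtype=np.uint8))

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_equivalence_with_brute_force_labeling(self, connectivity):
        """Component pixel-count multisets match a BFS flood fill."""
        rng = np.random.default_rng(42)
        img = (rng.random((64, 64, 3)) * 255).astype(np.uint8)
        params = DarkRegionParams(connectivity=connectivity)
        mask = luminance(img) < params.luminance_threshold
        expected = sorted(len(c) for c in
                          brute_force_components(mask, connectivity))
        got = sorted(r.pixel_count for r in detect_dark_regions(img, params))
        assert got == expected

    def test_regions_ordered_by_area_descending(self):
        img = white(100, 100)
        img[0:5, 0:5] = 0
        img[50:80, 50:80] = 0
        regions = detect_dark_regions(img)
        areas = [r.pixel_count for r in regions]
        assert areas == sorted(areas, reverse=True)


class TestScreen:
    def test_clean_tissue_not_flagged(self, dataset):
        img = dataset.warehouse_fixture.images[0]
        container = image_deid.read_container(img.file_path)
        decision = screen_wsi(container, image_id=img.image_id)
        assert not decision.flagged

    def test_simulated_sticker_flagged(self, tmp_path, small_spec, dataset):
        from pathbroker import fixtures

        img = dataset.warehouse_fixture.images[0]
        truth = fixtures.generate_wsi(
            small_spec,
            _bundle_for(dataset, img),
            tmp_path / "sticker.svs",
            dark_block_fraction=0.10,
        )
        container = image_deid.read_container(truth.path)
        params = DarkRegionParams(min_area_fraction=0.05)
        decision = screen_wsi(container, params)
        assert decision.flagged
        assert decision.regions[0].area_fraction >= truth.dark_fraction * 0.9

    def test_boundary_fraction_flags(self):
        """A region at exactly min_area_fraction is flagged (>=)."""
        img = white(100, 100)
        img[0:10, 0:50] = 0  # exactly 5%
        params = DarkRegionParams(min_area_fraction=0.05)
        regions = detect_dark_regions(img, params)
        assert regions[0].area_fraction == pytest.approx(0.05)
        flagged = any(r.area_fraction >= params.min_area_fraction
                      for r in regions)
        assert flagged

    def test_threshold_monotonicity(self):
        """Anything flagged at a low threshold stays flagged at a higher one."""
        rng = np.random.default_rng(7)
        img = (rng.random((80, 80, 3)) * 255).astype(np.uint8)
        img[0:30, 0:30] = 40
        flags = []
        for thr in (50, 100, 150, 200):
            p = DarkRegionParams(luminance_threshold=thr)
            flags.append(any(r.area_fraction >= p.min_area_fraction
                             for r in detect_dark_regions(img, p)))
        for lo, hi in zip(flags, flags[1:]):
            assert hi >= lo

    def test_growing_block_never_unflags(self):
        params = DarkRegionParams()
        flagged = []
        for frac in (0.05, 0.10, 0.20, 0.40):
            img = white(100, 100)
            side = int((frac * 100 * 100) ** 0.5)
            img[:side, :side] = 0
            regions = detect_dark_regions(img, params)
            flagged.append(any(r.area_fraction >= params.min_area_fraction
                               for r in regions))
        for lo, hi in zip(flagged, flagged[1:]):
            assert hi >= lo

    def test_screening_is_pure(self, dataset):
        img = dataset.warehouse_fixture.images[0]
        before = open(img.file_path, "rb").read()
        container = image_deid.read_container(img.file_path)
        screen_wsi(container)
        assert open(img.file_path, "rb").read() == before


def _bundle_for(dataset, img):
    from pathbroker.records import IdentifierBundle

    wf = dataset.warehouse_fixture
    sld = next(s for s in wf.slides if s.barcode == img.barcode)
    return IdentifierBundle(barcode=sld.barcode, image_id=img.image_id,
                            accession=sld.accession)


@pytest.mark.parametrize(
    "kw",
    [dict(luminance_threshold=0), dict(luminance_threshold=255),
     dict(min_area_fraction=0.0), dict(min_area_fraction=1.0),
     dict(connectivity=6)],
)
def test_invalid_params_rejected(kw):
    with pytest.raises(ValueError):
        DarkRegionParams(**kw)
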