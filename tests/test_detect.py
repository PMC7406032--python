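"""Nucleus segmentation, declumping, truth matching and outlines."""

from dataclasses import replace

import numpy as np
import pytest

import imageio.v3 as iio

from tilecount.config import PipelineConfig
from tilecount.detect import (
    LabelImage,
    NucleusRecord,
    match_to_truth,
    render_outlines,
    segment_nuclei,
)
from tilecount.errors import ContractError
from tilecount.io import TiledWellImage
from tilecount.pipeline import count_single_well
from tilecount.synth import GroundTruth, SyntheticPlateSpec, render_well
from tilecount.wells import WellMask, disc_mask
from tests.conftest import SMALL_GEOMETRY


def small(**kw) -> SyntheticPlateSpec:
    return SyntheticPlateSpec(**{**SMALL_GEOMETRY, "rng_seed": 0, **kw})


def _full_mask(shape):
    return WellMask(np.ones(shape, bool), (shape[0] / 2, shape[1] / 2),
                    min(shape) / 2, 0.0)


def _spot(px, r0, c0, sigma, peak):
    h, w = px.shape
    rr = np.arange(h)[:, None] - r0
    cc = np.arange(w)[None, :] - c0
    px += peak * np.exp(-(rr**2 + cc**2) / (2 * sigma**2))


class TestSegmentNuclei:
    def test_blank_image_zero_objects(self, default_cfg):
        img = TiledWellImage(pixels=np.full((60, 60), 0.1))
        mask = _full_mask((60, 60))
        labels, recs = segment_nuclei(img, mask, default_cfg)
        assert labels.n_objects == 0 and recs == []

    def test_full_pipeline_recovers_exact_count(self, small_cfg):
        img, truth = render_well(small(n_nuclei=30))
        res = count_single_well(img, small_cfg)
        assert res.record.count == truth.nucleus_count
        matched, missed, spurious = match_to_truth(res.nuclei, truth, 5.0)
        assert (matched, missed, spurious) == (truth.nucleus_count, 0, 0)

    def test_watershed_splits_touching_pair(self, default_cfg):
        px = np.full((80, 80), 0.05)
        _spot(px, 40, 31, 4.0, 0.6)
        _spot(px, 40, 49, 4.0, 0.6)  # 1.5 diameters apart (d = 12)
        img = TiledWellImage(pixels=np.clip(px, 0, 1))
        mask = _full_mask((80, 80))
        cfg_ws = default_cfg.with_overrides(
            manual_threshold=0.1, nucleus_diameter_px=(3.0, 20.0)
        )
        labels_ws, recs = segment_nuclei(img, mask, cfg_ws)
        assert labels_ws.n_objects == 2
        assert recs[0].centroid[1] < 40 < recs[1].centroid[1]
        # without declumping the merged pair is unresolvable: the blob is
        # either dropped by the strict gate or kept as a single object
        labels_none, _ = segment_nuclei(
            img, mask, cfg_ws.with_overrides(declump="none")
        )
        assert labels_none.n_objects == 0
        labels_loose, _ = segment_nuclei(
            img, mask,
            cfg_ws.with_overrides(declump="none",
                                  nucleus_diameter_px=(3.0, 30.0)),
        )
        assert labels_loose.n_objects == 1

    def test_size_gate_rejects_debris_and_blobs(self, default_cfg):
        px = np.full((100, 100), 0.05)
        _spot(px, 30, 30, 2.0, 0.6)           # accepted nucleus
        px[70, 70] = 0.9                       # 1-px debris: below min gate
        px[10:40, 60:95] += 0.5                # huge blob: above max gate
        img = TiledWellImage(pixels=np.clip(px, 0, 1))
        cfg = default_cfg.with_overrides(
            manual_threshold=0.3, declump="none", nucleus_diameter_px=(3.0, 12.0)
        )
        labels, recs = segment_nuclei(img, _full_mask((100, 100)), cfg)
        assert labels.n_objects == 1
        assert recs[0].centroid == pytest.approx((30, 30), abs=1.0)

    def test_raising_threshold_never_increases_count(self, default_cfg):
        """Monotone in the operating regime: thresholds above background.

        Below the background level the count is dominated by how the gate
        and declumping carve up the giant background component, so the
        sweep starts at the automatic (Otsu) threshold.
        """
        from skimage.filters import threshold_otsu

        img, _ = render_well(small(n_nuclei=30))
        res = count_single_well(img, PipelineConfig(well_smooth_sigma=12.0,
                                                    illum_smooth_sigma=8.0))
        enhanced, mask = res.enhanced, res.mask
        t0 = float(threshold_otsu(enhanced.pixels[mask.mask]))
        counts = []
        for t in np.linspace(t0, 0.95, 8):
            cfg = default_cfg.with_overrides(manual_threshold=float(t))
            labels, _ = segment_nuclei(enhanced, mask, cfg)
            counts.append(labels.n_objects)
        assert counts[0] == 30
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_count_invariant_under_scene_translation(self, small_cfg):
        base = small(n_nuclei=25, rng_seed=6)
        c0 = count_single_well(render_well(base)[0], small_cfg).record.count
        shifted = replace(base, well_center=(180.0 + 15, 220.0 - 20))
        c1 = count_single_well(render_well(shifted)[0], small_cfg).record.count
        assert c0 == c1 == 25

    def test_labels_contiguous_and_sorted(self, small_cfg):
        img, _ = render_well(small(n_nuclei=20))
        res = count_single_well(img, small_cfg)
        labels = [r.label for r in res.nuclei]
        assert labels == list(range(1, len(labels) + 1))
        assert res.nuclei == sorted(res.nuclei, key=lambda r: r.centroid)
        for r in res.nuclei:
            assert r.equivalent_diameter_px == pytest.approx(
                2 * np.sqrt(r.area_px / np.pi), rel=1e-6
            )

    def test_empty_mask_rejected(self, default_cfg):
        img = TiledWellImage(pixels=np.zeros((20, 20)))
        mask = WellMask(np.zeros((20, 20), bool), (10, 10), 5.0, 0.0)
        with pytest.raises(ContractError):
            segment_nuclei(img, mask, default_cfg)


class TestMatchToTruth:
    def _records(self, centers):
        return [
            NucleusRecord(i + 1, tuple(c), 10, 3.57, 0.5)
            for i, c in enumerate(centers)
        ]

    def test_perfect_detection(self):
        centers = [(10.0, 10.0), (30.0, 40.0), (50.0, 5.0)]
        truth = GroundTruth(np.array(centers), 3, (0, 0), 10.0)
        assert match_to_truth(self._records(centers), truth, 5.0) == (3, 0, 0)

    def test_total_miss(self):
        truth = GroundTruth(np.random.default_rng(0).uniform(0, 100, (50, 2)),
                            50, (0, 0), 10.0)
        assert match_to_truth([], truth, 5.0) == (0, 50, 0)

    def test_partial_match_with_spurious(self):
        rng = np.random.default_rng(1)
        tru = rng.uniform(20, 180, (100, 2))
        detected = tru[:99] + rng.uniform(-1.4, 1.4, (99, 2))
        detected = np.vstack([detected, [[500.0, 500.0]]])
        truth = GroundTruth(tru, 100, (0, 0), 10.0)
        assert match_to_truth(self._records(detected), truth, 5.0) == (99, 1, 1)

    def test_counts_partition(self):
        rng = np.random.default_rng(2)
        tru = rng.uniform(0, 200, (40, 2))
        det = rng.uniform(0, 200, (55, 2))
        truth = GroundTruth(tru, 40, (0, 0), 10.0)
        m, missed, spur = match_to_truth(self._records(det), truth, 8.0)
        assert m + missed == 40
        assert m + spur == 55

    def test_nonpositive_radius_rejected(self):
        truth = GroundTruth(np.zeros((1, 2)), 1, (0, 0), 10.0)
        with pytest.raises(ContractError):
            match_to_truth([], truth, 0.0)


class TestRenderOutlines:
    def test_no_objects_pure_green_rendering(self, tmp_path):
        img = TiledWellImage(pixels=np.random.default_rng(0).uniform(0, 1, (30, 30)))
        labels = LabelImage(np.zeros((30, 30), int), 0)
        p = render_outlines(img, labels, tmp_path / "o.png")
        out = iio.imread(p)
        assert out.shape == (30, 30, 3)
        assert np.array_equal(out[..., 1], np.round(img.pixels * 255))
        assert out[..., 0].max() == 0 and out[..., 2].max() == 0

    def test_disc_outline_length_near_circumference(self, tmp_path):
        lab = disc_mask((40, 40), (20.0, 20.0), 5.0).astype(int)
        img = TiledWellImage(pixels=np.zeros((40, 40)))
        p = render_outlines(img, LabelImage(lab, 1), tmp_path / "o.png")
        out = iio.imread(p)
        outline_px = int((out[..., 0] > 0).sum())
        assert outline_px == pytest.approx(2 * np.pi * 5, rel=0.2)

    def test_round_trip_shape(self, tmp_path):
        img = TiledWellImage(pixels=np.zeros((25, 35)))
        p = render_outlines(img, LabelImage(np.zeros((25, 35), int), 0),
                            tmp_path / "o.png")
        assert iio.imread(p).shape[:2] == (25, 35)
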