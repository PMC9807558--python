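"""Pixel classification bands, PEDCI arithmetic, size gate, overlays, cohort summary."""

import numpy as np
import pytest

from pedci import (
    PedMask,
    PipelineConfig,
    batch_summary,
    class_intensity_distributions,
    classify_pixels,
    compute_pedci,
    ped_size_filter,
    render_overlay,
)
from pedci.classify import ClassMap, PedciResult, TissueClass
from pedci.filters import LikelihoodMap
from pedci.preprocess import ProcessedImage


def _l7_from(values_in_mask, shape=(10, 10), box=(2, 7, 2, 7)):
    r0, r1, c0, c1 = box
    mask = np.zeros(shape, dtype=bool)
    mask[r0 : r1 + 1, c0 : c1 + 1] = True
    vals = np.full(shape, np.nan)
    vals[mask] = values_in_mask
    return LikelihoodMap(values=vals, mask=mask), PedMask(mask=mask)


class TestClassifyPixels:
    def test_bands(self):
        l7, mask = _l7_from(np.tile([0.0, 0.3, 0.8], 12))
        cmap = classify_pixels(l7, mask, gt2=0.6)
        flat = cmap.labels[mask.mask]
        assert (flat[::3] == TissueClass.SEROUS).all()
        assert (flat[1::3] == TissueClass.NEOVASCULAR).all()
        assert (flat[2::3] == TissueClass.FIBROUS).all()

    def test_tie_at_gt2_is_fibrous_by_default(self):
        l7, mask = _l7_from(np.full(36, 0.6))
        assert (classify_pixels(l7, mask, gt2=0.6).labels[mask.mask] == TissueClass.FIBROUS).all()
        flipped = classify_pixels(l7, mask, gt2=0.6, tie_break="neovascular")
        assert (flipped.labels[mask.mask] == TissueClass.NEOVASCULAR).all()

    def test_counts_match_loop_oracle(self, rng):
        vals = rng.uniform(0, 1, 36)
        vals[rng.random(36) < 0.3] = 0.0
        l7, mask = _l7_from(vals)
        cmap = classify_pixels(l7, mask, gt2=0.6)
        ser = sum(1 for v in vals if v == 0)
        fib = sum(1 for v in vals if v >= 0.6)
        neo = sum(1 for v in vals if 0 < v < 0.6)
        assert cmap.count(TissueClass.SEROUS) == ser
        assert cmap.count(TissueClass.NEOVASCULAR) == neo
        assert cmap.count(TissueClass.FIBROUS) == fib

    def test_partition_of_mask(self, rng):
        l7, mask = _l7_from(rng.uniform(0, 1, 36))
        cmap = classify_pixels(l7, mask, gt2=0.5)
        assert (cmap.mask == mask.mask).all()
        total = sum(cmap.count(c) for c in (TissueClass.SEROUS, TissueClass.NEOVASCULAR, TissueClass.FIBROUS))
        assert total == mask.n_pixels


class TestComputePedci:
    def test_all_serous_identity(self):
        l7, mask = _l7_from(np.zeros(36))
        res = compute_pedci(classify_pixels(l7, mask, gt2=0.6))
        assert (res.pedci_s, res.pedci_n, res.pedci_f) == (1.0, 0.0, 0.0)

    def test_fraction_arithmetic(self):
        labels = np.zeros((10, 10), dtype=np.int8)
        labels.flat[:50] = TissueClass.SEROUS
        labels.flat[50:75] = TissueClass.NEOVASCULAR
        labels.flat[75:] = TissueClass.FIBROUS
        res = compute_pedci(ClassMap(labels=labels))
        assert (res.pedci_s, res.pedci_n, res.pedci_f) == (0.5, 0.25, 0.25)

    def test_area_conversion_at_stated_scales(self):
        labels = np.full((20, 50), int(TissueClass.FIBROUS), dtype=np.int8)
        res = compute_pedci(ClassMap(labels=labels), PipelineConfig())
        assert res.n_total == 1000
        assert res.area_total_mm2 == pytest.approx(0.028)

    def test_indices_sum_to_one(self, rng):
        l7, mask = _l7_from(rng.uniform(0, 1, 36))
        res = compute_pedci(classify_pixels(l7, mask, gt2=0.6))
        assert res.pedci_s + res.pedci_n + res.pedci_f == pytest.approx(1.0, abs=1e-12)

    def test_scale_doubling_quadruples_areas_not_indices(self, rng):
        l7, mask = _l7_from(rng.uniform(0, 1, 36))
        cmap = classify_pixels(l7, mask, gt2=0.6)
        a = compute_pedci(cmap, PipelineConfig())
        b = compute_pedci(cmap, PipelineConfig(axial_scale_um=8.0, transverse_scale_um=14.0))
        assert b.area_total_mm2 == pytest.approx(4 * a.area_total_mm2)
        assert (b.pedci_s, b.pedci_n, b.pedci_f) == (a.pedci_s, a.pedci_n, a.pedci_f)


class TestThresholdMonotonicity:
    def test_gt2_sweep(self, rng):
        vals = rng.uniform(0, 1, 36)
        l7, mask = _l7_from(vals)
        prev_n, prev_f = -1.0, 2.0
        s_values = set()
        for gt2 in np.linspace(0.05, 1.0, 12):
            res = compute_pedci(classify_pixels(l7, mask, gt2=gt2))
            assert res.pedci_n >= prev_n - 1e-12
            assert res.pedci_f <= prev_f + 1e-12
            prev_n, prev_f = res.pedci_n, res.pedci_f
            s_values.add(res.pedci_s)
        assert len(s_values) == 1  # serous fraction independent of gt2


class TestSizeGate:
    @pytest.mark.parametrize(
        "rows,cols,included,reason",
        [
            (25, 15, True, ""),  # 100 um x 105 um, boundary inclusive
            (20, 15, False, "height"),  # 80 um tall
            (25, 14, False, "width"),  # 98 um wide
            (1, 1, False, "height,width"),
        ],
    )
    def test_100um_rule(self, rows, cols, included, reason):
        m = np.zeros((60, 60), dtype=bool)
        m[5 : 5 + rows, 5 : 5 + cols] = True
        gate = ped_size_filter(PedMask(mask=m), PipelineConfig())
        assert gate.included is included
        assert gate.reason == reason


class TestOverlayAndDistributions:
    def test_empty_class_map_leaves_grayscale(self):
        img = ProcessedImage(values=np.full((8, 8), 0.5))
        cmap = ClassMap(labels=np.zeros((8, 8), dtype=np.int8))
        rgb = render_overlay(img, cmap)
        assert (rgb[..., 0] == rgb[..., 1]).all() and (rgb[..., 1] == rgb[..., 2]).all()

    def test_colored_pixel_counts_match_classes(self, rng):
        l7, mask = _l7_from(rng.uniform(0, 1, 36))
        cmap = classify_pixels(l7, mask, gt2=0.6)
        img = ProcessedImage(values=np.zeros((10, 10)))
        rgb = render_overlay(img, cmap, outline=False).astype(int)
        # with a black base, each class pixel keeps only its own channel
        red = (rgb[..., 0] > 0) & (rgb[..., 1] == 0) & (rgb[..., 2] == 0)
        blue = (rgb[..., 2] > 0) & (rgb[..., 0] == 0) & (rgb[..., 1] == 0)
        green = (rgb[..., 1] > 0) & (rgb[..., 0] == 0) & (rgb[..., 2] == 0)
        assert red.sum() == cmap.count(TissueClass.SEROUS)
        assert blue.sum() == cmap.count(TissueClass.NEOVASCULAR)
        assert green.sum() == cmap.count(TissueClass.FIBROUS)

    def test_distribution_groups(self, rng):
        l7, mask = _l7_from(rng.uniform(0, 1, 36))
        cmap = classify_pixels(l7, mask, gt2=0.6)
        img = ProcessedImage(values=rng.uniform(0, 1, (10, 10)))
        table = class_intensity_distributions(img, cmap)
        counts = table.groupby("group").size()
        assert counts["total"] == 36
        assert counts.get("fibrovascular", 0) == cmap.count(TissueClass.NEOVASCULAR) + cmap.count(
            TissueClass.FIBROUS
        )
        assert counts["total"] == counts.get("serous", 0) + counts.get("fibrovascular", 0)

    def test_all_serous_distribution(self):
        l7, mask = _l7_from(np.zeros(36))
        cmap = classify_pixels(l7, mask, gt2=0.6)
        table = class_intensity_distributions(np.zeros((10, 10)), cmap)
        counts = table.groupby("group").size()
        assert counts["serous"] == 36 and counts["total"] == 36
        assert "fibrovascular" not in counts or counts["fibrovascular"] == 0


def _result(s, n, f, scale=0.028 / 1000):
    total = s + n + f
    return PedciResult(
        pedci_s=s / total, pedci_n=n / total, pedci_f=f / total,
        n_serous=s, n_neovascular=n, n_fibrous=f, n_total=total,
        area_serous_mm2=s * scale, area_neovascular_mm2=n * scale,
        area_fibrous_mm2=f * scale, area_total_mm2=total * scale,
    )


class TestBatchSummary:
    def test_single_result(self):
        table = batch_summary([_result(50, 30, 20)])
        row = table[table.component == "serous"].iloc[0]
        assert row.area_sd_mm2 == 0.0 and row.n_present == 1

    def test_two_results_mean_median(self):
        table = batch_summary([_result(100, 0, 0, scale=0.001), _result(300, 0, 0, scale=0.001)])
        row = table[table.component == "serous"].iloc[0]
        assert row.area_mean_mm2 == pytest.approx(0.2)
        assert row.area_median_mm2 == pytest.approx(0.2)

    def test_present_only_filtering(self):
        results = [_result(0, 50, 50), _result(40, 30, 30), _result(20, 40, 40)]
        table = batch_summary(results)
        row = table[table.component == "serous"].iloc[0]
        assert row.n_present == 2
        expected = np.mean([r.area_serous_mm2 for r in results if r.n_serous > 0])
        assert row.area_mean_mm2 == pytest.approx(expected)
        # indices are averaged over ALL eyes
        assert row.pedci_mean == pytest.approx(np.mean([r.pedci_s for r in results]))

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            batch_summary([])
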