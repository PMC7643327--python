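"""IPAD counting, influx signal, penetrating vessels, partition, linearization."""

import numpy as np
import pytest
from skimage.draw import line as draw_line
from skimage.morphology import dilation, disk as disk_footprint

from pvq.clearance import (
    CorticalSlice,
    count_ipad_arteries,
    count_penetrating_vessels,
    linearize_cortex,
    partition_cortex,
    regional_table,
    total_influx_signal,
)
from pvq.errors import ValidationError
from pvq.quant import ChannelImage, ThresholdPolicy
from pvq.synthetic import CorticalSliceSpec, make_cortical_slice


class TestIpadCounting:
    def test_counts_only_colocalized_vessels(self, noise_free_slice):
        """7 tracer-filled + 3 SMA-only vessels: exactly 7 accepted."""
        _, image, truth, slice_truth = noise_free_slice
        result = count_ipad_arteries(image)
        assert result.count == slice_truth["n_tracer_positive_arteries"]
        assert len(result.components) == len(truth)

    def test_blank_tracer_counts_zero(self, noise_free_slice):
        _, image, _, _ = noise_free_slice
        blank = ChannelImage(
            {"SMA": image.channel("SMA"), "FITC3K": np.zeros(image.shape)},
            pixel_size_um=image.pixel_size_um,
        )
        assert count_ipad_arteries(blank).count == 0

    def test_zero_colocal_fraction_counts_all_sma_components(self, noise_free_slice):
        _, image, truth, _ = noise_free_slice
        result = count_ipad_arteries(image, colocal_fraction=0.0)
        assert result.count == len(truth)

    def test_monotone_in_colocal_fraction(self, noise_free_slice):
        _, image, _, _ = noise_free_slice
        counts = [
            count_ipad_arteries(image, colocal_fraction=f).count
            for f in (0.0, 0.3, 0.6, 1.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_missing_channel_rejected(self):
        image = ChannelImage({"SMA": np.zeros((16, 16))})
        with pytest.raises(ValidationError, match="FITC3K"):
            count_ipad_arteries(image)


class TestInfluxSignal:
    def test_uniform_image_reads_zero(self, cortical_slice_pair):
        _, cslice, _ = cortical_slice_pair
        flat = ChannelImage({"FITC3K": np.full(cslice.image.shape, 40.0)})
        uniform = CorticalSlice(
            image=flat, brain_mask=cslice.brain_mask,
            midline_point=cslice.midline_point, midline_dir=cslice.midline_dir,
        )
        out = total_influx_signal(uniform, "FITC3K")
        assert out["mean_signal"] == pytest.approx(0.0)

    def test_recovers_known_added_signal(self):
        spec = CorticalSliceSpec(seed=0)
        cslice, truth = make_cortical_slice(spec)
        out = total_influx_signal(cslice, "FITC3K")
        # whole-brain mean: band sectors carry the regional signal, interior 0
        band_mean = truth[truth.channel == "FITC3K"].mean_signal.mean()
        assert 0.0 < out["mean_signal"] < band_mean
        assert out["background"] == pytest.approx(spec.background_level)

    def test_offset_invariance(self, cortical_slice_pair):
        """Adding a constant to the whole image leaves the background-subtracted
        signal unchanged when the background is estimated from the image."""
        _, cslice, _ = cortical_slice_pair
        shifted = CorticalSlice(
            image=ChannelImage(
                {r: cslice.image.channel(r) + 55.0 for r in cslice.image.channels},
                pixel_size_um=cslice.image.pixel_size_um,
            ),
            brain_mask=cslice.brain_mask,
            midline_point=cslice.midline_point, midline_dir=cslice.midline_dir,
        )
        a = total_influx_signal(cslice, "FITC3K")
        b = total_influx_signal(shifted, "FITC3K")
        assert b["mean_signal"] == pytest.approx(a["mean_signal"], rel=1e-12)

    def test_doubling_signal_doubles_subtracted_mean(self, cortical_slice_pair):
        _, cslice, _ = cortical_slice_pair
        arr = cslice.image.channel("FITC3K")
        bg = float(np.median(arr[~cslice.brain_mask]))
        doubled = CorticalSlice(
            image=ChannelImage({"FITC3K": bg + 2.0 * np.clip(arr - bg, 0, None)}),
            brain_mask=cslice.brain_mask,
            midline_point=cslice.midline_point, midline_dir=cslice.midline_dir,
        )
        a = total_influx_signal(cslice, "FITC3K")
        b = total_influx_signal(doubled, "FITC3K")
        assert b["mean_signal"] == pytest.approx(2.0 * a["mean_signal"], rel=1e-6)


class TestPenetratingVessels:
    def test_exact_count_on_ground_truth(self, cortical_slice_pair):
        spec, cslice, truth = cortical_slice_pair
        result = count_penetrating_vessels(cslice)
        assert result.count == spec.n_penetrating_vessels

    def test_tangential_stripes_rejected(self):
        """Stripes drawn parallel to the surface fail the orientation rule."""
        spec = CorticalSliceSpec(seed=3)
        cslice, _ = make_cortical_slice(spec)
        img = cslice.image.channel("FITC3K").copy()
        center = cslice.centroid
        r_mid = spec.brain_radius_px - 0.5 * spec.band_depth_um / spec.pixel_size_um
        for ang_deg in (30.0, 90.0, 150.0):
            a = np.radians(ang_deg)
            mid = np.array(center) + r_mid * np.array([-np.cos(a), np.sin(a)])
            tangent = np.array([np.sin(a), np.cos(a)])  # perpendicular to radial
            p0, p1 = mid - 15 * tangent, mid + 15 * tangent
            rr, cc = draw_line(int(p0[0]), int(p0[1]), int(p1[0]), int(p1[1]))
            stripe = np.zeros(img.shape, dtype=bool)
            stripe[rr, cc] = True
            img[dilation(stripe, disk_footprint(1))] = 400.0
        rotated = CorticalSlice(
            image=ChannelImage({"FITC3K": img}, pixel_size_um=spec.pixel_size_um),
            brain_mask=cslice.brain_mask, midline_point=cslice.midline_point,
            midline_dir=cslice.midline_dir, band_depth_um=spec.band_depth_um,
        )
        assert count_penetrating_vessels(rotated).count == 0

    def test_blank_tracers_count_zero(self, cortical_slice_pair):
        _, cslice, _ = cortical_slice_pair
        blank = CorticalSlice(
            image=ChannelImage({"FITC3K": np.zeros(cslice.image.shape)}),
            brain_mask=cslice.brain_mask, midline_point=cslice.midline_point,
            midline_dir=cslice.midline_dir, band_depth_um=cslice.band_depth_um,
        )
        assert count_penetrating_vessels(blank).count == 0


class TestPartition:
    def test_landmarks_at_60_120_give_equal_arc_areas(self, cortical_slice_pair):
        """Equal 60-degree spans of an annulus have equal areas."""
        _, cslice, _ = cortical_slice_pair
        masks = partition_cortex(cslice)
        areas = {k: int(v.sum()) for k, v in masks.items()}
        total = sum(areas.values())
        for region in ("dorsal", "lateral", "ventral"):
            assert areas[region] / total == pytest.approx(1 / 3, abs=0.01)

    def test_masks_are_disjoint_cover_of_the_band(self, cortical_slice_pair):
        _, cslice, _ = cortical_slice_pair
        masks = partition_cortex(cslice)
        theta = cslice.angle_map()
        band_hemi = cslice.band_mask() & (theta >= 0) & (theta <= 180)
        union = masks["dorsal"] | masks["lateral"] | masks["ventral"]
        np.testing.assert_array_equal(union, band_hemi)
        assert not (masks["dorsal"] & masks["lateral"]).any()
        assert not (masks["lateral"] & masks["ventral"]).any()
        assert not (masks["dorsal"] & masks["ventral"]).any()

    def test_degenerate_landmarks_flag_empty_region(self, cortical_slice_pair):
        _, cslice, _ = cortical_slice_pair
        degenerate = CorticalSlice(
            image=cslice.image, brain_mask=cslice.brain_mask,
            midline_point=cslice.midline_point, midline_dir=cslice.midline_dir,
            landmarks_deg=(0.0, 120.0), band_depth_um=cslice.band_depth_um,
        )
        with pytest.warns(UserWarning, match="dorsal region is empty"):
            masks = partition_cortex(degenerate)
        assert not masks["dorsal"].any()


class TestLinearization:
    def test_symmetric_signal_gives_flat_profile(self):
        spec = CorticalSliceSpec(
            influx_means={"FITC3K": {"dorsal": 50.0, "lateral": 50.0, "ventral": 50.0}},
            plaque_burden_pct={"dorsal": 0.0, "lateral": 0.0, "ventral": 0.0},
            seed=0,
        )
        cslice, _ = make_cortical_slice(spec)
        prof = linearize_cortex(cslice, channels=("FITC3K",))
        assert prof["FITC3K"].std() == pytest.approx(0.0, abs=1e-6)

    def test_gradient_profile_ordered_dorsal_to_ventral(self, cortical_slice_pair):
        """Arclength runs dorsal to ventral, so a ventral-high influx gradient
        yields increasing region-wise profile levels."""
        _, cslice, _ = cortical_slice_pair
        prof = linearize_cortex(cslice, channels=("FITC3K",))
        levels = prof.groupby("region")["FITC3K"].median()
        assert levels["ventral"] > levels["lateral"] > levels["dorsal"]
        assert (np.diff(prof["arclength_um"]) > 0).all()

    def test_zero_band_depth_rejected(self, cortical_slice_pair):
        _, cslice, _ = cortical_slice_pair
        with pytest.raises(ValidationError, match="band depth"):
            linearize_cortex(cslice, band_depth_um=0.0)


class TestRegionalTable:
    def test_noise_free_table_matches_generator_truth(self):
        spec = CorticalSliceSpec(seed=8)
        cslice, truth = make_cortical_slice(spec)
        table = regional_table([cslice], count_penetrating=False)
        merged = table.merge(truth, on=["region", "channel"], suffixes=("", "_truth"))
        np.testing.assert_allclose(merged.mean_signal, merged.mean_signal_truth, atol=1e-9)
        np.testing.assert_allclose(
            merged.plaque_burden_pct, merged.plaque_burden_pct_truth, atol=0.1
        )

    def test_seven_slices_give_21_rows_per_channel(self):
        slices = []
        for s in range(7):
            cslice, _ = make_cortical_slice(CorticalSliceSpec(seed=20 + s))
            cslice.slice_id = f"s{s}"
            slices.append(cslice)
        table = regional_table(slices, count_penetrating=False)
        for channel in ("FITC3K", "TMR40K"):
            assert (table.channel == channel).sum() == 21

    def test_slice_order_invariance(self):
        slices = []
        for s in range(3):
            cslice, _ = make_cortical_slice(CorticalSliceSpec(seed=30 + s))
            cslice.slice_id = f"s{s}"
            slices.append(cslice)
        a = regional_table(slices, count_penetrating=False)
        b = regional_table(slices[::-1], count_penetrating=False)
        import pandas as pd

        pd.testing.assert_frame_equal(a, b)

    def test_regional_orderings_reproduced_in_every_slice(self):
        """Ventral > lateral > dorsal influx and the reverse plaque gradient in
        each noise-free slice."""
        slices = []
        for s in range(3):
            cslice, _ = make_cortical_slice(
                CorticalSliceSpec(n_penetrating_vessels=9, seed=40 + s)
            )
            cslice.slice_id = f"s{s}"
            slices.append(cslice)
        table = regional_table(slices)
        for (sid, channel), g in table.groupby(["slice_id", "channel"]):
            g = g.set_index("region")
            assert (
                g.loc["ventral", "mean_signal"]
                > g.loc["lateral", "mean_signal"]
                > g.loc["dorsal", "mean_signal"]
            )
            assert (
                g.loc["dorsal", "plaque_burden_pct"]
                > g.loc["lateral", "plaque_burden_pct"]
                > g.loc["ventral", "plaque_burden_pct"]
            )
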