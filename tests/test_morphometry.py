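"""Territory shape measurement: centerline, width, length, slenderness,
painted-segment counting."""

import numpy as np
import pytest

from territory3d import morphometry as mm
from territory3d import segmentation as seg
from territory3d.geometry import random_rotation
from territory3d.io import VoxelImage
from territory3d.paint import two_color_scheme
from territory3d.synth.territory import generate_territory

from conftest import VOX, render_model, straight_tube


def segment_positive(vi, channel=0):
    return seg.segment_channel(vi, channel, "positive")


def measure(mask, voxel_size=VOX):
    cl = mm.extract_centerline(mask, voxel_size)
    vs = np.asarray(voxel_size)
    r0 = mm.medial_radius(mask, cl, vs)
    r = mm.refine_radius(mask, cl, r0, vs)
    d = max(2 * r + 0.25 * vs.min(), vs.min())
    length = mm.corrected_length(mask, cl, r, voxel_size)
    return cl, d, length


class TestCenterlineAndWidth:
    def test_straight_tube_length_within_5pct(self):
        m = straight_tube(radius=0.3, length=5.0)
        vi, _ = render_model(m)
        _, _, length = measure(segment_positive(vi))
        assert abs(length - 5.0) / 5.0 < 0.05

    def test_sphere_is_not_extended(self):
        # ball mask: degenerate skeleton falls back to the principal axis
        r = 0.5
        ax = (np.arange(16) + 0.5) * 0.1 - 0.8
        zz, yy, xx = np.meshgrid(ax, ax, ax, indexing="ij")
        mask = zz**2 + yy**2 + xx**2 <= r**2
        cl, d, length = measure(mask)
        assert d == pytest.approx(2 * r, abs=0.15)
        s = mm.slenderness(length, d)
        assert s < 2.0
        assert not mm.classify_extension(s)

    def test_curved_tube_uses_geodesic_not_chord(self, mono_paint):
        # strongly curled thread: the chord is far shorter than the arc
        m = generate_territory("extended", 8.0, 1, paint=mono_paint, seed=4,
                               nuclear_radius=1.6)
        m.bead_profile[:] = 1.0
        vi, _ = render_model(m)
        cl, _, length = measure(segment_positive(vi))
        chord = np.linalg.norm(m.centerline[-1] - m.centerline[0])
        assert length > 1.5 * chord
        assert abs(length - m.length) / m.length < 0.08

    def test_width_of_known_tube(self):
        m = straight_tube(radius=0.335, length=4.0)
        vi, _ = render_model(m)
        mask = segment_positive(vi)
        cl = mm.extract_centerline(mask, VOX)
        for method in ("volume", "edt"):
            d = mm.estimate_width(mask, cl, VOX, method=method)
            assert 0.57 <= d <= 0.77  # within one voxel of 0.67

    def test_width_panel_recovers_generator_mean(self, mono_paint):
        rng = np.random.default_rng(12)
        est, true = [], []
        for _ in range(16):
            m = generate_territory("compact", 1.5, 1, paint=mono_paint,
                                   seed=rng, nuclear_radius=1.8)
            m.bead_profile[:] = 1.0
            vi, _ = render_model(m)
            mask = segment_positive(vi)
            cl = mm.extract_centerline(mask, VOX)
            est.append(mm.estimate_width(mask, cl, VOX))
            true.append(m.width)
        se = 0.05 / np.sqrt(16)
        assert abs(np.mean(est) - 0.67) < 2 * se + 0.05  # + estimator allowance


class TestSlenderness:
    def test_ratio_and_strict_threshold(self):
        assert mm.slenderness(4.69, 0.67) == pytest.approx(7.0, abs=1e-9)
        assert mm.classify_extension(7.0)
        assert not mm.classify_extension(6.0)  # strictly greater than 6
        assert mm.classify_extension(6.0 + 1e-9)
        assert not mm.classify_extension(1.0)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            mm.slenderness(0.0, 0.5)
        with pytest.raises(ValueError):
            mm.slenderness(1.0, -1.0)

    def test_record_invariant(self):
        with pytest.raises(ValueError, match="L/D"):
            mm.MorphometryRecord("t", 0.5, 3.0, 99.0, 1, False)


class TestSegmentCounting:
    def _profile(self, values, n_channels=1, step=0.05):
        arr = np.asarray(values, dtype=float)
        s = np.arange(len(arr)) * step
        profs = arr[None] if n_channels == 1 else arr
        return s, np.atleast_2d(profs)

    def test_uniform_profile_is_one_segment(self):
        s, p = self._profile(np.ones(100))
        assert mm.count_segments_profile(s, p) == 1

    def test_three_beads_with_zero_troughs(self):
        t = np.linspace(0, 1, 200)
        prof = 0.5 - 0.5 * np.cos(2 * np.pi * 3 * t)
        s = t * 4.0
        # brute-force oracle: count maxima separated by < gap_fraction valleys
        n_peaks = sum(1 for i in range(1, 199)
                      if prof[i] > prof[i - 1] and prof[i] >= prof[i + 1])
        assert n_peaks == 3
        assert mm.count_segments_profile(s, prof[None]) == 3

    def test_two_color_tube_resolved_by_color_boundary(self):
        n = 200
        s = np.linspace(0, 4, n)
        ch0 = np.where(s < 2.0, 1.0, 0.0)
        ch1 = 1.0 - ch0
        assert mm.count_segments_profile(s, np.stack([ch0, ch1])) == 2

    def test_gap_insertion_increases_count_by_one(self):
        t = np.linspace(0, 1, 400)
        s = t * 6.0
        base = 0.55 + 0.45 * np.cos(2 * np.pi * 2 * t) ** 2  # no deep troughs
        k0 = mm.count_segments_profile(s, base[None])
        gapped = base.copy()
        gapped[175:225] = 0.0  # full-depth gap, wider than the merge distance
        assert mm.count_segments_profile(s, gapped[None]) == k0 + 1

    @pytest.mark.parametrize("k", [1, 3, 5])
    def test_rendered_bead_count_recovery(self, mono_paint, k):
        m = generate_territory("extended", 8.0, k, paint=mono_paint, seed=31,
                               nuclear_radius=1.6)
        vi, _ = render_model(m)
        mask = segment_positive(vi)
        cl = mm.extract_centerline(mask, VOX)
        assert mm.count_painted_segments(vi, cl, mono_paint) == k

    def test_empty_profile_rejected(self):
        s, p = self._profile(np.zeros(50))
        with pytest.raises(ValueError, match="empty"):
            mm.count_segments_profile(s, p)


class TestRigidInvariance:
    def test_measurements_invariant_under_rotation(self, mono_paint):
        m = generate_territory("extended", 7.0, 3, paint=mono_paint, seed=17,
                               nuclear_radius=1.6)
        rot = random_rotation(np.random.default_rng(99))
        m2 = m.transformed(rotation=rot)

        def run(model):
            vi, _ = render_model(model)
            mask = segment_positive(vi)
            cl, d, length = measure(mask)
            k = mm.count_painted_segments(vi, cl, mono_paint)
            return d, length, k

        d1, l1, k1 = run(m)
        d2, l2, k2 = run(m2)
        assert abs(d1 - d2) <= 0.1  # one voxel
        assert abs(l1 - l2) <= 0.2
        assert k1 == k2

    def test_full_pipeline_measure(self, halves_paint, mono_paint):
        m = generate_territory("extended", 8.0, 3, paint=halves_paint, seed=23,
                               nuclear_radius=1.6)
        vi, _ = render_model(m, n_channels=2)
        masks = {c: seg.segment_channel(vi, c, "positive")
                 for c in halves_paint.channels}
        ters = seg.assemble_territories(vi, masks, halves_paint)
        assert len(ters) == 1
        rec = mm.measure_territory(vi, ters[0], halves_paint)
        assert rec.highly_extended == (rec.slenderness_s > 6)
        assert abs(rec.slenderness_s - 8.0) < 1.0
        assert rec.width_d > 0
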