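"""Generator ground truth: paint schemes, territories, nuclei, rendering,
and gonad layouts."""

import numpy as np
import pytest

from territory3d import geometry
from territory3d.paint import PaintScheme, PaintSegment, three_color_scheme
from territory3d.synth.nucleus import (
    CONFIGURATIONS,
    NucleusSpec,
    PairSpec,
    generate_nucleus,
    paired_intervals,
    planted_association_profile,
    planted_edge_distance,
)
from territory3d.synth.optics import OpticsParams, nucleus_ground_truth, render_voxels
from territory3d.synth.territory import bead_profile, generate_territory
from territory3d.synth.gonad import generate_gonad

from conftest import render_model, straight_tube


class TestPaintScheme:
    def test_same_channel_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PaintScheme("c", (PaintSegment(0.0, 0.6, 0), PaintSegment(0.5, 1.0, 0)))

    def test_cross_channel_overlap_is_double_labeling(self):
        ps = PaintScheme("c", (PaintSegment(0.0, 1.0, 0), PaintSegment(0.0, 0.1, 1)))
        w = ps.channel_weights(np.array([0.05, 0.5]))
        assert w[0].tolist() == [1.0, 1.0]  # double labeled end
        assert w[1].tolist() == [1.0, 0.0]

    def test_pc_end_validation(self):
        with pytest.raises(ValueError):
            PaintScheme("c", (PaintSegment(0.0, 1.0, 0),), pc_end="middle")


class TestGenerateTerritory:
    def test_fixed_seed_is_bitwise_deterministic(self, mono_paint):
        a = generate_territory("compact", 1.5, 2, paint=mono_paint, seed=11)
        b = generate_territory("compact", 1.5, 2, paint=mono_paint, seed=11)
        assert np.array_equal(a.centerline, b.centerline)
        assert np.array_equal(a.bead_profile, b.bead_profile)
        assert a.tube_radius == b.tube_radius

    @pytest.mark.parametrize("stage,target", [("compact", 1.5), ("extended", 8.0)])
    def test_analytic_slenderness_hits_target(self, mono_paint, stage, target):
        m = generate_territory(stage, target, 1, paint=mono_paint, seed=3,
                               nuclear_radius=1.8)
        assert abs(m.slenderness - target) / target < 0.05

    def test_width_distribution_recovery(self, mono_paint):
        rng = np.random.default_rng(5)
        widths = [generate_territory("compact", 1.5, 1, paint=mono_paint,
                                     seed=rng).width for _ in range(200)]
        assert abs(np.mean(widths) - 0.67) < 2 * 0.05 / np.sqrt(200) + 0.01
        assert abs(np.std(widths, ddof=1) - 0.05) < 0.015

    @pytest.mark.parametrize("k", [1, 2, 5])
    def test_bead_profile_has_exactly_k_maxima(self, mono_paint, k):
        m = generate_territory("extended", 8.0, k, paint=mono_paint, seed=9,
                               nuclear_radius=1.8)
        p = m.bead_profile
        # brute-force scan for strict interior local maxima
        n_max = sum(1 for i in range(1, len(p) - 1)
                    if p[i] > p[i - 1] and p[i] > p[i + 1])
        assert n_max == k

    def test_invalid_parameters_rejected(self, mono_paint):
        with pytest.raises(ValueError):
            generate_territory("compact", 0.5, 1, paint=mono_paint)
        with pytest.raises(ValueError):
            generate_territory("compact", 1.5, 0, paint=mono_paint)
        with pytest.raises(ValueError):
            bead_profile(100, 1, floor=1.5)

    def test_infeasible_nuclear_radius_rejected(self, mono_paint):
        with pytest.raises(ValueError, match="cannot fit"):
            generate_territory("extended", 30.0, 1, paint=mono_paint, seed=0,
                               nuclear_radius=1.0)


class TestGenerateNucleus:
    @pytest.mark.parametrize("cfg", sorted(CONFIGURATIONS))
    def test_planted_profile_matches_configuration(self, thirds_paint, cfg):
        s = 5.0 if cfg == "no_alignment" else 8.0
        nuc = NucleusSpec(pairs=[PairSpec(paint=thirds_paint,
                                          stage_label="extended",
                                          configuration=cfg,
                                          target_slenderness=s,
                                          bead_count=3)])
        generate_nucleus(nuc, seed=21)
        a, b = nuc.territories[thirds_paint.chromosome_id]
        prof = planted_association_profile(a, b)
        bins = len(prof)
        expected = np.zeros(bins, dtype=bool)
        for lo, hi in paired_intervals(cfg, thirds_paint.pc_end):
            expected[int(lo * bins):int(np.ceil(hi * bins))] = True
        # within one bin of the planted boundaries (the association ramp
        # extends slightly past the nominal interval)
        mismatch = np.flatnonzero(prof != expected)
        boundary_bins = set()
        for lo, hi in paired_intervals(cfg, thirds_paint.pc_end):
            for edge in (int(lo * bins), int(np.ceil(hi * bins))):
                boundary_bins |= {edge - 1, edge, edge + 1}
        assert set(int(i) for i in mismatch) <= boundary_bins

    def test_full_alignment_over_95pct(self, thirds_paint):
        nuc = NucleusSpec(pairs=[PairSpec(paint=thirds_paint,
                                          stage_label="extended",
                                          configuration="full",
                                          target_slenderness=8.0)])
        generate_nucleus(nuc, seed=2)
        a, b = nuc.territories["I"]
        d = geometry.pairwise_coordinate_distances(a.centerline, b.centerline)
        assert (d <= 2 * a.tube_radius).mean() >= 0.95

    def test_no_contact_pairs_are_separated(self, thirds_paint):
        nuc = NucleusSpec(pairs=[PairSpec(paint=thirds_paint,
                                          stage_label="extended",
                                          configuration="no_contact",
                                          target_slenderness=8.0)])
        generate_nucleus(nuc, seed=4)
        a, b = nuc.territories["I"]
        assert planted_edge_distance(a, b) > 0.0

    def test_unknown_configuration_rejected(self, thirds_paint):
        with pytest.raises(ValueError, match="unknown configuration"):
            PairSpec(paint=thirds_paint, configuration="W-PC")

    def test_territories_fit_nuclear_sphere(self, thirds_paint):
        for cfg in ("Y-PC", "full", "no_contact"):
            nuc = NucleusSpec(pairs=[PairSpec(paint=thirds_paint,
                                              stage_label="extended",
                                              configuration=cfg,
                                              target_slenderness=8.0)])
            generate_nucleus(nuc, seed=6)
            for m in nuc.territories["I"]:
                extent = np.linalg.norm(m.centerline, axis=1).max() + m.tube_radius
                assert extent <= nuc.nuclear_radius + 1e-6


class TestRendering:
    def test_noise_free_render_equals_analytic_indicator(self):
        from conftest import analytic_capsule_mask

        m = straight_tube(radius=0.3, length=4.0)
        vi, origin = render_model(m)
        expected = analytic_capsule_mask(vi.shape, vi.voxel_size, origin,
                                         m.centerline[0], m.centerline[-1],
                                         m.tube_radius)
        assert np.array_equal(vi.channel(0) > 0, expected)
        assert np.allclose(np.unique(vi.channel(0)[expected]), 1.0)

    def test_photon_scale_linearity(self, thirds_paint):
        nuc = NucleusSpec(pairs=[PairSpec(paint=thirds_paint,
                                          configuration="full",
                                          stage_label="extended",
                                          target_slenderness=7.0)])
        generate_nucleus(nuc, seed=8)
        img1, _ = render_voxels(nuc, OpticsParams(photon_scale=1.0, dapi_channel=None,
                                                  n_channels=3, background=0.0))
        img2, _ = render_voxels(nuc, OpticsParams(photon_scale=2.0, dapi_channel=None,
                                                  n_channels=3, background=0.0))
        assert np.allclose(img2, 2 * img1)

    def test_double_labeled_end_emits_in_both_channels(self):
        paint = PaintScheme("c", (PaintSegment(0.0, 1.0, 0),
                                  PaintSegment(0.0, 0.1, 1)))
        m = straight_tube(radius=0.3, length=4.0)
        m.paint = paint
        vi, _ = render_model(m, n_channels=2)
        # terminal 10% emits in both channels, the rest only in channel 0
        both = (vi.channel(0) > 0) & (vi.channel(1) > 0)
        assert both.any()
        assert (vi.channel(1) > 0).sum() < 0.2 * (vi.channel(0) > 0).sum()

    def test_expected_photons_conserved(self):
        m = straight_tube(radius=0.3, length=4.0)
        vi, _ = render_model(m)
        voxvol = float(np.prod(vi.voxel_size))
        got = vi.channel(0).sum() * voxvol
        r, l = m.tube_radius, m.length
        analytic = np.pi * r**2 * l + 4.0 / 3.0 * np.pi * r**3
        shell = (2 * np.pi * r * l + 4 * np.pi * r**2) * vi.voxel_size[0]
        assert abs(got - analytic) <= shell

    def test_out_of_field_territory_raises(self):
        from territory3d.synth.optics import render_territory_channels

        m = straight_tube(radius=0.3, length=4.0, center=(50.0, 0, 0))
        with pytest.raises(ValueError, match="field of view"):
            render_territory_channels(m, (10, 10, 10), (0.1,) * 3,
                                      (-0.5, -0.5, -0.5), 1)

    def test_ground_truth_sidecar_is_jsonable(self, thirds_paint):
        import json

        nuc = NucleusSpec(pairs=[PairSpec(paint=thirds_paint,
                                          configuration="Y-PC",
                                          stage_label="extended",
                                          target_slenderness=7.0)])
        generate_nucleus(nuc, seed=13)
        truth = nucleus_ground_truth(nuc)
        parsed = json.loads(json.dumps(truth))
        assert parsed["pairs"]["I"]["configuration"] == "Y-PC"
        assert len(parsed["pairs"]["I"]["association_profile"]) == 20


class TestGenerateGonad:
    def test_wildtype_zone_rows(self):
        layout = generate_gonad("wildtype", 10, 11, 15, nuclei_per_row=1, seed=0)
        assert layout.zone_rows == {"premeiotic": (1, 10),
                                    "transition": (11, 21),
                                    "pachytene": (22, 36)}
        tz = [p.nucleus for p in layout.nuclei if 11 <= p.row <= 21]
        assert all(n.clustered for n in tz)
        pm = [p.nucleus for p in layout.nuclei if p.row <= 10]
        assert not any(n.clustered for n in pm)

    def test_syp1_six_zone_widths(self):
        layout = generate_gonad("syp1", 5, 11, 16, nuclei_per_row=1, seed=0)
        # 27 meiotic rows: n = round(27/5) = 5, zone 6 = 27 - 20 = 7
        widths = [b - a + 1 for z, (a, b) in layout.zone_rows.items()
                  if z != "premeiotic"]
        assert widths == [5, 5, 5, 5, 7]
        assert layout.scheme_kind == "syp1_six_zone"

    def test_same_seed_reproduces_layout(self):
        a = generate_gonad("wildtype", 2, 2, 2, nuclei_per_row=1, seed=5)
        b = generate_gonad("wildtype", 2, 2, 2, nuclei_per_row=1, seed=5)
        for pa, pb in zip(a.nuclei, b.nuclei):
            ta = nucleus_ground_truth(pa.nucleus)
            tb = nucleus_ground_truth(pb.nucleus)
            assert ta == tb

    def test_empty_layout_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            generate_gonad("wildtype", 2, 2, 2, nuclei_per_row=0)
        with pytest.raises(ValueError, match="zone needs|at least"):
            generate_gonad("wildtype", 0, 2, 2, nuclei_per_row=1)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            generate_gonad("mystery")
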