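"""Pairwise territory relationships: edge distance, proximity categories,
association profiles, alignment states and configurations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from territory3d import topology as tp
from territory3d.morphometry import Centerline

from conftest import VOX


def reference_proximity(d, D):
    """Independent piecewise reference of the printed category rules."""
    if d == 0:
        return "touching"
    if 0 < d <= D:
        return "close"
    if D < d <= 2 * D:
        return "intermediate"
    return "far"


def ball_mask(center, radius, shape=(40, 40, 60), vox=0.1):
    ax = [(np.arange(s) + 0.5) * vox for s in shape]
    zz, yy, xx = np.meshgrid(*ax, indexing="ij")
    c = np.asarray(center)
    return (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= radius**2


class TestEdgeDistance:
    def test_two_spheres_analytic(self):
        a = ball_mask((2.0, 2.0, 1.5), 1.0)
        b = ball_mask((2.0, 2.0, 4.5), 1.0)
        d = tp.edge_distance(a, b, VOX)
        assert d == pytest.approx(1.0, abs=0.1)
        # brute-force oracle: min pairwise voxel-center distance
        ca = (np.argwhere(a) + 0.5) * 0.1
        cb = (np.argwhere(b) + 0.5) * 0.1
        brute = min(np.linalg.norm(ca[i] - cb).min()
                    for i in range(0, len(ca), 7))
        assert d <= brute + 1e-9

    def test_overlapping_and_identical_masks(self):
        a = ball_mask((2.0, 2.0, 2.0), 1.0)
        b = ball_mask((2.0, 2.0, 2.5), 1.0)
        assert tp.edge_distance(a, b, VOX) == 0.0
        assert tp.edge_distance(a, a, VOX) == 0.0

    def test_symmetry(self):
        a = ball_mask((2.0, 2.0, 1.0), 0.6)
        b = ball_mask((2.0, 2.0, 4.8), 0.7)
        assert tp.edge_distance(a, b, VOX) == tp.edge_distance(b, a, VOX)

    def test_empty_mask_rejected(self):
        a = ball_mask((2.0, 2.0, 2.0), 0.5)
        with pytest.raises(ValueError):
            tp.edge_distance(a, np.zeros_like(a), VOX)


class TestProximity:
    @pytest.mark.parametrize("ratio,expected", [
        (0.5, "close"), (1.0, "close"), (1.5, "intermediate"),
        (2.5, "far"), (3.0, "far"),
    ])
    def test_printed_examples(self, ratio, expected):
        assert tp.classify_proximity(ratio * 0.67, 0.67) == expected

    def test_touching(self):
        assert tp.classify_proximity(0.0, 0.67, touching=True) == "touching"
        assert tp.classify_proximity(0.0, 0.67) == "touching"

    def test_2d_boundary_flag(self):
        D = 0.67
        assert tp.classify_proximity(2 * D, D) == "intermediate"
        assert tp.classify_proximity(2 * D, D, boundary_2d="far") == "far"

    def test_grid_matches_reference(self):
        D = 0.67
        for r in np.arange(0.0, 4.001, 0.01):
            got = tp.classify_proximity(r * D, D)
            assert got == reference_proximity(r * D, D)

    @given(d=st.floats(min_value=0, max_value=100),
           D=st.floats(min_value=1e-3, max_value=100))
    @settings(max_examples=200, deadline=None)
    def test_partition_property(self, d, D):
        cat = tp.classify_proximity(d, D)
        assert cat in tp.PROXIMITY_CATEGORIES

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            tp.classify_proximity(-0.1, 0.67)


def line_centerline(start, end, n=101, pc_at_start=True):
    pts = np.linspace(start, end, n)
    return Centerline(points=pts, pc_at_start=pc_at_start)


class TestAssociationProfile:
    def test_coincident_centerlines_fully_paired(self):
        a = line_centerline((0, 0, 0), (0, 0, 5))
        b = line_centerline((0, 0.1, 0), (0, 0.1, 5))
        prof = tp.association_profile(a, b, epsilon=0.67)
        assert prof.all()

    def test_separated_centerlines_unpaired(self):
        a = line_centerline((0, 0, 0), (0, 0, 5))
        b = line_centerline((0, 2.0, 0), (0, 2.0, 5))
        assert not tp.association_profile(a, b, epsilon=0.67).any()

    def test_homolog_swap_symmetry(self):
        rng = np.random.default_rng(3)
        a = Centerline(np.cumsum(rng.normal(0, 0.1, (50, 3)), axis=0))
        b = Centerline(a.points + rng.normal(0, 0.5, 3))
        p1 = tp.association_profile(a, b, epsilon=0.67)
        p2 = tp.association_profile(b, a, epsilon=0.67)
        assert np.array_equal(p1, p2)

    def test_planted_partial_run_boundary(self, thirds_paint):
        from territory3d.synth.nucleus import (NucleusSpec, PairSpec,
                                               generate_nucleus)
        from territory3d.morphometry import Centerline as CL

        nuc = NucleusSpec(pairs=[PairSpec(paint=thirds_paint,
                                          stage_label="extended",
                                          configuration="Y-PC",
                                          target_slenderness=8.0)])
        generate_nucleus(nuc, seed=5)
        a, b = nuc.territories["I"]
        prof = tp.association_profile(CL(a.centerline), CL(b.centerline),
                                      epsilon=a.width)
        runs = np.flatnonzero(prof)
        assert runs[0] == 0
        assert abs((runs[-1] + 1) / len(prof) - 0.5) <= 0.1  # within one bin


class TestAlignmentState:
    def test_extremes(self):
        assert tp.classify_alignment_state(np.ones(20, bool)) == "full"
        assert tp.classify_alignment_state(np.zeros(20, bool)) == "unaligned"

    def test_partial(self):
        prof = np.zeros(20, bool)
        prof[:10] = True
        assert tp.classify_alignment_state(prof) == "partial"

    def test_full_requires_terminal_bins(self):
        prof = np.ones(20, bool)
        prof[0] = False
        assert tp.classify_alignment_state(prof) == "partial"
        prof = np.ones(20, bool)
        prof[7] = False  # one interior dropout tolerated
        assert tp.classify_alignment_state(prof) == "full"


def profile_with_runs(runs, bins=20):
    p = np.zeros(bins, bool)
    for a, b in runs:
        p[a:b] = True
    return p


class TestConfiguration:
    @pytest.mark.parametrize("runs,touching,expected", [
        ([], False, "no_contact"),
        ([], True, "no_alignment"),
        ([(0, 2)], True, "V-PC"),
        ([(0, 3)], True, "V-PC"),
        ([(0, 10)], True, "Y-PC"),
        ([(17, 20)], True, "V-NPC"),
        ([(10, 20)], True, "Y-NPC"),
        ([(8, 12)], True, "X"),
        ([(0, 2), (18, 20)], True, "O"),
        ([(0, 20)], True, "full"),
        ([(0, 2), (9, 11), (18, 20)], True, "other"),
    ])
    def test_taxonomy(self, runs, touching, expected):
        prof = profile_with_runs(runs)
        assert tp.classify_configuration(prof, touching) == expected

    def test_pc_on_right_flips_sides(self):
        prof = profile_with_runs([(0, 2)])
        assert tp.classify_configuration(prof, True, pc_at_start=False) == "V-NPC"

    def test_full_consistency_with_alignment_state(self):
        prof = np.ones(20, bool)
        assert tp.classify_configuration(prof, True) == "full"
        assert tp.classify_alignment_state(prof) == "full"


class TestImageRouteRecovery:
    @pytest.mark.parametrize("cfg", ["Y-PC", "X", "full", "no_contact"])
    def test_spot_checks(self, thirds_paint, cfg):
        from territory3d.panels import configuration_recovery_panel

        df = configuration_recovery_panel(per_label=2, seed=77, labels=[cfg])
        assert (df["recovered"] == cfg).all()
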