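"""Image-route scoring of homolog pairs.

Homologs carry identical paint, so whenever two homologs associate anywhere
along their length their segmented masks fuse into a single territory.  This
module recovers the association geometry of such a merged territory from its
skeleton graph:

1. **strand contraction** — thinning a side-by-side (paired) stretch of two
   tubes yields either a single line or two parallel strands bridged into a
   ladder.  Skeleton voxels that lie within the pairing distance of a
   *geodesically distant*, like-colored voxel are partner strands; merging
   each partner pair collapses ladders onto a single homolog-pair axis.
2. **topology + terminal colors** — on the contracted graph, the
   configurations become distinguishable shapes: a simple path with
   opposite-colored tips is a fully aligned pair; a path with like-colored
   tips is a V folded at the opposite end; three branches from a junction are
   a V or Y (the odd-colored branch is the shared stretch, V vs Y by its
   relative length); four branches around a middle stretch are an X; a wide
   cycle is an O.  A junction whose neighborhood mixes fluorophores of
   *non-adjacent* chromosome segments is a contact between unrelated regions
   (one homolog's end against the other's middle), scored as no-alignment.

The result is expressed as an association profile + touching flag and then
labeled by :func:`territory3d.topology.classify_configuration`, so the
taxonomy rules live in one place.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from territory3d import morphometry as mm
from territory3d import skeleton as sk
from territory3d import topology as tp
from territory3d.io import VoxelImage
from territory3d.paint import PaintScheme
from territory3d.segmentation import TerritoryMask

__all__ = ["score_homolog_pair", "decompose_merged_pair"]

#: spatial partner search radius, in units of tube radius
PARTNER_RADIUS_FACTOR = 2.4
#: a partner is a distinct strand when its geodesic distance exceeds this
#: multiple of the spatial distance (plus an absolute floor, µm)
PARTNER_GEODESIC_RATIO = 3.0
PARTNER_GEODESIC_FLOOR = 0.8
#: cycles narrower than this (µm) are thinning ladders, not O-shapes
MIN_CYCLE_WIDTH = 0.7
#: nominal V-type paired fraction when the shared stretch is unresolvable
NOMINAL_TIP_FRACTION = 0.1
DEFAULT_BINS = tp.DEFAULT_BINS


# ---------------------------------------------------------------------------
# skeleton features

def _skeleton_features(image: VoxelImage, mask: np.ndarray, paint: PaintScheme):
    vs = np.asarray(image.voxel_size, dtype=float)
    g = sk.skeleton_voxel_graph(mask, vs)
    nodes = sorted(g.nodes)
    if len(nodes) < 2:
        return None
    pos = (np.asarray(nodes, dtype=float) + 0.5) * vs
    idx = np.asarray(nodes)
    segs = sorted(paint.segments, key=lambda s: s.start)
    # lightly smoothed, background-subtracted channels: stable color calls
    # under Poisson noise
    smooth = []
    for s in segs:
        ch = ndimage.gaussian_filter(image.channel(s.channel), 1.0)
        bg = float(np.median(ch[~mask])) if (~mask).any() else 0.0
        smooth.append(np.clip(ch - bg, 0.0, None))
    vals = np.stack([c[idx[:, 0], idx[:, 1], idx[:, 2]] for c in smooth])
    rank = vals.argmax(axis=0)
    rank[vals.max(axis=0) <= 0] = -1
    # blur-robust tube radius: the half-maximum of a blurred edge stays at
    # the true surface, so measure the EDT of the half-max core mask rather
    # than of the (PSF-fattened) segmentation mask
    summed = np.sum(smooth, axis=0)
    node_int = summed[idx[:, 0], idx[:, 1], idx[:, 2]]
    ref = float(np.median(node_int[node_int > 0])) if (node_int > 0).any() else 0.0
    if ref > 0:
        core = mask & (summed >= 0.5 * ref)
        edt_core = ndimage.distance_transform_edt(core, sampling=vs)
        rc = edt_core[idx[:, 0], idx[:, 1], idx[:, 2]]
        rc = rc[rc > 0]
        r_hat = (float(np.median(rc)) if rc.size else 0.3) + 0.5 * float(vs.min())
    else:
        r_hat = 0.3
    return dict(graph=g, nodes=nodes, pos=pos, r_hat=r_hat, rank=rank,
                segs=segs, smooth_channels=smooth)


def _partner_pairs(feat) -> list[tuple[int, int]]:
    """Index pairs of geodesically distant, like-colored strand partners."""
    g = feat["graph"]
    nodes = feat["nodes"]
    pos = feat["pos"]
    rank = feat["rank"]
    rho = PARTNER_RADIUS_FACTOR * feat["r_hat"]
    tree = cKDTree(pos)
    raw = tree.query_pairs(rho, output_type="ndarray")
    cand: dict[int, list[int]] = {}
    for i, j in raw:
        if rank[i] >= 0 and rank[j] >= 0 and abs(int(rank[i]) - int(rank[j])) <= 1:
            cand.setdefault(int(i), []).append(int(j))
    out = []
    cutoff = max(PARTNER_GEODESIC_RATIO * rho, PARTNER_GEODESIC_FLOOR)
    for i, js in cand.items():
        dist = nx.single_source_dijkstra_path_length(
            g, nodes[i], cutoff=cutoff, weight="weight")
        for j in js:
            spat = float(np.linalg.norm(pos[i] - pos[j]))
            need = max(PARTNER_GEODESIC_RATIO * spat, PARTNER_GEODESIC_FLOOR)
            if dist.get(nodes[j], np.inf) >= need:
                out.append((i, j))
    return out


def _contract(feat):
    """Merge partner strands; returns (graph, positions, ranks) keyed by
    representative node id (int)."""
    nodes = feat["nodes"]
    pos = feat["pos"]
    rank = feat["rank"]
    n = len(nodes)
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in _partner_pairs(feat):
        parent[find(i)] = find(j)
    groups: dict[int, list[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    gpos = {k: pos[v].mean(axis=0) for k, v in groups.items()}
    grank = {}
    for k, v in groups.items():
        rs = [int(rank[i]) for i in v if rank[i] >= 0]
        grank[k] = int(np.median(rs)) if rs else -1
    node_of = {nodes[i]: find(i) for i in range(n)}
    h = nx.Graph()
    h.add_nodes_from(groups)
    for a, b in feat["graph"].edges:
        ga, gb = node_of[a], node_of[b]
        if ga == gb:
            continue
        w = float(np.linalg.norm(gpos[ga] - gpos[gb]))
        if not h.has_edge(ga, gb) or h.edges[ga, gb]["weight"] > w:
            h.add_edge(ga, gb, weight=max(w, 1e-6))
    sk._reduce_triangles(h)
    return h, gpos, grank


def _contact_length(image: VoxelImage, mask: np.ndarray, feat) -> float:
    """Skeleton length whose neighborhood mixes non-adjacent segment colors.

    Homologous association juxtaposes like-colored (or boundary-adjacent)
    regions; a neighborhood containing strong signal from two *non-adjacent*
    chromosome segments can only be a contact between unrelated regions of
    the two homologs.
    """
    vs = np.asarray(image.voxel_size, dtype=float)
    segs = feat["segs"]
    if len(segs) < 3:
        return 0.0
    vox_idx = np.argwhere(mask)
    vtree = cKDTree((vox_idx + 0.5) * vs)
    rad = 1.8 * feat["r_hat"]
    chans = feat["smooth_channels"]
    total = 0.0
    g = feat["graph"]
    nodes = feat["nodes"]
    for i, n in enumerate(nodes):
        near = vtree.query_ball_point(feat["pos"][i], rad)
        if not near:
            continue
        sub = vox_idx[near]
        vals = [float(c[sub[:, 0], sub[:, 1], sub[:, 2]].mean()) for c in chans]
        vmax = max(vals)
        if vmax <= 0:
            continue
        present = [k for k, v in enumerate(vals) if v > 0.3 * vmax]
        if present and (max(present) - min(present)) > 1:
            total += sum(d["weight"] for d in
                         (g.edges[n, m] for m in g.neighbors(n))) / 2.0
    return total


def _cycle_width(cycle, gpos) -> float:
    """Max distance between geodesically opposite points of a cycle."""
    pts = np.asarray([gpos[c] for c in cycle])
    m = len(pts)
    if m < 4:
        return 0.0
    return float(max(np.linalg.norm(pts[i] - pts[(i + m // 2) % m])
                     for i in range(m)))


def _break_skinny_cycles(h: nx.Graph, gpos) -> int:
    """Remove thinning-ladder remnants; returns the number of wide cycles."""
    for _ in range(200):
        cycles = nx.cycle_basis(h)
        skinny = [c for c in cycles if _cycle_width(c, gpos) < MIN_CYCLE_WIDTH]
        if not skinny:
            return len(cycles)
        c = skinny[0]
        edges = list(zip(c, c[1:] + [c[0]]))
        edges = [e for e in edges if h.has_edge(*e)]
        if not edges:
            return len(cycles)
        drop = max(edges, key=lambda e: h.edges[e]["weight"])
        h.remove_edge(*drop)
    return len(nx.cycle_basis(h))


# ---------------------------------------------------------------------------
# classification on the contracted graph

def _majority_rank(h, grank, start, max_dist=0.35) -> int:
    dist = nx.single_source_dijkstra_path_length(h, start, cutoff=max_dist,
                                                 weight="weight")
    rs = [grank[n] for n in dist if grank[n] >= 0]
    if not rs:
        return -1
    vals, counts = np.unique(rs, return_counts=True)
    return int(vals[counts.argmax()])


def _junction_ranks(h, grank, junction, radius=0.45) -> set[int]:
    dist = nx.single_source_dijkstra_path_length(h, junction, cutoff=radius,
                                                 weight="weight")
    return {grank[n] for n in dist if grank[n] >= 0}


def _mixed_nonadjacent(ranks: set[int]) -> bool:
    return bool(ranks) and (max(ranks) - min(ranks)) > 1


def decompose_merged_pair(image: VoxelImage, territory: TerritoryMask,
                          paint: PaintScheme, bins: int = DEFAULT_BINS,
                          ) -> tuple[np.ndarray, bool, list[str]]:
    """Association profile (left-anchored coordinate) + touching flag."""
    flags: list[str] = []
    profile = np.zeros(bins, dtype=bool)
    feat = _skeleton_features(image, territory.mask, paint)
    if feat is None:
        flags.append("degenerate_skeleton")
        return profile, True, flags
    n_seg = len(feat["segs"])
    if _contact_length(image, territory.mask, feat) >= 0.12:
        flags.append("unrelated_region_contact")
        return profile, True, flags
    h, gpos, grank = _contract(feat)
    n_wide = _break_skinny_cycles(h, gpos)
    bg = sk.branch_graph(h, spur_length=0.3)
    ends = bg.endpoints
    junctions = bg.junctions

    def set_run(lo: float, hi: float) -> None:
        i0 = int(np.floor(lo * bins + 1e-9))
        i1 = int(np.ceil(hi * bins - 1e-9))
        profile[max(i0, 0):min(i1, bins)] = True

    if n_wide >= 1:
        # homologs joined at both ends, bowed apart between: O
        set_run(0.0, NOMINAL_TIP_FRACTION)
        set_run(1.0 - NOMINAL_TIP_FRACTION, 1.0)
        return profile, True, flags

    if len(ends) == 2 and not junctions:
        r0 = _majority_rank(h, grank, ends[0])
        r1 = _majority_rank(h, grank, ends[1])
        if r0 < 0 or r1 < 0:
            flags.append("unorientable")
            profile[:] = True
            return profile, True, flags
        if {r0, r1} == {0, n_seg - 1}:
            profile[:] = True  # opposite terminal colors: fully aligned
            return profile, True, flags
        if r0 == r1 and r0 in (0, n_seg - 1):
            # V folded at the end opposite to the tips
            if r0 == 0:
                set_run(1.0 - NOMINAL_TIP_FRACTION, 1.0)
            else:
                set_run(0.0, NOMINAL_TIP_FRACTION)
            return profile, True, flags
        flags.append("ambiguous_path_colors")
        return profile, True, flags

    if len(ends) == 3 and len(junctions) == 1:
        jranks = _junction_ranks(h, grank, junctions[0])
        if _mixed_nonadjacent(jranks):
            return profile, True, flags  # unrelated-region contact
        tip_ranks = [_majority_rank(h, grank, e) for e in ends]
        counts = {r: tip_ranks.count(r) for r in set(tip_ranks)}
        minority = [r for r, c in counts.items() if c == 1]
        if len(minority) != 1 or minority[0] not in (0, n_seg - 1):
            flags.append("ambiguous_branch_colors")
            return profile, True, flags
        trunk_rank = minority[0]
        trunk_end = ends[tip_ranks.index(trunk_rank)]
        trunk = next(b for b in bg.branches
                     if trunk_end in (b.end_a, b.end_b))
        arms = [b for b in bg.branches if b is not trunk]
        arm_len = float(np.mean([b.length for b in arms])) if arms else 0.0
        frac = trunk.length / max(trunk.length + arm_len, 1e-9)
        frac = min(max(frac, 0.05), 0.95)
        if trunk_rank == 0:
            set_run(0.0, frac)
        else:
            set_run(1.0 - frac, 1.0)
        return profile, True, flags

    if len(ends) == 4 and 1 <= len(junctions) <= 2:
        jranks = set()
        for j in junctions:
            jranks |= _junction_ranks(h, grank, j)
        if _mixed_nonadjacent(jranks):
            return profile, True, flags  # transversal crossing
        if len(junctions) == 2:
            middle = [b for b in bg.branches
                      if {b.end_a, b.end_b} == set(junctions)]
            m = min(b.length for b in middle) if middle else 0.0
        else:
            m = 0.0
        arms = [b for b in bg.branches
                if (b.end_a in ends) != (b.end_b in ends)]
        hom_len = m + sum(b.length for b in arms) / 2.0
        frac = max(m / max(hom_len, 1e-9), 2.0 / bins)
        set_run(0.5 - frac / 2.0, 0.5 + frac / 2.0)
        return profile, True, flags

    flags.append(f"complex_skeleton:{len(ends)}e{len(junctions)}j")
    return profile, True, flags


def score_homolog_pair(image: VoxelImage, territories: list[TerritoryMask],
                       paint: PaintScheme, nucleus_id: str = "n0",
                       bins: int = DEFAULT_BINS) -> tp.PairRecord:
    """Full pair scoring of one chromosome's 1-2 segmented territories.

    Two territories: unpaired homologs — edge distance, proximity and the
    no_contact configuration.  One territory: merged homologs — skeleton
    decomposition into an association profile, then alignment state and
    configuration.
    """
    if not 1 <= len(territories) <= 2:
        raise ValueError("expected 1 or 2 territories for a homolog pair")
    flags: list[str] = []
    if len(territories) == 2:
        a, b = territories
        cl_a = mm.extract_centerline(a)
        cl_b = mm.extract_centerline(b)
        d_a = mm.estimate_width(a, cl_a)
        d_b = mm.estimate_width(b, cl_b)
        scale = 0.5 * (d_a + d_b)
        d = tp.edge_distance(a, b)
        touching = d == 0.0
        profile = np.zeros(bins, dtype=bool)
        if touching:
            flags.append("touching_but_split")
    else:
        t = territories[0]
        cl = mm.extract_centerline(t)
        scale = mm.estimate_width(t, cl)
        d = 0.0
        profile, touching, dflags = decompose_merged_pair(image, t, paint, bins)
        flags.extend(dflags)
    config = tp.classify_configuration(profile, touching,
                                       pc_at_start=paint.pc_end == "left")
    state = tp.classify_alignment_state(profile)
    if config == "no_contact":
        state = "unaligned"
    return tp.PairRecord(
        nucleus_id=nucleus_id,
        chromosome_a=paint.chromosome_id,
        chromosome_b=paint.chromosome_id,
        kind="homologous",
        edge_distance_d=d,
        scale_d=scale,
        proximity=tp.classify_proximity(d, scale, touching),
        alignment_state=state,
        configuration=config,
        paired_fraction=float(np.mean(profile)),
        association_profile=profile,
        flags=flags,
    )
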