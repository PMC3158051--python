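"""End-to-end orchestration: synth -> segmentation -> morphometry ->
topology -> zoning/statistics, as a reproducible run with a manifest.

A run writes, under its output directory:

* ``stacks/<nucleus>.ome.tif`` and ``stacks/<nucleus>.truth.json`` (synth
  scenarios);
* ``territories.csv`` — per-territory morphometry (D, L, S, k, extension);
* ``pairs.csv`` — per-pair scores (edge distance, proximity, alignment
  state, configuration);
* ``nuclei.csv`` — per-nucleus rows, detected clustering, assigned zones;
* ``summary.json`` — zone metric tables, joint alignment matrices and the
  category statistics;
* ``manifest.json`` — config, software version, per-stage counts, sha256 of
  every output, and any stage failure.

Reruns with the same config and seed reproduce all tables bit-identically:
every random stream is derived from the run seed and the nucleus position.
"""

from __future__ import annotations

import hashlib
import json
import logging
import traceback
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

import territory3d
from territory3d import io as t3dio
from territory3d import morphometry as mm
from territory3d import segmentation as seg
from territory3d import topology as tp
from territory3d import zoning
from territory3d.pairing import score_homolog_pair
from territory3d.stats import chi_square_two_tailed, mann_whitney_two_tailed
from territory3d.synth.gonad import SCENARIOS, generate_gonad
from territory3d.synth.optics import OpticsParams, default_noisy_optics, render_voxels

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "score_nucleus", "validate_against_truth"]


class RunConfig(BaseModel):
    """Schema-validated configuration of a pipeline run."""

    scenario: str = "wildtype"
    seed: int = 0
    out_dir: Path = Path("territory3d-run")
    input_dir: Path | None = None  # score existing stacks instead of synth
    rows_premeiotic: int = 10
    rows_tz: int = 11
    rows_pachytene: int = 15
    nuclei_per_row: int = 2
    noise: bool = True
    threshold_policy: str = "background"
    min_volume: int = seg.DEFAULT_MIN_VOLUME
    merge_gap: float = Field(default=seg.DEFAULT_MERGE_GAP, gt=0)
    gap_fraction: float = mm.DEFAULT_GAP_FRACTION
    min_separation: float = mm.DEFAULT_MIN_SEPARATION
    min_prominence_fraction: float = mm.DEFAULT_MIN_PROMINENCE_FRACTION
    boundary_2d: str = "intermediate"
    premeiotic_rows_zone: int | None = None  # defaults to rows_premeiotic
    pachytene_length: int = 15
    write_stacks: bool = True

    def zone_scheme(self) -> zoning.ZoneScheme:
        kind = "syp1_six_zone" if self.scenario == "syp1" else "standard"
        pm = self.premeiotic_rows_zone or self.rows_premeiotic
        return zoning.ZoneScheme(kind=kind, premeiotic_rows=pm,
                                 pachytene_length=self.pachytene_length)

    def optics(self, nucleus_seed: int) -> OpticsParams:
        if self.noise:
            return default_noisy_optics(seed=nucleus_seed)
        return OpticsParams(photon_scale=100.0)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def detect_clustering(image: t3dio.VoxelImage, threshold: float = 0.10) -> bool:
    """Clustered-chromatin call from DAPI asymmetry.

    The intensity-weighted DAPI centroid of a clustered (transition-zone)
    nucleus is displaced toward the crowded side; the call compares that
    displacement with the nuclear radius (half the field extent).
    """
    c = image.dapi_channel
    if c is None:
        return False
    dapi = image.channel(c).astype(float)
    dapi = dapi - dapi.min()
    total = dapi.sum()
    if total <= 0:
        return False
    vs = np.asarray(image.voxel_size)
    grids = np.meshgrid(*[(np.arange(s) + 0.5) * v
                          for s, v in zip(image.shape, vs)], indexing="ij")
    centroid = np.array([float((g * dapi).sum() / total) for g in grids])
    center = np.array([s * v / 2.0 for s, v in zip(image.shape, vs)])
    radius = float(min(center))
    return bool(np.linalg.norm(centroid - center) > threshold * radius)


def score_nucleus(image: t3dio.VoxelImage, paints, nucleus_id: str,
                  config: RunConfig):
    """Segment and score one nucleus; returns (territory rows, pair rows,
    clustered flag)."""
    region = seg.nuclear_region(image)
    paint_channels = sorted({c for p in paints for c in p.channels})
    channel_masks = {
        c: seg.segment_channel(image, c, config.threshold_policy,
                               config.min_volume, region)
        for c in paint_channels
    }
    territory_rows = []
    pair_rows = []
    per_chrom_masks = {}
    for paint in paints:
        ters = seg.assemble_territories(image, channel_masks, paint,
                                        nucleus_id=nucleus_id,
                                        merge_gap=config.merge_gap)
        if not ters:
            log.warning("%s/%s: no territory found", nucleus_id,
                        paint.chromosome_id)
            continue
        if ters[0].fragmented:
            log.warning("%s/%s: fragmented, excluded from pair scoring",
                        nucleus_id, paint.chromosome_id)
        per_chrom_masks[paint.chromosome_id] = (paint, ters)
        for i, t in enumerate(ters):
            rec = mm.measure_territory(
                image, t, paint,
                gap_fraction=config.gap_fraction,
                min_prominence_fraction=config.min_prominence_fraction,
                min_separation=config.min_separation)
            territory_rows.append({
                "nucleus_id": nucleus_id,
                "chromosome": paint.chromosome_id,
                "territory_index": i,
                "width_d": rec.width_d,
                "length_l": rec.length_l,
                "slenderness_s": rec.slenderness_s,
                "segment_count": rec.segment_count_k,
                "highly_extended": rec.highly_extended,
                "fragmented": t.fragmented,
            })
        if not ters[0].fragmented and len(ters) <= 2:
            rec = score_homolog_pair(image, ters, paint, nucleus_id)
            pair_rows.append(_pair_row(rec))
    # heterologous pairs: largest territory of each chromosome pairing
    chroms = sorted(per_chrom_masks)
    for i, ca in enumerate(chroms):
        for cb in chroms[i + 1:]:
            pa, ta = per_chrom_masks[ca]
            pb, tb = per_chrom_masks[cb]
            for ma in ta:
                for mb in tb:
                    d = tp.edge_distance(ma, mb)
                    cl_a = mm.extract_centerline(ma)
                    cl_b = mm.extract_centerline(mb)
                    scale = 0.5 * (mm.estimate_width(ma, cl_a)
                                   + mm.estimate_width(mb, cl_b))
                    rec = tp.PairRecord(
                        nucleus_id=nucleus_id, chromosome_a=ca,
                        chromosome_b=cb, kind="heterologous",
                        edge_distance_d=d, scale_d=scale,
                        proximity=tp.classify_proximity(
                            d, scale, d == 0.0, config.boundary_2d),
                    )
                    pair_rows.append(_pair_row(rec))
    clustered = detect_clustering(image)
    return territory_rows, pair_rows, clustered


def _pair_row(rec: tp.PairRecord) -> dict:
    return {
        "nucleus_id": rec.nucleus_id,
        "chromosome_a": rec.chromosome_a,
        "chromosome_b": rec.chromosome_b,
        "kind": rec.kind,
        "edge_distance": rec.edge_distance_d,
        "scale_d": rec.scale_d,
        "proximity": rec.proximity,
        "alignment_state": rec.alignment_state,
        "configuration": rec.configuration,
        "paired_fraction": rec.paired_fraction,
        "flags": ";".join(rec.flags),
    }


def run_pipeline(config: RunConfig) -> dict:
    """Run synth -> score -> report; returns the manifest dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": json.loads(config.model_dump_json()),
        "version": territory3d.__version__,
        "stages": {},
        "outputs": {},
    }
    try:
        stacks = _stage_synth(config, out, manifest)
        terr_df, pair_df, nuc_df = _stage_score(config, stacks, manifest)
        _stage_report(config, out, terr_df, pair_df, nuc_df, manifest)
    except Exception as exc:  # stage failures land in the manifest
        stage = manifest.get("failed_stage", "unknown")
        manifest["error"] = {"stage": stage, "message": str(exc),
                             "trace": traceback.format_exc()}
        log.error("pipeline failed in stage %s: %s", stage, exc)
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest["outputs"][str(f.relative_to(out))] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  default=str))
    return manifest


def _stage_synth(config: RunConfig, out: Path, manifest: dict):
    manifest["failed_stage"] = "synth"
    if config.input_dir is not None:
        stack_dir = Path(config.input_dir)
        if not stack_dir.exists():
            raise FileNotFoundError(
                f"io_segmentation input not found: {stack_dir}")
        files = sorted(stack_dir.glob("*.ome.tif"))
        stacks = [(f, f.with_suffix("").with_suffix(".truth.json")) for f in files]
        manifest["stages"]["synth"] = {"skipped": True, "n_stacks": len(stacks)}
        return stacks
    if config.scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {config.scenario!r}")
    layout = generate_gonad(
        scenario=config.scenario,
        rows_premeiotic=config.rows_premeiotic,
        rows_tz=config.rows_tz,
        rows_pachytene=config.rows_pachytene,
        nuclei_per_row=config.nuclei_per_row,
        seed=config.seed,
    )
    stack_dir = out / "stacks"
    stack_dir.mkdir(exist_ok=True)
    stacks = []
    from territory3d.synth.optics import nucleus_ground_truth

    import zlib

    for pl in layout.nuclei:
        nuc = pl.nucleus
        nseed = int(np.random.default_rng(
            [config.seed, pl.row, zlib.crc32(nuc.nucleus_id.encode())]
        ).integers(2**31))
        optics = config.optics(nseed)
        img, truth = render_voxels(nuc, optics)
        vi = t3dio.VoxelImage(img, optics.voxel_size)
        if config.write_stacks:
            spath = stack_dir / f"{nuc.nucleus_id}.ome.tif"
            tpath = stack_dir / f"{nuc.nucleus_id}.truth.json"
            t3dio.write_stack(spath, vi)
            t3dio.write_truth(tpath, truth)
            stacks.append((spath, tpath))
        else:
            stacks.append((vi, truth))
    manifest["stages"]["synth"] = {
        "n_nuclei": len(layout.nuclei),
        "zone_rows": {k: list(v) for k, v in layout.zone_rows.items()},
    }
    manifest["_layout"] = layout
    return stacks


def _stage_score(config: RunConfig, stacks, manifest: dict):
    manifest["failed_stage"] = "io_segmentation"
    from territory3d.synth.gonad import _wildtype_paints, _x_paints

    paints = _wildtype_paints() if config.scenario == "wildtype" else _x_paints()
    terr_rows, pair_rows, nuc_rows = [], [], []
    for item, truth_src in stacks:
        if isinstance(item, (str, Path)):
            vi = t3dio.read_stack(item)
            truth = t3dio.read_truth(truth_src) if Path(truth_src).exists() else {}
        else:
            vi, truth = item, truth_src
        nucleus_id = truth.get("nucleus_id", Path(str(item)).stem)
        manifest["failed_stage"] = "score"
        t_rows, p_rows, clustered = score_nucleus(vi, paints, nucleus_id, config)
        terr_rows.extend(t_rows)
        pair_rows.extend(p_rows)
        nuc_rows.append({
            "nucleus_id": nucleus_id,
            "row": truth.get("row"),
            "clustered": clustered,
            "planted_zone": truth.get("zone"),
            "planted_clustered": truth.get("clustered"),
        })
    manifest["stages"]["score"] = {
        "n_nuclei": len(nuc_rows),
        "n_territories": len(terr_rows),
        "n_pairs": len(pair_rows),
        "n_fragmented": int(sum(r["fragmented"] for r in terr_rows)),
    }
    return (pd.DataFrame(terr_rows), pd.DataFrame(pair_rows),
            pd.DataFrame(nuc_rows))


def _stage_report(config: RunConfig, out: Path, terr_df, pair_df, nuc_df,
                  manifest: dict) -> None:
    manifest["failed_stage"] = "zoning_stats"
    # chromosome-I alignment per nucleus feeds the zone assignment
    if len(pair_df):
        chr_i = (pair_df[(pair_df["kind"] == "homologous")
                         & (pair_df["chromosome_a"] == "I")]
                 .set_index("nucleus_id")["alignment_state"])
        nuc_df["chrI_alignment"] = nuc_df["nucleus_id"].map(chr_i)
    else:
        nuc_df["chrI_alignment"] = None
    if nuc_df["row"].notna().all() and len(nuc_df):
        nuc_df = zoning.assign_zones(nuc_df, config.zone_scheme())
    else:
        nuc_df["zone"] = None
    zone_of = nuc_df.set_index("nucleus_id")["zone"]
    terr_df["zone"] = terr_df["nucleus_id"].map(zone_of)
    pair_df["zone"] = pair_df["nucleus_id"].map(zone_of)

    terr_df.to_csv(out / "territories.csv", index=False)
    pair_df.to_csv(out / "pairs.csv", index=False)
    nuc_df.to_csv(out / "nuclei.csv", index=False)

    summary: dict = {"zone_rows": {k: list(v) for k, v in
                                   nuc_df.attrs.get("zone_rows", {}).items()}}
    hom = pair_df[pair_df["kind"] == "homologous"].copy()
    het = pair_df[pair_df["kind"] == "heterologous"].copy()
    if len(hom) and len(het):
        pm = nuc_df[nuc_df["zone"] == "premeiotic"]["nucleus_id"]
        cats = list(tp.PROXIMITY_CATEGORIES)
        h1 = hom[hom["nucleus_id"].isin(pm)]["proximity"].value_counts()
        h2 = het[het["nucleus_id"].isin(pm)]["proximity"].value_counts()
        table = np.array([[int(h1.get(c, 0)) for c in cats],
                          [int(h2.get(c, 0)) for c in cats]])
        keep = table.sum(axis=0) > 0
        summary["premeiotic_proximity"] = {
            "categories": cats,
            "homologous": table[0].tolist(),
            "heterologous": table[1].tolist(),
        }
        if keep.sum() >= 2 and table.sum(axis=1).min() > 0:
            summary["premeiotic_proximity"]["chi_square_p"] = (
                chi_square_two_tailed(table[:, keep]))
    morpho = terr_df.rename(columns={"chromosome": "chromosome"})
    hom_named = hom.rename(columns={"chromosome_a": "chromosome"})
    tables = zoning.summarize_zone_metrics(morpho, hom_named)
    for name, df in tables.items():
        summary[name] = json.loads(df.to_json(orient="records"))
    # joint chromosome alignment matrix per the standard two-paint design
    chroms = sorted(hom["chromosome_a"].unique())
    if len(chroms) == 2:
        a = hom[hom["chromosome_a"] == chroms[0]].set_index("nucleus_id")["alignment_state"]
        b = hom[hom["chromosome_a"] == chroms[1]].set_index("nucleus_id")["alignment_state"]
        common = a.index.intersection(b.index)
        if len(common):
            matd = zoning.joint_alignment_matrix(a[common], b[common])
            summary["joint_alignment_matrix"] = {
                "chromosomes": chroms,
                "states": list(matd.index),
                "counts": matd.values.tolist(),
            }
    # segment counts: transition zone vs premeiotic (per chromosome)
    mw = {}
    for chrom, grp in terr_df.groupby("chromosome"):
        a = grp[grp["zone"] == "premeiotic"]["segment_count"]
        b = grp[grp["zone"] == "transition"]["segment_count"]
        if len(a) and len(b):
            mw[chrom] = mann_whitney_two_tailed(a, b)
    if mw:
        summary["segment_count_mw_p"] = mw
    (out / "summary.json").write_text(json.dumps(summary, indent=2,
                                                 default=str))
    manifest["stages"]["report"] = {"tables": ["territories.csv", "pairs.csv",
                                               "nuclei.csv", "summary.json"]}
    manifest.pop("failed_stage", None)
    manifest.pop("_layout", None)


def validate_against_truth(out_dir: str | Path) -> dict:
    """Recovery report of a synth-scenario run against its planted truth.

    Confusion matrices for configuration and proximity, zone recovery, and
    bias/RMSE of the morphometric estimators.
    """
    out = Path(out_dir)
    stack_dir = out / "stacks"
    truths = {}
    for tf in sorted(stack_dir.glob("*.truth.json")):
        t = t3dio.read_truth(tf)
        truths[t["nucleus_id"]] = t
    if not truths:
        raise FileNotFoundError(f"no ground-truth sidecars under {stack_dir}")
    terr = pd.read_csv(out / "territories.csv")
    pairs = pd.read_csv(out / "pairs.csv")
    nuc = pd.read_csv(out / "nuclei.csv")

    report: dict = {}
    # configuration confusion
    conf = {}
    hom = pairs[pairs["kind"] == "homologous"]
    for _, row in hom.iterrows():
        t = truths.get(row["nucleus_id"])
        if not t:
            continue
        planted = t["pairs"].get(row["chromosome_a"], {}).get("configuration")
        if planted:
            conf.setdefault(planted, {})
            conf[planted][row["configuration"]] = (
                conf[planted].get(row["configuration"], 0) + 1)
    report["configuration_confusion"] = conf
    n_ok = sum(v.get(k, 0) for k, v in conf.items())
    n_tot = sum(sum(v.values()) for v in conf.values())
    report["configuration_accuracy"] = n_ok / n_tot if n_tot else None

    # morphometry recovery (per planted territory, matched by chromosome;
    # only meaningful for unmerged pairs, so restrict to 2-territory ones)
    errs = {"width": [], "length": [], "slenderness": [], "segments": []}
    for _, row in terr.iterrows():
        t = truths.get(row["nucleus_id"])
        if not t:
            continue
        models = t["territories"].get(row["chromosome"])
        planted_pair = t["pairs"].get(row["chromosome"], {})
        if not models or planted_pair.get("configuration") not in (
                "no_contact", None):
            continue
        m = models[int(row["territory_index"]) % len(models)]
        errs["width"].append(row["width_d"] - m["width"])
        errs["length"].append(row["length_l"] - m["length"])
        errs["slenderness"].append(row["slenderness_s"] - m["slenderness"])
    report["estimator_errors"] = {
        k: {"bias": float(np.mean(v)), "rmse": float(np.sqrt(np.mean(np.square(v))))}
        for k, v in errs.items() if v
    }
    # clustering + zone recovery
    merged = nuc.dropna(subset=["planted_zone"])
    if len(merged):
        report["clustering_accuracy"] = float(
            (merged["clustered"] == merged["planted_clustered"]).mean())
        # the pachytene scoring window starts 5 rows proximal of the TZ, so
        # planted-pachytene nuclei in that gap ("post_transition") are simply
        # unscored, not misassigned
        compatible = {"pachytene": {"pachytene", "post_transition", "proximal"},
                      "zone2": {"transition"}, "zone3": {"transition"}}
        agree = [
            (str(r["zone"]) == str(r["planted_zone"])) or
            (str(r["zone"]) in compatible.get(str(r["planted_zone"]), set()))
            for _, r in merged.iterrows() if pd.notna(r.get("zone"))
        ]
        if agree:
            report["zone_agreement"] = float(np.mean(agree))
    (out / "validation.json").write_text(json.dumps(report, indent=2))
    return report
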