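"""Whole-gonad synthesis: row-organized nuclei with planted zone structure.

The C. elegans gonad is a spatio-temporal gradient: nuclei enter at the
distal tip, spend their first ~10 rows in the premeiotic zone (compact ovoid
territories, unclustered chromatin), traverse the transition zone
(leptotene/zygotene; chromatin clustered to one nuclear side, territories
elongating, chromosome I in a mixture of alignment states), and reach
pachytene (homologs fully synapsed, appearing as single merged territories).

Scenario presets emulate the genotypes scored in the source study:

``wildtype``
    chromosomes I and II; TZ mixture of alignment states; pachytene mostly
    fully aligned.
``syp1``
    no synaptonemal-complex central region: partial (PC-end) associations
    persist but full alignment never occurs; the meiotic region is divided
    into five equal-width scoring zones (widths n,n,n,n,N-4n with
    n = round(N/5)).
``him8e1489``
    X-chromosome PC-binding lost *and* territory extension lost: X stays
    compact and never aligns; chromosome I behaves as wild type.
``him8me4``
    X extends normally but fails to align; chromosome I as wild type.
``meDf2``
    X-PC deleted: no X extension and no X alignment, but X territories remain
    beaded (elevated painted-segment counts).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from territory3d.paint import PaintScheme, three_color_scheme, two_color_scheme
from territory3d.synth.nucleus import NucleusSpec, PairSpec, generate_nucleus

__all__ = ["NucleusPlacement", "GonadLayout", "generate_gonad", "SCENARIOS"]

SCENARIOS = ("wildtype", "syp1", "him8e1489", "him8me4", "meDf2")


@dataclass
class NucleusPlacement:
    row: int
    nucleus: NucleusSpec


@dataclass
class GonadLayout:
    genotype: str
    nuclei: list[NucleusPlacement]
    zone_rows: dict[str, tuple[int, int]]  # planted zone -> (first_row, last_row)
    scheme_kind: str = "standard"  # or "syp1_six_zone"

    @property
    def n_rows(self) -> int:
        return max(p.row for p in self.nuclei)

    def planted_zone_of_row(self, row: int) -> str:
        for zone, (a, b) in self.zone_rows.items():
            if a <= row <= b:
                return zone
        raise KeyError(f"row {row} not covered by any planted zone")


def _sample_config(rng: np.random.Generator, table: dict[str, float]) -> str:
    labels = list(table)
    p = np.array([table[k] for k in labels], dtype=float)
    p /= p.sum()
    return labels[rng.choice(len(labels), p=p)]


# alignment-configuration mixtures per (scenario, zone, chromosome kind)
TZ_MIX_ALIGNING = {"full": 0.40, "Y-PC": 0.20, "V-PC": 0.15,
                   "no_contact": 0.15, "no_alignment": 0.10}
TZ_MIX_NONALIGNING = {"no_contact": 0.55, "no_alignment": 0.45}
PACHYTENE_MIX_ALIGNING = {"full": 0.9, "Y-PC": 0.1}
SYP1_MIX = {"V-PC": 0.35, "Y-PC": 0.25, "X": 0.05, "O": 0.05,
            "no_alignment": 0.15, "no_contact": 0.15}


def _wildtype_paints() -> list[PaintScheme]:
    return [two_color_scheme("I", (0, 1)), two_color_scheme("II", (2, 3))]


def _x_paints() -> list[PaintScheme]:
    return [two_color_scheme("I", (0, 1)), two_color_scheme("X", (2, 3))]


def _meiotic_pair(rng: np.random.Generator, paint: PaintScheme, scenario: str,
                  zone: str) -> PairSpec:
    """Extended-stage pair spec for one chromosome in a meiotic-zone nucleus."""
    chrom = paint.chromosome_id
    extends = True
    if chrom == "X" and scenario in ("him8e1489", "meDf2"):
        extends = False
    aligns = True
    if scenario == "syp1":
        mix = SYP1_MIX
    elif chrom == "X" and scenario in ("him8e1489", "him8me4", "meDf2"):
        aligns = False
        mix = TZ_MIX_NONALIGNING
    elif zone == "pachytene":
        mix = PACHYTENE_MIX_ALIGNING
    else:
        mix = TZ_MIX_ALIGNING
    cfg = _sample_config(rng, mix)
    if cfg == "no_alignment":
        slend = float(rng.uniform(3.5, 5.5))
    elif extends:
        slend = float(rng.uniform(3.0, 10.0)) if zone != "pachytene" else float(rng.uniform(6.5, 10.0))
    else:
        slend = float(rng.uniform(1.2, 2.5))
    if cfg not in ("no_contact", "no_alignment"):
        # paired constructions use planar threads, which fit the nuclear
        # sphere only up to moderate extension
        slend = min(slend, 8.0)
    beads = 1
    if extends or (chrom == "X" and scenario == "meDf2"):
        beads = int(rng.integers(2, 6))
    stage = "extended" if (extends and slend > 2.5) else "compact"
    if stage == "compact" and cfg not in ("no_contact", "no_alignment", "full"):
        # compact non-extending chromosomes don't hold partial thread configs
        cfg = "no_contact" if not aligns else cfg
    return PairSpec(paint=paint, stage_label=stage, configuration=cfg,
                    target_slenderness=slend, bead_count=beads)


def _premeiotic_pair(rng: np.random.Generator, paint: PaintScheme) -> PairSpec:
    return PairSpec(paint=paint, stage_label="compact", configuration=None,
                    target_slenderness=float(rng.uniform(1.2, 2.0)),
                    bead_count=1)


def generate_gonad(scenario: str = "wildtype",
                   rows_premeiotic: int = 10,
                   rows_tz: int = 11,
                   rows_pachytene: int = 15,
                   nuclei_per_row: int = 2,
                   seed: int = 0,
                   paints: list[PaintScheme] | None = None,
                   nuclear_radius: float = 2.0) -> GonadLayout:
    """Generate a row-organized gonad with planted zone labels.

    Per-nucleus random streams are split hierarchically from
    ``(seed, row, index)`` so that a given nucleus is reproducible under
    layout changes.  Zone labels are planted: the recovered zoning of the
    scoring pipeline is validated against them.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; choose from {SCENARIOS}")
    if min(rows_premeiotic, rows_tz, rows_pachytene) < 1:
        raise ValueError("every zone needs at least one row")
    if nuclei_per_row < 1:
        raise ValueError("empty layout: need at least one nucleus per row")
    if paints is None:
        paints = _wildtype_paints() if scenario == "wildtype" else _x_paints()

    n_meiotic = rows_tz + rows_pachytene
    zone_rows: dict[str, tuple[int, int]]
    if scenario == "syp1":
        from territory3d.zoning import split_meiotic_zones

        widths = split_meiotic_zones(n_meiotic)
        zone_rows = {"premeiotic": (1, rows_premeiotic)}
        start = rows_premeiotic + 1
        for i, w in enumerate(widths, start=2):
            zone_rows[f"zone{i}"] = (start, start + w - 1)
            start += w
        scheme_kind = "syp1_six_zone"
    else:
        zone_rows = {
            "premeiotic": (1, rows_premeiotic),
            "transition": (rows_premeiotic + 1, rows_premeiotic + rows_tz),
            "pachytene": (rows_premeiotic + rows_tz + 1,
                          rows_premeiotic + rows_tz + rows_pachytene),
        }
        scheme_kind = "standard"

    total_rows = rows_premeiotic + n_meiotic
    placements: list[NucleusPlacement] = []
    for row in range(1, total_rows + 1):
        for k in range(nuclei_per_row):
            rng = np.random.default_rng([seed, row, k])
            zone = next(z for z, (a, b) in zone_rows.items() if a <= row <= b)
            meiotic = row > rows_premeiotic
            if scenario == "syp1":
                clustered = meiotic  # syp-1 TZ morphology persists
            else:
                clustered = zone == "transition"
            if not meiotic:
                pairs = [_premeiotic_pair(rng, p) for p in paints]
            else:
                zone_kind = "pachytene" if zone == "pachytene" else "transition"
                pairs = [_meiotic_pair(rng, p, scenario, zone_kind)
                         for p in paints]
            nuc = NucleusSpec(
                pairs=pairs,
                nucleus_id=f"{scenario}-r{row:02d}n{k}",
                nuclear_radius=nuclear_radius,
                clustered=clustered,
                row=row,
                zone_label=zone,
            )
            generate_nucleus(nuc, rng)
            placements.append(NucleusPlacement(row=row, nucleus=nuc))
    return GonadLayout(genotype=scenario, nuclei=placements,
                       zone_rows=zone_rows, scheme_kind=scheme_kind)
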