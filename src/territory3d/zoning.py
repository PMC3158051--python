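"""Gonad zone assignment and the category tables built from scored nuclei.

Zones along the distal-proximal axis are assigned from row indices (1-based,
counted from the distal tip):

* premeiotic — the first ``premeiotic_rows`` rows (10 by default; the
  proximity analysis instead uses the first 15 cell diameters, so the value
  is a parameter);
* transition zone — the maximal contiguous run of rows, after the premeiotic
  zone, in which at least half the nuclei have clustered chromatin and fewer
  than 90% show full chromosome-I alignment (a quantitative rendering of the
  visual definition: clustered distribution plus a mixture of chromosome-I
  alignment states);
* pachytene — a fixed-length window (15 rows by default) beginning
  ``pachytene_offset`` (5) rows from the proximal end of the transition zone;
* rows between/beyond those windows are labeled ``post_transition`` /
  ``proximal`` so that zone labels always partition the gonad.

For gonads without full alignment (syp-1), the meiotic region (N rows) is
instead divided into five scoring zones of widths (n, n, n, n, N - 4n) with
n = N/5 rounded to the nearest integer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ZoneScheme",
    "split_meiotic_zones",
    "assign_zones",
    "joint_alignment_matrix",
    "summarize_zone_metrics",
]

ALIGNMENT_STATES = ("unaligned", "partial", "full")


@dataclass(frozen=True)
class ZoneScheme:
    kind: str = "standard"  # or "syp1_six_zone"
    premeiotic_rows: int = 10
    pachytene_offset: int = 5
    pachytene_length: int = 15
    clustered_fraction_min: float = 0.5
    full_fraction_max: float = 0.9

    def __post_init__(self) -> None:
        if self.kind not in ("standard", "syp1_six_zone"):
            raise ValueError(f"unknown zone scheme {self.kind!r}")
        if self.premeiotic_rows < 1:
            raise ValueError("premeiotic_rows must be >= 1")
        if not 15 <= self.pachytene_length <= 20:
            raise ValueError("pachytene window length must be 15-20 rows")


def split_meiotic_zones(n_rows: int) -> tuple[int, int, int, int, int]:
    """Widths of the five syp-1 scoring zones for ``n_rows`` meiotic rows.

    ``n = round(n_rows / 5)`` (half away from zero); zones 2-5 get ``n`` rows
    each and zone 6 gets the remainder ``n_rows - 4n``.
    """
    if n_rows < 5:
        raise ValueError("need at least 5 meiotic rows to form five zones")
    n = int(np.floor(n_rows / 5.0 + 0.5))
    last = n_rows - 4 * n
    if last < 0:
        raise ValueError(f"degenerate gonad: N={n_rows} leaves a negative sixth zone")
    return (n, n, n, n, last)


def assign_zones(nuclei: pd.DataFrame, scheme: ZoneScheme | None = None) -> pd.DataFrame:
    """Assign a zone label to every nucleus.

    Parameters
    ----------
    nuclei:
        One row per nucleus with columns ``nucleus_id``, ``row`` (1-based),
        ``clustered`` (bool) and, for the standard scheme, ``chrI_alignment``
        in {"unaligned", "partial", "full"} for meiotic rows.

    Returns
    -------
    DataFrame
        ``nuclei`` with an added ``zone`` column; the attribute
        ``df.attrs["zone_rows"]`` maps zone label to (first, last) row; the
        transition zone span is empty (and logged via attrs) when no row
        meets the criteria.
    """
    scheme = scheme or ZoneScheme()
    df = nuclei.copy()
    rows = np.sort(df["row"].unique())
    if rows.min() != 1 or np.any(np.diff(rows) != 1):
        raise ValueError("row indices must be contiguous from 1")
    max_row = int(rows.max())
    pm_end = min(scheme.premeiotic_rows, max_row)

    if scheme.kind == "syp1_six_zone":
        n_meiotic = max_row - pm_end
        widths = split_meiotic_zones(n_meiotic)
        spans = {"premeiotic": (1, pm_end)}
        start = pm_end + 1
        for i, w in enumerate(widths, start=2):
            spans[f"zone{i}"] = (start, start + w - 1)
            start += w
    else:
        tz_span = _transition_span(df, scheme, pm_end, max_row)
        spans = {"premeiotic": (1, pm_end)}
        if tz_span is not None:
            tz_a, tz_b = tz_span
            spans["transition"] = (tz_a, tz_b)
            pa_a = tz_b + scheme.pachytene_offset
            pa_b = min(pa_a + scheme.pachytene_length - 1, max_row)
            if pa_a > tz_b + 1:
                spans["post_transition"] = (tz_b + 1, pa_a - 1)
            if pa_a <= max_row:
                spans["pachytene"] = (pa_a, pa_b)
            if pa_b < max_row:
                spans["proximal"] = (pa_b + 1, max_row)
        elif pm_end < max_row:
            spans["post_transition"] = (pm_end + 1, max_row)

    def zone_of(row: int) -> str:
        for z, (a, b) in spans.items():
            if a <= row <= b:
                return z
        raise AssertionError(f"row {row} escaped the zone partition")

    df["zone"] = df["row"].map(zone_of)
    df.attrs["zone_rows"] = spans
    return df


def _transition_span(df: pd.DataFrame, scheme: ZoneScheme, pm_end: int,
                     max_row: int) -> tuple[int, int] | None:
    """First maximal run of TZ-criteria rows after the premeiotic zone."""
    start = None
    end = None
    for r in range(pm_end + 1, max_row + 1):
        sub = df[df["row"] == r]
        clustered = float(sub["clustered"].mean())
        if "chrI_alignment" in sub:
            full = float((sub["chrI_alignment"] == "full").mean())
        else:
            full = 0.0
        ok = clustered >= scheme.clustered_fraction_min and full < scheme.full_fraction_max
        if ok and start is None:
            start = r
        if start is not None:
            if ok:
                end = r
            else:
                break
    if start is None:
        return None
    return (start, end)


def joint_alignment_matrix(states_a, states_b) -> pd.DataFrame:
    """3x3 count matrix over joint alignment states of two chromosomes.

    Rows index the first chromosome's state, columns the second's, in the
    order unaligned / partial / full; nuclei are counted once, so the cells
    sum to the number of nuclei.
    """
    a = list(states_a)
    b = list(states_b)
    if len(a) != len(b):
        raise ValueError("state lists must have equal length")
    for s in a + b:
        if s not in ALIGNMENT_STATES:
            raise ValueError(f"unknown alignment state {s!r}")
    mat = pd.DataFrame(0, index=list(ALIGNMENT_STATES),
                       columns=list(ALIGNMENT_STATES))
    for sa, sb in zip(a, b):
        mat.loc[sa, sb] += 1
    return mat


def summarize_zone_metrics(morphometry: pd.DataFrame,
                           pairs: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Per-zone/chromosome summary tables of the scored quantities.

    Parameters
    ----------
    morphometry:
        Per-territory records with columns ``zone``, ``chromosome``,
        ``segment_count``, ``slenderness``, ``highly_extended`` and
        ``nucleus_id``.
    pairs:
        Per-pair records with ``zone``, ``chromosome``, ``alignment_state``,
        ``nucleus_id``.

    Returns
    -------
    dict with keys
        ``segment_counts`` — mean ± SD of painted-segment counts;
        ``extended`` — % highly extended ± SEM (percentage points);
        ``alignment`` — % fully aligned nuclei;
        ``tz_strata`` — transition-zone nuclei stratified by chromosome-I
        full-alignment status (TZ-Full vs TZ-NF), mean segment counts per
        stratum.  Empty strata are absent rather than zero.
    """
    out: dict[str, pd.DataFrame] = {}

    g = morphometry.groupby(["zone", "chromosome"])["segment_count"]
    out["segment_counts"] = g.agg(mean="mean", sd="std", n="count").reset_index()

    def pct_sem(x):
        p = float(np.mean(x)) * 100.0
        n = len(x)
        sem = float(np.std(x, ddof=1) / np.sqrt(n)) * 100.0 if n > 1 else np.nan
        return pd.Series({"pct": p, "sem": sem, "n": n})

    out["extended"] = (
        morphometry.groupby(["zone", "chromosome"])["highly_extended"]
        .apply(pct_sem).unstack().reset_index()
    )

    al = pairs.copy()
    al["full"] = al["alignment_state"] == "full"
    out["alignment"] = (
        al.groupby(["zone", "chromosome"])["full"]
        .agg(pct=lambda x: 100.0 * np.mean(x), n="count").reset_index()
    )

    # stratify TZ nuclei by chromosome-I full alignment
    tz_pairs = pairs[(pairs["zone"] == "transition") & (pairs["chromosome"] == "I")]
    status = tz_pairs.set_index("nucleus_id")["alignment_state"] == "full"
    tz_morpho = morphometry[morphometry["zone"] == "transition"].copy()
    tz_morpho = tz_morpho[tz_morpho["nucleus_id"].isin(status.index)]
    if len(tz_morpho):
        tz_morpho["stratum"] = np.where(
            tz_morpho["nucleus_id"].map(status), "TZ-Full", "TZ-NF")
        out["tz_strata"] = (
            tz_morpho.groupby(["stratum", "chromosome"])["segment_count"]
            .agg(mean="mean", sd="std", n="count").reset_index()
        )
    else:
        out["tz_strata"] = pd.DataFrame(
            columns=["stratum", "chromosome", "mean", "sd", "n"])
    return out
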