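"""Chromosome paint schemes.

A paint scheme assigns fluorophore channels to intervals of the normalized
chromosome coordinate, which runs from 0 at the pairing-center (PC) end to 1
at the non-PC end.  Intervals assigned to the *same* channel must not overlap;
intervals on different channels may overlap, which is how double-labeled
chromosome ends (used to orient a territory when only two dyes are available)
are expressed.  Coordinates not covered by any interval are unpainted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["PaintSegment", "PaintScheme", "two_color_scheme", "three_color_scheme"]


@dataclass(frozen=True)
class PaintSegment:
    """One painted interval ``[start, end]`` of chromosome coordinate."""

    start: float
    end: float
    channel: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.start < self.end <= 1.0):
            raise ValueError(f"invalid paint interval [{self.start}, {self.end}]")
        if self.channel < 0:
            raise ValueError("channel index must be non-negative")


@dataclass(frozen=True)
class PaintScheme:
    """Fluorophore assignment along one chromosome.

    Parameters
    ----------
    chromosome_id:
        Label, e.g. ``"I"`` or ``"X"``.
    segments:
        Painted intervals.  Sorted on construction.
    pc_end:
        Which chromosome end carries the pairing center; ``"left"`` maps the
        PC to coordinate 0, ``"right"`` to coordinate 1.
    """

    chromosome_id: str
    segments: tuple[PaintSegment, ...]
    pc_end: str = "left"

    def __post_init__(self) -> None:
        if self.pc_end not in ("left", "right"):
            raise ValueError("pc_end must be 'left' or 'right'")
        if not self.segments:
            raise ValueError("a paint scheme needs at least one painted segment")
        segs = tuple(sorted(self.segments, key=lambda s: (s.start, s.channel)))
        object.__setattr__(self, "segments", segs)
        by_channel: dict[int, list[PaintSegment]] = {}
        for s in segs:
            by_channel.setdefault(s.channel, []).append(s)
        for ch, ss in by_channel.items():
            for a, b in zip(ss, ss[1:]):
                if b.start < a.end:
                    raise ValueError(
                        f"overlapping intervals on channel {ch}: "
                        f"[{a.start},{a.end}] and [{b.start},{b.end}]"
                    )

    @property
    def channels(self) -> tuple[int, ...]:
        """Sorted distinct channels used by this scheme."""
        return tuple(sorted({s.channel for s in self.segments}))

    @property
    def pc_coordinate(self) -> float:
        return 0.0 if self.pc_end == "left" else 1.0

    def channel_weights(self, coords: np.ndarray) -> np.ndarray:
        """Indicator matrix ``(n_coords, n_channels_total)``.

        ``weights[i, c] = 1`` iff coordinate ``coords[i]`` lies in an interval
        painted with channel ``c``.  Columns run over ``0..max(channel)``.
        """
        coords = np.asarray(coords, dtype=float)
        n_ch = max(self.channels) + 1
        w = np.zeros((coords.size, n_ch))
        for s in self.segments:
            inside = (coords >= s.start) & (coords <= s.end)
            w[inside, s.channel] = 1.0
        return w

    def dominant_segment(self, coord: float) -> int | None:
        """Index (into ``segments``) of the first interval containing ``coord``."""
        for i, s in enumerate(self.segments):
            if s.start <= coord <= s.end:
                return i
        return None


def two_color_scheme(chromosome_id: str, channels: tuple[int, int] = (0, 1),
                     pc_end: str = "left") -> PaintScheme:
    """Half/half two-dye paint (left half one dye, right half the other)."""
    a, b = channels
    return PaintScheme(
        chromosome_id=chromosome_id,
        segments=(PaintSegment(0.0, 0.5, a), PaintSegment(0.5, 1.0, b)),
        pc_end=pc_end,
    )


def three_color_scheme(chromosome_id: str, channels: tuple[int, int, int] = (0, 1, 2),
                       pc_end: str = "left",
                       double_label_pc: bool = False) -> PaintScheme:
    """Thirds painted with three dyes; optionally double-label the PC end."""
    a, b, c = channels
    segs = [
        PaintSegment(0.0, 1.0 / 3.0, a),
        PaintSegment(1.0 / 3.0, 2.0 / 3.0, b),
        PaintSegment(2.0 / 3.0, 1.0, c),
    ]
    if double_label_pc:
        if pc_end == "left":
            segs.append(PaintSegment(0.0, 0.1, c))
        else:
            segs.append(PaintSegment(0.9, 1.0, a))
    return PaintScheme(chromosome_id=chromosome_id, segments=tuple(segs), pc_end=pc_end)
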