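"""Affection fill scales: colours for binary and quantitative traits.

A binary affection gets the classic two-colour fill (white = unaffected,
dark = affected).  A quantitative affection gets a colour gradient over its
observed range; when a clinical threshold is given, the range is split
there into an "unaffected" and an "affected" sub-gradient so the drawing
distinguishes the two groups while still showing magnitude within each.
Missing values always get a dedicated colour.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

__all__ = ["FillScale", "generate_colors",
           "BORDER_AVAILABLE", "BORDER_UNAVAILABLE"]

MISSING_COLOR = "#aaaaaa"
BINARY_UNAFFECTED = "#ffffff"
BINARY_AFFECTED = "#333333"
#: default gradient endpoints (lightness strictly decreasing with value)
UNAFFECTED_ENDPOINTS = ("#ffffff", "#a8c4e0")
AFFECTED_ENDPOINTS = ("#f2b6b6", "#7a0c0c")
SINGLE_ENDPOINTS = ("#ffffff", "#7a0c0c")

#: symbol border colours keyed on the availability flag
BORDER_AVAILABLE = "#000000"
BORDER_UNAVAILABLE = "#777777"


def _hex_to_rgb(color: str) -> tuple:
    c = color.lstrip("#")
    return tuple(int(c[i:i + 2], 16) for i in (0, 2, 4))


def _rgb_to_hex(rgb: tuple) -> str:
    return "#%02x%02x%02x" % tuple(int(round(v)) for v in rgb)


def _interpolate(start: str, end: str, n: int) -> list:
    """n colours linearly interpolated in RGB from start to end inclusive."""
    a, b = _hex_to_rgb(start), _hex_to_rgb(end)
    if n == 1:
        return [_rgb_to_hex(b)]
    return [_rgb_to_hex(tuple(a[k] + (b[k] - a[k]) * i / (n - 1)
                              for k in range(3)))
            for i in range(n)]


@dataclass
class FillScale:
    """Total, deterministic mapping from affection values to fill colours.

    ``mode`` is "binary" or "continuous".  Continuous scales hold
    half-open-on-the-right intervals (the last interval of each gradient is
    closed); the threshold value itself belongs to the affected side.
    """

    affection_index: int
    mode: str
    intervals: list = field(default_factory=list)  # [(lo, hi, colour), ...]
    binary_colors: dict = field(default_factory=dict)
    missing_color: str = MISSING_COLOR
    threshold: Optional[float] = None
    labels: list = field(default_factory=list)

    def color_for(self, value: Optional[float]) -> str:
        if value is None:
            return self.missing_color
        if self.mode == "binary":
            try:
                return self.binary_colors[float(value)]
            except KeyError:
                raise ValueError(f"value {value!r} outside binary scale")
        for i, (lo, hi, color) in enumerate(self.intervals):
            last = i == len(self.intervals) - 1 or \
                self.intervals[i + 1][0] > hi  # closing interval of a gradient
            if lo <= value < hi or (last and value == hi):
                return color
        raise ValueError(f"value {value!r} outside scale range")

    def to_dict(self) -> dict:
        return {
            "affection_index": self.affection_index,
            "mode": self.mode,
            "threshold": self.threshold,
            "missing_color": self.missing_color,
            "binary_colors": {str(k): v for k, v in self.binary_colors.items()},
            "intervals": [list(iv) for iv in self.intervals],
            "labels": list(self.labels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FillScale":
        return cls(
            affection_index=d["affection_index"], mode=d["mode"],
            intervals=[tuple(iv) for iv in d.get("intervals", [])],
            binary_colors={float(k): v
                           for k, v in d.get("binary_colors", {}).items()},
            missing_color=d.get("missing_color", MISSING_COLOR),
            threshold=d.get("threshold"),
            labels=list(d.get("labels", [])),
        )


def generate_colors(values: Sequence[Optional[float]], mode: str = "auto",
                    threshold: Optional[float] = None,
                    endpoints_affected: tuple = AFFECTED_ENDPOINTS,
                    endpoints_unaffected: tuple = UNAFFECTED_ENDPOINTS,
                    n_breaks: int = 5,
                    affection_index: int = 0) -> FillScale:
    """Build a :class:`FillScale` for one affection column.

    ``mode`` "auto" treats a column as binary iff its non-missing values
    are a subset of {0, 1}.  Continuous scales split the observed range at
    ``threshold`` (values >= threshold count as affected) into two linear
    RGB gradients of ``n_breaks`` steps each; without a threshold a single
    gradient covers the whole range.  A single distinct value yields a
    degenerate one-interval scale.  An all-missing column is an error.
    """
    observed = [float(v) for v in values if v is not None]
    if not observed:
        raise ValueError("cannot build a fill scale from an all-missing column")
    if mode == "auto":
        mode = "binary" if set(observed) <= {0.0, 1.0} else "continuous"
    if mode == "binary":
        bad = sorted(set(observed) - {0.0, 1.0})
        if bad:
            raise ValueError(f"binary scale given non-binary values: {bad}")
        return FillScale(
            affection_index=affection_index, mode="binary",
            binary_colors={0.0: BINARY_UNAFFECTED, 1.0: BINARY_AFFECTED},
            labels=["unaffected", "affected"])
    if mode != "continuous":
        raise ValueError(f"unknown scale mode {mode!r}")
    if n_breaks < 1:
        raise ValueError("n_breaks must be >= 1")

    lo, hi = min(observed), max(observed)
    intervals: list = []
    labels: list = []

    def add_gradient(a: float, b: float, endpoints: tuple, tag: str):
        if a == b:
            colors = _interpolate(*endpoints, 1)
            intervals.append((a, b, colors[0]))
            labels.append(f"{tag} [{a:g}]")
            return
        colors = _interpolate(*endpoints, n_breaks)
        step = (b - a) / n_breaks
        # exact endpoints, so boundary values are never left uncovered
        edges = [a + i * step for i in range(n_breaks)] + [b]
        for i, color in enumerate(colors):
            intervals.append((edges[i], edges[i + 1], color))
            labels.append(f"{tag} [{edges[i]:g}, {edges[i + 1]:g})")

    if threshold is None or not (lo < threshold <= hi):
        add_gradient(lo, hi, SINGLE_ENDPOINTS if threshold is None
                     else AFFECTED_ENDPOINTS if lo >= threshold
                     else UNAFFECTED_ENDPOINTS, "value")
        used_threshold = None
    else:
        add_gradient(lo, threshold, endpoints_unaffected, "unaffected")
        add_gradient(threshold, hi, endpoints_affected, "affected")
        used_threshold = threshold
    return FillScale(affection_index=affection_index, mode="continuous",
                     intervals=intervals, threshold=used_threshold,
                     labels=labels)
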