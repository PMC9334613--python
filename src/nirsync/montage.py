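"""Optode montage construction for dyadic fNIRS over bilateral DLPFC and TPJ.

The standard layout places four 2x2 probe sets (two sources + two detectors
each) over the left/right dorsolateral prefrontal cortex (surrounding the
10-20 positions F3 and F4) and the left/right temporo-parietal junction
(neighboring CP5 and CP6), yielding 16 measurement channels with a uniform
3 cm source-detector separation, four channels per region of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ROIS = ("lDLPFC", "rDLPFC", "lTPJ", "rTPJ")

#: 10-20 anchor label per ROI.
ROI_ANCHORS = {"lDLPFC": "F3", "rDLPFC": "F4", "lTPJ": "CP5", "rTPJ": "CP6"}

# Idealized flattened-scalp anchor coordinates in cm (x: left-negative,
# y: anterior-positive).  Only relative geometry matters downstream.
_ANCHOR_XY = {"F3": (-4.5, 6.0), "F4": (4.5, 6.0), "CP5": (-6.5, -4.0), "CP6": (6.5, -4.0)}


@dataclass(frozen=True)
class Optode:
    label: str
    x: float
    y: float


@dataclass(frozen=True)
class Channel:
    index: int          # 1-based channel number
    source: str
    detector: str
    distance_cm: float
    roi: str


@dataclass
class Montage:
    """A set of sources, detectors and source-detector channels with ROI labels."""

    sources: list[Optode]
    detectors: list[Optode]
    channels: list[Channel]
    anchor_labels: dict[str, str] = field(default_factory=lambda: dict(ROI_ANCHORS))

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def roi_map(self) -> dict[int, str]:
        return {ch.index: ch.roi for ch in self.channels}

    def channels_in_roi(self, roi: str) -> list[Channel]:
        return [ch for ch in self.channels if ch.roi == roi]

    def validate(self) -> None:
        idx = [ch.index for ch in self.channels]
        if idx != list(range(1, len(idx) + 1)):
            raise ValueError("channel indices must be consecutive from 1")
        for ch in self.channels:
            if ch.roi not in ROIS:
                raise ValueError(f"unknown ROI {ch.roi!r} on channel {ch.index}")


class LayoutError(ValueError):
    """Unknown montage layout identifier."""


def _probe_set(roi: str, tag: str) -> tuple[list[Optode], list[Optode], list[tuple[str, str]]]:
    """One 2x2 probe set: sources on one diagonal, detectors on the other.

    With square side 3 cm every source-detector pair along an edge is a
    3 cm channel; the two diagonal pairings (3*sqrt(2) cm) are not used.
    """
    ax, ay = _ANCHOR_XY[ROI_ANCHORS[roi]]
    a = 3.0
    srcs = [Optode(f"S{tag}1", ax - a / 2, ay - a / 2), Optode(f"S{tag}2", ax + a / 2, ay + a / 2)]
    dets = [Optode(f"D{tag}1", ax + a / 2, ay - a / 2), Optode(f"D{tag}2", ax - a / 2, ay + a / 2)]
    pairs = [(s.label, d.label) for s in srcs for d in dets]
    return srcs, dets, pairs


def build_montage(layout_spec: str = "rps-16") -> Montage:
    """Build a named montage layout.

    Parameters
    ----------
    layout_spec : str
        ``"rps-16"`` — the full four-probe-set layout (16 channels, 4 per
        ROI).  ``"mini-8"`` — a reduced test layout with one source and two
        detectors per ROI (8 channels, 2 per ROI).  ``"single-1"`` — one
        source + one detector (1 channel), for minimal unit tests.

    Raises
    ------
    LayoutError
        If ``layout_spec`` is not a known identifier.
    """
    if layout_spec == "rps-16":
        sources: list[Optode] = []
        detectors: list[Optode] = []
        channels: list[Channel] = []
        k = 1
        for i, roi in enumerate(ROIS):
            srcs, dets, pairs = _probe_set(roi, str(i + 1))
            sources += srcs
            detectors += dets
            for s, d in pairs:
                channels.append(Channel(k, s, d, 3.0, roi))
                k += 1
        m = Montage(sources, detectors, channels)
    elif layout_spec == "mini-8":
        sources, detectors, channels = [], [], []
        k = 1
        for i, roi in enumerate(ROIS):
            ax, ay = _ANCHOR_XY[ROI_ANCHORS[roi]]
            s = Optode(f"S{i + 1}1", ax, ay)
            d1 = Optode(f"D{i + 1}1", ax - 3.0, ay)
            d2 = Optode(f"D{i + 1}2", ax + 3.0, ay)
            sources.append(s)
            detectors += [d1, d2]
            channels.append(Channel(k, s.label, d1.label, 3.0, roi))
            channels.append(Channel(k + 1, s.label, d2.label, 3.0, roi))
            k += 2
        m = Montage(sources, detectors, channels)
    elif layout_spec == "single-1":
        s = Optode("S11", 0.0, 0.0)
        d = Optode("D11", 3.0, 0.0)
        m = Montage([s], [d], [Channel(1, s.label, d.label, 3.0, "lDLPFC")])
    else:
        raise LayoutError(f"unknown montage layout {layout_spec!r}")
    m.validate()
    return m


def optode_positions(montage: Montage) -> dict[str, np.ndarray]:
    """Positions as arrays for serialization (sources then detectors)."""
    return {
        "source_pos": np.array([[o.x, o.y, 0.0] for o in montage.sources]),
        "detector_pos": np.array([[o.x, o.y, 0.0] for o in montage.detectors]),
        "source_labels": [o.label for o in montage.sources],
        "detector_labels": [o.label for o in montage.detectors],
    }
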