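"""Frame-subtraction spatial activity maps.

A frame-subtraction map is the average of 10 frames during the odor
stimulation period minus the average of the 10 frames immediately preceding
odor onset, computed on a trial-averaged movie.  Activated regions are
positive, suppressed regions negative.  By default the stimulation window
starts 25 frames (1 s) after onset, near the indicator response peak; the
offset is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from odorbulb.protocol import MovieStack, StimulusProtocol

__all__ = ["ActivityMap", "frame_subtraction", "scale_maps"]


@dataclass
class ActivityMap:
    """H x W signed intensity-difference image with window metadata."""

    data: np.ndarray
    stim_window: tuple[int, int]
    baseline_window: tuple[int, int]
    label: str = ""
    scaling: str = "none"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("activity map must be 2-D")


def frame_subtraction(
    movie: MovieStack,
    protocol: StimulusProtocol,
    stim_window_offset: int = 25,
    window_frames: int = 10,
) -> ActivityMap:
    """Stimulation-minus-baseline difference image of a trial-averaged movie.

    ``map = mean(frames [onset + offset, onset + offset + window)) -
    mean(frames [onset - window, onset))``.
    """
    onset = protocol.onset_frame
    s0 = onset + stim_window_offset
    s1 = s0 + window_frames
    b0 = onset - window_frames
    b1 = onset
    T = movie.n_frames
    if b0 < 0 or s1 > T:
        raise ValueError(
            f"frame-subtraction windows [{b0},{b1}) / [{s0},{s1}) out of range for {T} frames"
        )
    data = movie.data.astype(float)
    diff = data[s0:s1].mean(axis=0) - data[b0:b1].mean(axis=0)
    return ActivityMap(
        data=diff,
        stim_window=(s0, s1),
        baseline_window=(b0, b1),
        label=movie.label,
    )


def scale_maps(maps: list[ActivityMap], mode: str = "shared_max") -> list[ActivityMap]:
    """Scale maps to [-1, 1] by their own or a shared absolute maximum.

    ``shared_max`` divides every map by the largest |value| across all maps
    (preserving relative intensity across stimuli within a subject);
    ``per_stimulus_max`` scales each map to its own maximum.  All-zero maps
    are left untouched.
    """
    if not maps:
        raise ValueError("at least one map is required")
    if mode not in ("shared_max", "per_stimulus_max"):
        raise ValueError(f"unknown scaling mode {mode!r}")
    if mode == "shared_max":
        global_max = max(np.abs(m.data).max() for m in maps)
        scales = [global_max] * len(maps)
    else:
        scales = [np.abs(m.data).max() for m in maps]
    out = []
    for m, s in zip(maps, scales):
        scaled = m.data / s if s > 0 else m.data.copy()
        out.append(
            ActivityMap(
                data=scaled,
                stim_window=m.stim_window,
                baseline_window=m.baseline_window,
                label=m.label,
                scaling=mode,
            )
        )
    return out
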