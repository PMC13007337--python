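"""ROI trace extraction and conversion to trial-averaged, filtered ΔF/F.

The analysis trace for every downstream quantity is built in a fixed order:
extract per-trial ROI traces, average the retained trials, divide by the mean
of the 10 frames immediately preceding stimulus onset (ΔF/F), then low-pass
filter at 5 Hz with a zero-phase 4th-order Butterworth filter.

ΔF/F convention: ``dff = F / F0 - 1`` so baseline sits at 0.  All response
magnitudes and z-scores downstream are differences or SD ratios, so they are
invariant to this -1 shift relative to the pure-ratio convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import signal

from odorbulb.protocol import MovieStack, ROISet, StimulusProtocol

__all__ = ["TraceMatrix", "extract_traces", "average_trials", "compute_dff", "lowpass"]

_KINDS = ("raw", "dff", "dff_filtered")


@dataclass
class TraceMatrix:
    """cells x frames fluorescence traces with processing-stage bookkeeping.

    ``kind`` advances only raw → dff → dff_filtered; ``trial`` is the source
    trial index or ``"mean"`` for trial-averaged traces.
    """

    data: np.ndarray
    cell_ids: list
    kind: str
    protocol: StimulusProtocol
    trial: int | str = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("trace data must be 2-D (cells x frames)")
        if self.kind not in _KINDS:
            raise ValueError(f"kind must be one of {_KINDS}, got {self.kind!r}")
        if self.data.shape[0] != len(self.cell_ids):
            raise ValueError("cell_ids length does not match trace rows")
        if self.data.shape[1] != self.protocol.n_frames:
            raise ValueError(
                f"trace length {self.data.shape[1]} does not match protocol "
                f"trial length {self.protocol.n_frames}"
            )

    @property
    def n_cells(self) -> int:
        return self.data.shape[0]


def _disk_indices(cx: float, cy: float, radius: float, H: int, W: int, cell_id) -> np.ndarray:
    """Flat pixel indices of the disk of given radius around (cx, cy)."""
    x0 = int(np.floor(cx - radius))
    x1 = int(np.ceil(cx + radius)) + 1
    y0 = int(np.floor(cy - radius))
    y1 = int(np.ceil(cy + radius)) + 1
    xs = np.arange(max(x0, 0), min(x1, W))
    ys = np.arange(max(y0, 0), min(y1, H))
    if xs.size == 0 or ys.size == 0:
        raise ValueError(f"ROI for cell {cell_id!r} lies fully outside the frame")
    gx, gy = np.meshgrid(xs, ys)
    inside = (gx - cx) ** 2 + (gy - cy) ** 2 <= radius**2
    if not inside.any():
        raise ValueError(f"ROI for cell {cell_id!r} covers no pixels inside the frame")
    return (gy[inside] * W + gx[inside]).ravel()


def extract_traces(
    movie: MovieStack,
    rois: ROISet,
    trial: int | None = None,
    protocol: StimulusProtocol | None = None,
) -> TraceMatrix:
    """Mean intensity inside each circular ROI, frame by frame.

    ``trial`` selects the per-trial (dx, dy) ROI offsets compensating subject
    drift; centers must remain inside the frame after offsetting.  When no
    protocol is given, the default timing grid is assumed and must match the
    movie length.
    """
    T, H, W = movie.shape
    protocol = protocol or StimulusProtocol(frame_rate_hz=movie.frame_rate_hz)
    if protocol.n_frames != T:
        raise ValueError(
            f"movie has {T} frames but protocol defines {protocol.n_frames}-frame trials"
        )
    centers = rois.centers(trial=trial)
    bad = [
        cid
        for cid, (cx, cy) in zip(rois.cell_ids, centers)
        if not (0 <= cx < W and 0 <= cy < H)
    ]
    if bad:
        raise ValueError(f"ROI centers outside frame after offsets: {bad}")

    flat = movie.data.reshape(T, H * W)
    radii = rois.rois["radius"].to_numpy(dtype=float)
    out = np.empty((len(rois), T))
    for i, (cid, (cx, cy), r) in enumerate(zip(rois.cell_ids, centers, radii)):
        idx = _disk_indices(cx, cy, r, H, W, cid)
        out[i] = flat[:, idx].mean(axis=1)

    return TraceMatrix(
        data=out,
        cell_ids=list(rois.cell_ids),
        kind="raw",
        protocol=protocol,
        trial=trial if trial is not None else 0,
    )


def average_trials(
    trials: Sequence[TraceMatrix], discard: Sequence[int] = ()
) -> TraceMatrix:
    """Elementwise mean of retained trials.

    ``discard`` lists positions in ``trials`` to drop (e.g. trials with gross
    movement artifacts, flagged by the caller); at least one trial must remain.
    """
    if not trials:
        raise ValueError("no trials given")
    keep = [tm for k, tm in enumerate(trials) if k not in set(discard)]
    if not keep:
        raise ValueError("all trials discarded; nothing to average")
    ref = keep[0]
    for tm in keep[1:]:
        if tm.data.shape != ref.data.shape or tm.cell_ids != ref.cell_ids:
            raise ValueError("trials must share shape and cell identities")
        if tm.kind != ref.kind:
            raise ValueError("trials must share processing kind")
    mean = np.mean([tm.data for tm in keep], axis=0)
    return TraceMatrix(
        data=mean, cell_ids=list(ref.cell_ids), kind=ref.kind, protocol=ref.protocol, trial="mean"
    )


def compute_dff(tm: TraceMatrix, protocol: StimulusProtocol | None = None, f0_frames: int = 10) -> TraceMatrix:
    """Convert raw traces to ΔF/F against the pre-onset baseline.

    Per cell, ``F0`` is the mean of the ``f0_frames`` frames immediately
    preceding stimulus onset; the whole trace is divided by ``F0`` and shifted
    by -1 so the F0 window has mean 0 by construction.
    """
    if tm.kind != "raw":
        raise ValueError(f"compute_dff expects raw traces, got kind={tm.kind!r}")
    protocol = protocol or tm.protocol
    onset = protocol.onset_frame
    if onset - f0_frames < 0:
        raise ValueError(f"baseline window [{onset - f0_frames}, {onset}) is out of range")
    f0 = tm.data[:, onset - f0_frames : onset].mean(axis=1)
    bad = np.asarray(tm.cell_ids, dtype=object)[f0 <= 0]
    if bad.size:
        raise ValueError(f"nonpositive baseline F0 for cells: {bad.tolist()}")
    dff = tm.data / f0[:, None] - 1.0
    return TraceMatrix(
        data=dff, cell_ids=list(tm.cell_ids), kind="dff", protocol=protocol, trial=tm.trial
    )


def lowpass(tm: TraceMatrix, cutoff_hz: float = 5.0, order: int = 4) -> TraceMatrix:
    """Zero-phase Butterworth low-pass filter of ΔF/F traces.

    Forward-backward application (``sosfiltfilt``) keeps transient peaks in
    place (no temporal lag) and has unit DC gain.  The cutoff must lie below
    the Nyquist frequency.
    """
    if tm.kind != "dff":
        raise ValueError(f"lowpass expects dff traces, got kind={tm.kind!r}")
    nyquist = tm.protocol.frame_rate_hz / 2.0
    if cutoff_hz >= nyquist:
        raise ValueError(f"cutoff {cutoff_hz} Hz is not below Nyquist ({nyquist} Hz)")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=tm.protocol.frame_rate_hz, output="sos")
    filtered = signal.sosfiltfilt(sos, tm.data, axis=1)
    return TraceMatrix(
        data=filtered,
        cell_ids=list(tm.cell_ids),
        kind="dff_filtered",
        protocol=tm.protocol,
        trial=tm.trial,
    )
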