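"""End-to-end analysis drivers tying movies to response tables.

These helpers implement the canonical processing order: per-trial ROI
extraction → trial averaging → ΔF/F → 5 Hz zero-phase low-pass → response
quantification.  Movies are processed one (stimulus, trial) at a time so a
full multi-stimulus session never needs to reside in memory at once.
"""

from __future__ import annotations

import warnings
from typing import Callable, Sequence

from odorbulb.protocol import MovieStack, ROISet, StimulusProtocol
from odorbulb.responses import ResponseTable, build_response_table
from odorbulb.simulate import ClippingWarning, GroundTruth, render_ideal_traces, render_movie
from odorbulb.traces import TraceMatrix, average_trials, compute_dff, extract_traces, lowpass

__all__ = ["analysis_traces", "analyze_movies", "analyze_simulation"]


def analysis_traces(
    trials: Sequence[TraceMatrix],
    protocol: StimulusProtocol,
    discard: Sequence[int] = (),
    lowpass_hz: float = 5.0,
) -> TraceMatrix:
    """Trial-averaged, filtered ΔF/F analysis trace from raw per-trial traces."""
    mean = average_trials(trials, discard=discard)
    return lowpass(compute_dff(mean, protocol), cutoff_hz=lowpass_hz)


def analyze_movies(
    movie_source: Callable[[str, int], MovieStack],
    rois: ROISet,
    protocol: StimulusProtocol,
    discard: dict[str, Sequence[int]] | None = None,
    lowpass_hz: float = 5.0,
) -> ResponseTable:
    """Run the full single-cell analysis over one subject's movie set.

    ``movie_source(stimulus, trial)`` returns the trial movie (loaded from
    disk or rendered on the fly).  ``discard`` optionally lists trial indices
    to drop per stimulus (caller-flagged movement artifacts).
    """
    discard = discard or {}
    per_stim: dict[str, TraceMatrix] = {}
    for stim in protocol.stimulus_labels:
        trials = []
        for trial in range(protocol.n_trials_per_stimulus):
            movie = movie_source(stim, trial)
            trials.append(extract_traces(movie, rois, trial=trial, protocol=protocol))
        per_stim[stim] = analysis_traces(
            trials, protocol, discard=discard.get(stim, ()), lowpass_hz=lowpass_hz
        )
    return build_response_table(per_stim, protocol)


def analyze_simulation(
    gt: GroundTruth, protocol: StimulusProtocol | None = None, lowpass_hz: float = 5.0
) -> ResponseTable:
    """Simulate movies from ground truth and run the full analysis on them.

    Renders each (stimulus, trial) movie on the fly and analyzes it with the
    exact pipeline used for recorded data; ROI centers and per-trial drift
    offsets come from the ground truth, mirroring the manual ROI bookkeeping
    done on real recordings.
    """
    protocol = protocol or gt.protocol
    ideal = render_ideal_traces(gt, protocol)
    rois = gt.to_roiset(include_drift_offsets=True)

    def source(stim: str, trial: int) -> MovieStack:
        # background-pixel clipping is expected for noisy renders on the
        # dark default background; it never touches ROI pixels
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ClippingWarning)
            return render_movie(gt, ideal, stim, trial, protocol)

    return analyze_movies(source, rois, protocol, lowpass_hz=lowpass_hz)
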