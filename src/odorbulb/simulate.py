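"""Synthetic nuclear-GCaMP movie generator with per-cell ground truth.

The simulator emulates widefield imaging of nuclear-localized GCaMP6s somata
in the larval olfactory bulb: discrete round somata on a dark background,
odor-locked fluorescence transients with single-compartment indicator
kinetics, additive sensor noise, optional photobleaching, and slow rigid
XY drift between trials.  Every realized quantity is a deterministic
function of the ground-truth seed, so each downstream stage can be tested
against planted values.

Tuning structure: each cell has one preferred stimulus carrying its largest
(signed) response amplitude, plus weaker off-stimulus responses.  "Selective"
cells respond mostly to their preferred stimulus; "broad" cells carry
sizeable off-stimulus amplitudes.  Suppressed (negative-going) responses are
modeled as negative amplitudes on the positive baseline.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from odorbulb.protocol import MovieStack, ROISet, StimulusProtocol

__all__ = [
    "TuningConfig",
    "GroundTruth",
    "ClippingWarning",
    "sample_ground_truth",
    "render_ideal_traces",
    "render_movie",
]


class ClippingWarning(UserWarning):
    """More than 1% of rendered pixels clipped at zero intensity.

    With the default dark (zero-count) background and additive Gaussian
    sensor noise, roughly half of the pure-background pixels fall below zero
    and are clipped; this distorts the noise distribution only at background
    pixels, never inside the bright somata the ROIs cover.  Callers that
    consider this expected (any noisy render on a dark background) may filter
    this category.
    """


@dataclass(frozen=True)
class TuningConfig:
    """Distributions governing per-cell tuning, geometry and movie noise.

    Amplitudes are peak ΔF/F values.  ``preferred_amp_range`` bounds the
    preferred-stimulus amplitude; off-stimulus amplitudes are drawn as a
    fraction of the preferred amplitude (``off_rel_range_*`` per class), with
    probability ``p_suppressed`` of being sign-flipped into a suppression.
    ``noise_sd`` is the additive Gaussian sensor noise in camera counts;
    with the default soma brightness (``f0_range``) it puts the peak
    signal-to-noise ratio of a typical preferred response well above 10.
    """

    p_selective: float = 0.7
    preferred_amp_range: tuple[float, float] = (0.3, 0.8)
    off_rel_range_selective: tuple[float, float] = (0.0, 0.2)
    off_rel_range_broad: tuple[float, float] = (0.3, 0.9)
    p_suppressed: float = 0.1
    radius_px: float = 3.0
    f0_range: tuple[float, float] = (800.0, 1200.0)
    rise_tau_s: float = 0.2
    decay_tau_s: float = 2.0
    background: float = 0.0
    noise_sd: float = 20.0
    bleach_tau_s: float | None = None
    drift_max_px: int = 1
    # somata centers at least ~5 sigma apart: cross-soma ROI contamination < 1%
    min_center_distance_px: float = 8.0
    frame_shape: tuple[int, int] = (256, 256)


@dataclass
class GroundTruth:
    """Planted per-cell tuning plus movie-level nuisance parameters.

    ``cells`` columns: cell_id, x, y, radius, f0, rise_tau_s, decay_tau_s,
    preferred_stimulus.  ``amplitudes`` is cells x stimuli (signed peak ΔF/F).
    ``drift`` is an (n_trials, 2) integer array of per-trial (dx, dy) shifts
    applied rigidly to the whole frame content.
    """

    cells: pd.DataFrame
    amplitudes: pd.DataFrame
    protocol: StimulusProtocol
    noise_sd: float
    background: float
    bleach_tau_s: float | None
    drift: np.ndarray
    seed: int
    frame_shape: tuple[int, int] = (256, 256)

    def __post_init__(self) -> None:
        if (self.cells["rise_tau_s"] <= 0).any():
            raise ValueError("rise_tau_s must be > 0")
        if (self.cells["decay_tau_s"] <= self.cells["rise_tau_s"]).any():
            raise ValueError("decay_tau_s must exceed rise_tau_s")
        if not np.isfinite(self.amplitudes.to_numpy()).all():
            raise ValueError("amplitudes must be finite")
        amps = self.amplitudes.to_numpy()
        cols = list(self.amplitudes.columns)
        pref_idx = [cols.index(p) for p in self.cells["preferred_stimulus"]]
        pref_amp = amps[np.arange(len(amps)), pref_idx]
        if not np.all(pref_amp >= amps.max(axis=1)):
            raise ValueError("preferred_stimulus must attain the maximum signed amplitude")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_roiset(self, include_drift_offsets: bool = True) -> ROISet:
        """True-center ROIs; offsets mirror the planted per-trial drift."""
        rois = self.cells[["cell_id", "x", "y", "radius"]].copy()
        offsets = None
        if include_drift_offsets and np.any(self.drift):
            rows = []
            for trial, (dx, dy) in enumerate(self.drift):
                for cid in self.cells["cell_id"]:
                    rows.append({"cell_id": cid, "trial": trial, "dx": dx, "dy": dy})
            offsets = pd.DataFrame(rows)
        return ROISet(rois=rois, offsets=offsets)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.cells.to_csv(directory / "ground_truth_cells.csv", index=False)
        self.amplitudes.to_csv(directory / "ground_truth_amplitudes.csv")
        meta = {
            "noise_sd": self.noise_sd,
            "background": self.background,
            "bleach_tau_s": self.bleach_tau_s,
            "drift": self.drift.tolist(),
            "seed": self.seed,
        }
        (directory / "ground_truth_meta.json").write_text(json.dumps(meta, indent=2))


def _place_centers(
    n_cells: int,
    frame_shape: tuple[int, int],
    margin: float,
    min_dist: float,
    rng: np.random.Generator,
    max_tries: int = 200000,
) -> np.ndarray:
    """Dart-throwing placement with a minimum center-to-center distance."""
    H, W = frame_shape
    lo_x, hi_x = margin, W - 1 - margin
    lo_y, hi_y = margin, H - 1 - margin
    if hi_x <= lo_x or hi_y <= lo_y:
        raise ValueError("frame too small for the requested ROI margin")
    centers: list[tuple[float, float]] = []
    placed = np.empty((0, 2))
    tries = 0
    while len(centers) < n_cells:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not place {n_cells} cells with min distance {min_dist:.1f}px "
                f"in a {W}x{H} frame (density infeasible)"
            )
        x = rng.uniform(lo_x, hi_x)
        y = rng.uniform(lo_y, hi_y)
        if len(centers):
            d2 = (placed[:, 0] - x) ** 2 + (placed[:, 1] - y) ** 2
            if d2.min() < min_dist**2:
                continue
        centers.append((x, y))
        placed = np.asarray(centers)
    return np.round(placed).astype(int)


def sample_ground_truth(
    n_cells: int,
    protocol: StimulusProtocol,
    tuning: TuningConfig | None = None,
    seed: int = 0,
) -> GroundTruth:
    """Draw a deterministic ground-truth population for one simulated subject."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    tuning = tuning or TuningConfig()
    rng = np.random.default_rng(seed)

    min_dist = max(tuning.min_center_distance_px, 2.0)  # centers never closer than 2 px
    margin = 2.0 * tuning.radius_px + tuning.drift_max_px + 1
    centers = _place_centers(n_cells, tuning.frame_shape, margin, min_dist, rng)

    labels = protocol.stimulus_labels
    m = len(labels)
    pref_idx = rng.integers(0, m, size=n_cells)
    selective = rng.random(n_cells) < tuning.p_selective
    pref_amp = rng.uniform(*tuning.preferred_amp_range, size=n_cells)

    amps = np.zeros((n_cells, m))
    for i in range(n_cells):
        rel_range = (
            tuning.off_rel_range_selective if selective[i] else tuning.off_rel_range_broad
        )
        rel = rng.uniform(*rel_range, size=m)
        sign = np.where(rng.random(m) < tuning.p_suppressed, -1.0, 1.0)
        amps[i] = pref_amp[i] * rel * sign
        amps[i, pref_idx[i]] = pref_amp[i]  # preferred response is the signed max

    f0 = rng.uniform(*tuning.f0_range, size=n_cells)
    cells = pd.DataFrame(
        {
            "cell_id": [f"cell{i:04d}" for i in range(n_cells)],
            "x": centers[:, 0],
            "y": centers[:, 1],
            "radius": tuning.radius_px,
            "f0": f0,
            "rise_tau_s": tuning.rise_tau_s,
            "decay_tau_s": tuning.decay_tau_s,
            "preferred_stimulus": [labels[j] for j in pref_idx],
            "tuning_class": np.where(selective, "selective", "broad"),
        }
    )
    amplitudes = pd.DataFrame(amps, index=cells["cell_id"], columns=list(labels))

    n_trials = protocol.n_trials_per_stimulus
    if tuning.drift_max_px > 0 and n_trials > 1:
        drift = rng.integers(-tuning.drift_max_px, tuning.drift_max_px + 1, size=(n_trials, 2))
        drift[0] = 0  # first trial defines the reference position
    else:
        drift = np.zeros((n_trials, 2), dtype=int)

    return GroundTruth(
        cells=cells,
        amplitudes=amplitudes,
        protocol=protocol,
        noise_sd=tuning.noise_sd,
        background=tuning.background,
        bleach_tau_s=tuning.bleach_tau_s,
        drift=np.asarray(drift, dtype=int),
        seed=int(seed),
        frame_shape=tuning.frame_shape,
    )


def _transient_kernel(rise_tau_s: float, decay_tau_s: float, frame_rate_hz: float, n_frames: int) -> np.ndarray:
    """Difference-of-exponentials indicator impulse response on the frame grid."""
    t = np.arange(n_frames) / frame_rate_hz
    return np.exp(-t / decay_tau_s) - np.exp(-t / rise_tau_s)


def render_ideal_traces(gt: GroundTruth, protocol: StimulusProtocol | None = None) -> dict[str, np.ndarray]:
    """Noiseless per-cell ΔF/F traces for every stimulus.

    The transient is the stimulus-window boxcar convolved with a
    difference-of-exponentials kernel (rise_tau, decay_tau), rescaled so the
    trace extremum equals the stored signed amplitude.  Traces are identically
    zero before stimulus onset.  Returns ``{stimulus: (n_cells, n_frames)}``;
    trials share the same ideal trace (trial-to-trial variability enters only
    through movie rendering).
    """
    protocol = protocol or gt.protocol
    n = protocol.n_frames
    onset, offset = protocol.onset_frame, protocol.offset_frame
    boxcar = np.zeros(n)
    boxcar[onset:offset] = 1.0

    # one normalized shape per distinct kinetics pair
    shape_cache: dict[tuple[float, float], np.ndarray] = {}

    def shape_for(rise: float, decay: float) -> np.ndarray:
        key = (rise, decay)
        if key not in shape_cache:
            kern = _transient_kernel(rise, decay, protocol.frame_rate_hz, n)
            conv = np.convolve(boxcar, kern)[:n]
            peak = np.abs(conv).max()
            shape_cache[key] = conv / peak if peak > 0 else conv
        return shape_cache[key]

    out: dict[str, np.ndarray] = {}
    kin = gt.cells[["rise_tau_s", "decay_tau_s"]].to_numpy()
    for stim in protocol.stimulus_labels:
        amps = gt.amplitudes[stim].to_numpy()
        traces = np.empty((gt.n_cells, n))
        for i in range(gt.n_cells):
            traces[i] = amps[i] * shape_for(kin[i, 0], kin[i, 1])
        out[stim] = traces
    return out


def render_movie(
    gt: GroundTruth,
    ideal_traces: dict[str, np.ndarray],
    stimulus: str,
    trial: int,
    protocol: StimulusProtocol | None = None,
    dtype=np.float32,
) -> MovieStack:
    """Render one trial movie for one stimulus.

    Pixel model: each soma is an isotropic Gaussian profile (σ = radius / 2)
    with center intensity ``F0 x (1 + ΔF/F(t))``, on a flat background,
    multiplied by an optional exponential bleach factor, shifted rigidly by
    the trial's (dx, dy) drift, with additive Gaussian noise.  Negative pixel
    values are clipped at zero; clipping of more than 1% of pixels warns.
    Output is float32 by default (float64 available for precision-critical
    noiseless renders) and bit-reproducible for a fixed ground-truth seed.
    """
    protocol = protocol or gt.protocol
    stim_idx = protocol.stimulus_index(stimulus)
    if not (0 <= trial < protocol.n_trials_per_stimulus):
        raise ValueError(f"trial {trial} outside protocol (n={protocol.n_trials_per_stimulus})")
    n = protocol.n_frames
    H, W = gt.frame_shape

    dx, dy = (int(v) for v in gt.drift[trial])
    traces = ideal_traces[stimulus]

    movie = np.full((n, H, W), gt.background, dtype=dtype)
    for i in range(gt.n_cells):
        cx = int(gt.cells["x"].iloc[i]) + dx
        cy = int(gt.cells["y"].iloc[i]) + dy
        r = float(gt.cells["radius"].iloc[i])
        sigma = r / 2.0
        half = int(np.ceil(3 * sigma))
        x0, x1 = max(cx - half, 0), min(cx + half + 1, W)
        y0, y1 = max(cy - half, 0), min(cy + half + 1, H)
        if x0 >= x1 or y0 >= y1:
            continue
        xs = np.arange(x0, x1) - cx
        ys = np.arange(y0, y1) - cy
        profile = np.exp(-(xs[None, :] ** 2 + ys[:, None] ** 2) / (2 * sigma**2)).astype(dtype)
        f0 = float(gt.cells["f0"].iloc[i])
        amp_t = (f0 * (1.0 + traces[i])).astype(dtype)
        movie[:, y0:y1, x0:x1] += amp_t[:, None, None] * profile[None, :, :]

    if gt.bleach_tau_s is not None:
        t = np.arange(n, dtype=dtype) / protocol.frame_rate_hz
        movie *= np.exp(-t / gt.bleach_tau_s)[:, None, None].astype(dtype)

    if gt.noise_sd > 0:
        rng = np.random.default_rng([gt.seed, stim_idx, trial])
        noise_dtype = np.float32 if dtype == np.float32 else np.float64
        movie += gt.noise_sd * rng.standard_normal(movie.shape, dtype=noise_dtype)

    clipped = movie < 0
    n_clipped = int(clipped.sum())
    if n_clipped:
        movie[clipped] = 0.0
        frac = n_clipped / movie.size
        if frac > 0.01:
            warnings.warn(
                f"{100 * frac:.1f}% of pixels clipped at zero intensity",
                ClippingWarning,
                stacklevel=2,
            )

    return MovieStack(
        data=movie,
        frame_rate_hz=protocol.frame_rate_hz,
        label=f"{stimulus}_trial{trial}",
    )
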