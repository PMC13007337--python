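"""Stimulus protocol definition and file I/O for movies, ROI tables and count tables.

The stimulus protocol encodes the trial timing grid used throughout the
package: each trial starts with a pre-stimulus baseline, followed by an odor
stimulation window and a post-stimulus recovery period.  Default values match
a widefield acquisition at 25 frames/s with a 3 s baseline, 5 s stimulation
and 16 s post-stimulus window (600-frame trials, stimulus onset at frame 75),
with a seven-stimulus odor panel delivered in 3 trials each.

All frame indexing is 0-based with half-open windows ``[start, end)``.
Pixel coordinates follow the raster convention: x = column, y = row,
origin at the top-left of the frame.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "DEFAULT_STIMULI",
    "StimulusProtocol",
    "MovieStack",
    "ROISet",
    "CountVolumeTable",
    "load_protocol",
    "read_movie",
    "write_movie",
    "read_rois",
    "write_rois",
    "read_count_volume_table",
    "write_table",
]

#: Seven-stimulus odor panel (one control water line plus six odorants).
DEFAULT_STIMULI: tuple[str, ...] = (
    "water",
    "NaCl",
    "LCA",
    "adenosine",
    "cadaverine",
    "alanine",
    "NH4Cl",
)

_PROTOCOL_KEYS = {
    "frame_rate_hz",
    "baseline_s",
    "stimulus_s",
    "post_s",
    "trial_duration_s",
    "stimuli",
    "n_trials",
}


class ProtocolError(ValueError):
    """Raised for malformed or inconsistent protocol configurations."""


@dataclass(frozen=True)
class StimulusProtocol:
    """Trial timing grid and stimulus panel.

    Parameters
    ----------
    frame_rate_hz
        Acquisition rate in frames per second.
    baseline_s, stimulus_s, post_s
        Durations of the pre-stimulus baseline, the odor stimulation window
        and the post-stimulus period, in seconds.
    stimulus_labels
        Ordered, unique stimulus names; the order defines category order in
        every downstream summary and breaks preference ties.
    n_trials_per_stimulus
        Number of repeated trials recorded per stimulus.
    """

    frame_rate_hz: float = 25.0
    baseline_s: float = 3.0
    stimulus_s: float = 5.0
    post_s: float = 16.0
    stimulus_labels: tuple[str, ...] = DEFAULT_STIMULI
    n_trials_per_stimulus: int = 3

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0:
            raise ProtocolError(f"frame_rate_hz must be > 0, got {self.frame_rate_hz}")
        for name in ("baseline_s", "stimulus_s", "post_s"):
            if getattr(self, name) <= 0:
                raise ProtocolError(f"{name} must be > 0, got {getattr(self, name)}")
        labels = tuple(self.stimulus_labels)
        object.__setattr__(self, "stimulus_labels", labels)
        if len(labels) < 1:
            raise ProtocolError("at least one stimulus label is required")
        if len(set(labels)) != len(labels):
            raise ProtocolError(f"stimulus labels are not unique: {labels}")
        if self.n_trials_per_stimulus < 1:
            raise ProtocolError("n_trials_per_stimulus must be >= 1")

    # -- derived frame arithmetic (exact integers) ---------------------------

    @property
    def trial_duration_s(self) -> float:
        return self.baseline_s + self.stimulus_s + self.post_s

    @property
    def n_frames(self) -> int:
        """Total frames per trial."""
        return int(round(self.trial_duration_s * self.frame_rate_hz))

    @property
    def onset_frame(self) -> int:
        """First frame of odor stimulation (round-to-nearest of baseline x rate)."""
        return int(round(self.baseline_s * self.frame_rate_hz))

    @property
    def offset_frame(self) -> int:
        """First frame after the stimulation window."""
        return int(round((self.baseline_s + self.stimulus_s) * self.frame_rate_hz))

    @property
    def n_stimulus_frames(self) -> int:
        return self.offset_frame - self.onset_frame

    @property
    def n_stimuli(self) -> int:
        return len(self.stimulus_labels)

    def stimulus_index(self, label: str) -> int:
        try:
            return self.stimulus_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown stimulus label {label!r}") from None


def load_protocol(config_source: str | Path | dict) -> StimulusProtocol:
    """Build a :class:`StimulusProtocol` from a YAML file, YAML string or dict.

    Recognized keys: ``frame_rate_hz``, ``baseline_s``, ``stimulus_s``,
    ``post_s``, ``stimuli`` (list of labels), ``n_trials`` and optionally
    ``trial_duration_s`` (validated against the sum of the three windows).
    Missing keys take the package defaults; unknown keys produce a warning
    but never an error.
    """
    if isinstance(config_source, dict):
        cfg = dict(config_source)
    else:
        if isinstance(config_source, Path) or (
            isinstance(config_source, str) and "\n" not in config_source and Path(config_source).exists()
        ):
            text = Path(config_source).read_text()
        else:
            text = str(config_source)
        try:
            cfg = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ProtocolError(f"could not parse protocol config: {exc}") from exc
        if cfg is None:
            cfg = {}
        if not isinstance(cfg, dict):
            raise ProtocolError("protocol config must be a key-value mapping")

    unknown = set(cfg) - _PROTOCOL_KEYS
    if unknown:
        warnings.warn(f"ignoring unknown protocol keys: {sorted(unknown)}", stacklevel=2)

    proto = StimulusProtocol(
        frame_rate_hz=float(cfg.get("frame_rate_hz", 25.0)),
        baseline_s=float(cfg.get("baseline_s", 3.0)),
        stimulus_s=float(cfg.get("stimulus_s", 5.0)),
        post_s=float(cfg.get("post_s", 16.0)),
        stimulus_labels=tuple(cfg.get("stimuli", DEFAULT_STIMULI)),
        n_trials_per_stimulus=int(cfg.get("n_trials", 3)),
    )
    if "trial_duration_s" in cfg:
        stated = float(cfg["trial_duration_s"])
        if not np.isclose(stated, proto.trial_duration_s, rtol=0, atol=1e-9):
            raise ProtocolError(
                f"trial_duration_s={stated} does not equal "
                f"baseline_s + stimulus_s + post_s = {proto.trial_duration_s}"
            )
    return proto


@dataclass
class MovieStack:
    """A T x H x W single-channel fluorescence movie with frame-rate metadata."""

    data: np.ndarray
    frame_rate_hz: float = 25.0
    label: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3:
            raise ValueError(f"movie data must be T x H x W, got shape {arr.shape}")
        if arr.shape[0] < 1 or arr.shape[1] < 1 or arr.shape[2] < 1:
            raise ValueError(f"movie has a zero-length axis: shape {arr.shape}")
        if not np.isfinite(arr).all():
            raise ValueError("movie intensities must be finite")
        if arr.min() < 0:
            raise ValueError("movie intensities must be nonnegative")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be > 0")
        self.data = arr

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape


def read_movie(path: str | Path, frame_rate_hz: float = 25.0, label: str = "") -> MovieStack:
    """Read a single-channel multi-page TIFF as a :class:`MovieStack`.

    Multi-channel (RGB or extra-sample) TIFFs are rejected; this reader makes
    no intensity corrections (no dark-frame subtraction).
    """
    arr = tifffile.imread(str(path))
    arr = np.asarray(arr)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(
            f"unsupported TIFF layout with shape {arr.shape}; "
            "expected a single-channel multi-page stack"
        )
    # RGB stored as pages of H x W x 3 collapses to ndim 4 above; pages that
    # are suspiciously thin in the last axis indicate interleaved channels.
    if arr.shape[-1] in (3, 4) and arr.shape[-1] < 8 and arr.ndim == 3 and arr.shape[1] > 8:
        raise ValueError("multi-channel / RGB TIFF input is not supported")
    return MovieStack(data=arr, frame_rate_hz=frame_rate_hz, label=label or Path(path).stem)


def write_movie(movie: MovieStack, path: str | Path) -> None:
    """Write a movie as an uncompressed multi-page TIFF (lossless for integer dtypes)."""
    tifffile.imwrite(str(path), movie.data, photometric="minisblack")


@dataclass
class ROISet:
    """Circular somatic ROIs: per-cell center and radius, optional per-trial offsets.

    ``rois`` has columns ``cell_id, x, y, radius``; ``offsets`` (optional) has
    columns ``cell_id, trial, dx, dy`` giving the rigid per-trial shift applied
    to that cell's center, compensating slow XY drift between trials.
    """

    rois: pd.DataFrame
    offsets: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        required = ["cell_id", "x", "y", "radius"]
        missing = [c for c in required if c not in self.rois.columns]
        if missing:
            raise ValueError(f"ROI table is missing columns: {missing}")
        df = self.rois[required].copy().reset_index(drop=True)
        if df["cell_id"].duplicated().any():
            dupes = df.loc[df["cell_id"].duplicated(), "cell_id"].tolist()
            raise ValueError(f"duplicate cell_id values: {dupes}")
        if (df["radius"] < 1).any():
            bad = df.loc[df["radius"] < 1, "cell_id"].tolist()
            raise ValueError(f"ROI radius must be >= 1 pixel; offenders: {bad}")
        if (df["x"] < 0).any() or (df["y"] < 0).any():
            bad = df.loc[(df["x"] < 0) | (df["y"] < 0), "cell_id"].tolist()
            raise ValueError(f"negative ROI center coordinates; offenders: {bad}")
        self.rois = df
        if self.offsets is not None:
            off = self.offsets[["cell_id", "trial", "dx", "dy"]].copy().reset_index(drop=True)
            self.offsets = off

    def __len__(self) -> int:
        return len(self.rois)

    @property
    def cell_ids(self) -> list:
        return self.rois["cell_id"].tolist()

    def centers(self, trial: int | None = None) -> np.ndarray:
        """(n_cells, 2) array of (x, y) centers with trial offsets applied."""
        xy = self.rois[["x", "y"]].to_numpy(dtype=float)
        if trial is not None and self.offsets is not None:
            off = self.offsets[self.offsets["trial"] == trial]
            if len(off):
                shift = (
                    off.set_index("cell_id")[["dx", "dy"]]
                    .reindex(self.rois["cell_id"])
                    .fillna(0.0)
                    .to_numpy(dtype=float)
                )
                xy = xy + shift
        return xy


def read_rois(path: str | Path) -> ROISet:
    """Read an ROI CSV with header ``cell_id,x,y,radius[,trial,dx,dy]``.

    Rows carrying ``trial,dx,dy`` values populate the per-trial offset table;
    base geometry rows (one per cell) must have those columns empty or absent.
    """
    df = pd.read_csv(path)
    has_offsets = {"trial", "dx", "dy"}.issubset(df.columns)
    if has_offsets:
        base = df[df["trial"].isna()] if df["trial"].isna().any() else df.drop_duplicates("cell_id")
        offsets = df.dropna(subset=["trial"])
        offsets = offsets.astype({"trial": int}) if len(offsets) else None
        if df["trial"].isna().any():
            # mixed file: geometry rows have blank trial, offset rows are extra
            base = df[df["trial"].isna()]
        return ROISet(rois=base, offsets=offsets)
    return ROISet(rois=df)


def write_rois(roiset: ROISet, path: str | Path) -> None:
    rois = roiset.rois.copy()
    if roiset.offsets is not None and len(roiset.offsets):
        rois["trial"] = np.nan
        rois["dx"] = np.nan
        rois["dy"] = np.nan
        off = roiset.offsets.copy()
        geo = roiset.rois.set_index("cell_id")
        off = off.join(geo, on="cell_id")
        out = pd.concat([rois, off[rois.columns]], ignore_index=True)
    else:
        out = rois
    out.to_csv(path, index=False)


@dataclass
class CountVolumeTable:
    """Per-sample neuron counts and olfactory-bulb volumes for group statistics.

    Columns: ``sample_id, group, timepoint_dpf, cell_count, ob_volume`` with
    volumes in µm³ (strictly positive) and integral nonnegative counts.
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "group", "timepoint_dpf", "cell_count", "ob_volume")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"count/volume table is missing columns: {missing}")
        df = self.table[list(self.REQUIRED)].copy().reset_index(drop=True)
        if (df["ob_volume"] <= 0).any():
            bad = df.loc[df["ob_volume"] <= 0, "sample_id"].tolist()
            raise ValueError(f"ob_volume must be > 0; offenders: {bad}")
        counts = df["cell_count"].to_numpy(dtype=float)
        if (counts < 0).any() or not np.allclose(counts, np.round(counts)):
            raise ValueError("cell_count values must be nonnegative integers")
        df["cell_count"] = counts.astype(int)
        self.table = df


def read_count_volume_table(path: str | Path) -> CountVolumeTable:
    return CountVolumeTable(pd.read_csv(path))


def write_table(obj, path: str | Path) -> None:
    """Write any table-backed object (or bare DataFrame) to CSV."""
    if isinstance(obj, pd.DataFrame):
        obj.to_csv(path, index=False)
    elif hasattr(obj, "table"):
        obj.table.to_csv(path, index=False)
    elif hasattr(obj, "to_frame"):
        obj.to_frame().to_csv(path, index=False)
    else:
        raise TypeError(f"do not know how to write {type(obj).__name__} to CSV")
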