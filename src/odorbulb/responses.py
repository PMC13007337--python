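"""Per-cell odor-response quantification and population summaries.

Definitions used throughout (all on the trial-averaged, 5 Hz-filtered ΔF/F
analysis trace):

* **response magnitude** ``r`` — mean ΔF/F over the first 30 frames of odor
  stimulation minus the mean over the 10 frames immediately preceding onset
  (signed; negative values are suppressed responses);
* **significance** — the peak ΔF/F during the stimulation window must lie at
  least 6 standard deviations above the pre-stimulus (full baseline) period;
* **preferred stimulus** — the stimulus with the largest signed magnitude,
  assigned only to cells with at least one significant response;
* **lifetime sparseness** ``LS = (Σ_j r_j / m)² / (Σ_j r_j² / m)`` over the
  m stimuli, with suppressed (negative) magnitudes rectified to 0 first.
  LS is 1/m for a cell driven by a single stimulus and 1 for a cell
  responding uniformly to all of them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from odorbulb.protocol import StimulusProtocol
from odorbulb.traces import TraceMatrix

__all__ = [
    "ResponseTable",
    "CategoryCounts",
    "response_magnitude",
    "is_significant",
    "assign_preference",
    "lifetime_sparseness",
    "build_response_table",
    "sort_population_heatmap",
    "category_counts",
    "summarize_category_counts",
]


def response_magnitude(
    trace: np.ndarray,
    protocol: StimulusProtocol,
    response_frames: int = 30,
    pre_frames: int = 10,
) -> float:
    """Signed response magnitude of one analysis trace.

    ``mean(dff[onset, onset + response_frames)) - mean(dff[onset - pre_frames,
    onset))``.  Negative values indicate suppression.
    """
    trace = np.asarray(trace, dtype=float)
    onset = protocol.onset_frame
    if trace.shape[-1] < onset + response_frames:
        raise ValueError(
            f"trace of length {trace.shape[-1]} too short for a "
            f"{response_frames}-frame response window at onset {onset}"
        )
    if onset - pre_frames < 0:
        raise ValueError("pre-stimulus window out of range")
    return float(
        trace[onset : onset + response_frames].mean()
        - trace[onset - pre_frames : onset].mean()
    )


def is_significant(
    trace: np.ndarray, protocol: StimulusProtocol, z_threshold: float = 6.0
) -> tuple[bool, float]:
    """6-SD peak test of one analysis trace against its pre-stimulus period.

    ``peak_z`` is the maximum ΔF/F over the full stimulation window, centered
    on the baseline mean and scaled by the baseline SD (sample SD over the
    whole pre-stimulus period).  Returns ``(peak_z >= z_threshold, peak_z)``.
    """
    trace = np.asarray(trace, dtype=float)
    onset, offset = protocol.onset_frame, protocol.offset_frame
    baseline = trace[:onset]
    if baseline.size < 2:
        raise ValueError("baseline window must contain at least 2 frames")
    sd = baseline.std(ddof=1)
    if sd == 0:
        raise ValueError(
            "degenerate baseline (SD = 0); significance is undefined on noiseless traces"
        )
    peak = trace[onset:offset].max()
    peak_z = float((peak - baseline.mean()) / sd)
    return peak_z >= z_threshold, peak_z


def assign_preference(
    magnitudes: np.ndarray,
    significant: np.ndarray,
    labels: tuple[str, ...] | list[str],
) -> str | None:
    """Preferred-stimulus label for one cell, or None if nothing is significant.

    The preferred stimulus is the argmax of the signed magnitudes across all
    stimuli; exact ties go to the earlier label in protocol order (warned).
    Cells whose only responses are suppressions (all magnitudes <= 0) are not
    classified.
    """
    magnitudes = np.asarray(magnitudes, dtype=float)
    significant = np.asarray(significant, dtype=bool)
    if not significant.any():
        return None
    if magnitudes.max() <= 0:
        return None
    best = magnitudes.max()
    ties = np.flatnonzero(magnitudes == best)
    if ties.size > 1:
        warnings.warn(
            f"preference tie between {[labels[i] for i in ties]}; "
            "keeping the first in protocol order",
            stacklevel=2,
        )
    return labels[int(ties[0])]


def lifetime_sparseness(magnitudes: np.ndarray, rectify: bool = True) -> float:
    """Lifetime sparseness of one cell's m-stimulus magnitude vector.

    ``LS = (Σ r/m)² / (Σ r²/m)``; negative magnitudes are rectified to 0
    before the formula (the statistic is not defined for mixed-sign input).
    Returns NaN when every rectified magnitude is 0.
    """
    r = np.asarray(magnitudes, dtype=float)
    if r.size < 2:
        raise ValueError("lifetime sparseness requires at least 2 stimuli")
    if rectify:
        r = np.clip(r, 0.0, None)
    elif (r < 0).any():
        raise ValueError("magnitudes must be nonnegative when rectify=False")
    m = r.size
    denom = (r**2).sum() / m
    if denom == 0:  # all zero (or underflowed to it)
        return float("nan")
    return float((r.sum() / m) ** 2 / denom)


@dataclass
class ResponseTable:
    """Per-(cell, stimulus) response quantities plus per-cell summaries.

    ``long`` columns: cell_id, stimulus, magnitude, peak_z, significant.
    ``cells`` columns: cell_id, preferred (label or NaN), ls (NaN when
    undefined), n_significant.
    """

    long: pd.DataFrame
    cells: pd.DataFrame
    protocol: StimulusProtocol

    def magnitude_matrix(self) -> pd.DataFrame:
        """cells x stimuli signed magnitudes in protocol stimulus order."""
        wide = self.long.pivot(index="cell_id", columns="stimulus", values="magnitude")
        return wide.reindex(columns=list(self.protocol.stimulus_labels)).loc[
            self.cells["cell_id"]
        ]

    def to_frame(self) -> pd.DataFrame:
        """Flat export: one row per (cell, stimulus) with per-cell columns repeated."""
        return self.long.merge(self.cells, on="cell_id", how="left")


def build_response_table(
    traces_by_stimulus: dict[str, TraceMatrix], protocol: StimulusProtocol
) -> ResponseTable:
    """Assemble the full response table from per-stimulus analysis traces.

    Each entry of ``traces_by_stimulus`` must be a trial-averaged, filtered
    ΔF/F :class:`TraceMatrix` covering the same cells.
    """
    labels = protocol.stimulus_labels
    missing = [s for s in labels if s not in traces_by_stimulus]
    if missing:
        raise ValueError(f"missing traces for stimuli: {missing}")
    ref = traces_by_stimulus[labels[0]]
    cell_ids = list(ref.cell_ids)

    rows = []
    mags = np.empty((len(cell_ids), len(labels)))
    sigs = np.empty((len(cell_ids), len(labels)), dtype=bool)
    zs = np.empty((len(cell_ids), len(labels)))
    for j, stim in enumerate(labels):
        tm = traces_by_stimulus[stim]
        if tm.kind != "dff_filtered":
            raise ValueError(
                f"analysis traces must be dff_filtered; stimulus {stim!r} is {tm.kind!r}"
            )
        if list(tm.cell_ids) != cell_ids:
            raise ValueError("all stimuli must cover the same cells in the same order")
        for i in range(len(cell_ids)):
            mags[i, j] = response_magnitude(tm.data[i], protocol)
            sigs[i, j], zs[i, j] = is_significant(tm.data[i], protocol)

    for i, cid in enumerate(cell_ids):
        for j, stim in enumerate(labels):
            rows.append(
                {
                    "cell_id": cid,
                    "stimulus": stim,
                    "magnitude": mags[i, j],
                    "peak_z": zs[i, j],
                    "significant": bool(sigs[i, j]),
                }
            )

    prefs = [assign_preference(mags[i], sigs[i], labels) for i in range(len(cell_ids))]
    ls = [
        lifetime_sparseness(mags[i]) if prefs[i] is not None else float("nan")
        for i in range(len(cell_ids))
    ]
    cells = pd.DataFrame(
        {
            "cell_id": cell_ids,
            "preferred": prefs,
            "ls": ls,
            "n_significant": sigs.sum(axis=1),
        }
    )
    return ResponseTable(long=pd.DataFrame(rows), cells=cells, protocol=protocol)


def sort_population_heatmap(table: ResponseTable) -> tuple[list, np.ndarray]:
    """Population heat-map ordering: by preferred stimulus, then response strength.

    Classified cells are grouped by preferred stimulus in protocol order and
    sorted within group by descending magnitude to the preferred stimulus,
    with cell_id as the final (stable, deterministic) key.  Unclassified
    cells are excluded.  Returns ``(ordered cell_ids, cells x stimuli
    magnitude matrix in that order)``.
    """
    labels = list(table.protocol.stimulus_labels)
    classified = table.cells.dropna(subset=["preferred"]).copy()
    if classified.empty:
        return [], np.empty((0, len(labels)))
    wide = table.magnitude_matrix().loc[classified["cell_id"]]
    classified["pref_rank"] = classified["preferred"].map(labels.index)
    classified["pref_mag"] = [
        wide.loc[cid, pref] for cid, pref in zip(classified["cell_id"], classified["preferred"])
    ]
    ordered = classified.sort_values(
        by=["pref_rank", "pref_mag", "cell_id"], ascending=[True, False, True], kind="mergesort"
    )["cell_id"].tolist()
    return ordered, wide.loc[ordered].to_numpy()


@dataclass
class CategoryCounts:
    """Preferred-stimulus category counts per preparation and group summaries.

    ``per_preparation`` columns: preparation, group, stimulus, count, total
    (the preparation's number of classified cells).  ``summary`` columns:
    group, stimulus, mean_count, sem_count, n_preparations.
    """

    per_preparation: pd.DataFrame
    summary: pd.DataFrame

    def group_totals(self) -> pd.DataFrame:
        """Mean and SEM of classified cells per preparation, by group."""
        totals = self.per_preparation.drop_duplicates(["preparation", "group"])[
            ["preparation", "group", "total"]
        ]
        out = (
            totals.groupby("group")["total"]
            .agg(mean_total="mean", sem_total=lambda v: v.std(ddof=1) / np.sqrt(len(v)), n="count")
            .reset_index()
        )
        return out


def category_counts(
    tables: list[ResponseTable],
    groups: list[str],
    preparations: list[str] | None = None,
) -> CategoryCounts:
    """Count preferred-stimulus categories per preparation and summarize by group.

    ``tables[k]`` is the response table of preparation k, with group label
    ``groups[k]``.  Per-preparation category counts always sum to that
    preparation's number of classified cells.
    """
    if len(tables) != len(groups):
        raise ValueError("tables and groups must have the same length")
    if not tables:
        raise ValueError("at least one preparation is required")
    preparations = preparations or [f"prep{k}" for k in range(len(tables))]
    labels = list(tables[0].protocol.stimulus_labels)
    rows = []
    for prep, group, table in zip(preparations, groups, tables):
        prefs = table.cells["preferred"].dropna()
        total = int(len(prefs))
        counts = prefs.value_counts()
        for stim in labels:
            rows.append(
                {
                    "preparation": prep,
                    "group": group,
                    "stimulus": stim,
                    "count": int(counts.get(stim, 0)),
                    "total": total,
                }
            )
    per_prep = pd.DataFrame(rows)
    return CategoryCounts(per_preparation=per_prep, summary=summarize_category_counts(per_prep))


def summarize_category_counts(per_prep: pd.DataFrame) -> pd.DataFrame:
    """Group-level mean and SEM of per-preparation category counts.

    Input columns: preparation, group, stimulus, count.  Because the mean is
    linear, per-category group means sum exactly to the group's mean number
    of classified cells per preparation.
    """
    def _sem(v: pd.Series) -> float:
        return float(v.std(ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")

    out = (
        per_prep.groupby(["group", "stimulus"], sort=False)["count"]
        .agg(mean_count="mean", sem_count=_sem, n_preparations="count")
        .reset_index()
    )
    return out
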