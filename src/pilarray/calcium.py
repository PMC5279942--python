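"""ΔF/F computation and agonist-response scoring for calcium imaging.

Fluorescence intensity time series (one per cell, frames every few
seconds) are normalized to the mean of an initial baseline period:

    ΔF/F = (F − F₀) / F₀

A cell *responds* to an agonist epoch when its peak ΔF/F within the
epoch exceeds a threshold; cells that fail the viability epoch (ATP) are
excluded from statistics on the later agonist epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Epoch",
    "FluorescenceTrace",
    "EpochScore",
    "delta_f_over_f",
    "score_epoch",
    "score_cells",
    "population_trace",
]


@dataclass(frozen=True)
class Epoch:
    """One agonist application window."""

    label: str
    start_s: float
    duration_s: float

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass(frozen=True)
class FluorescenceTrace:
    """Per-cell fluorescence intensities with agonist-epoch annotations.

    The first ``n_baseline_frames`` frames precede every epoch and define
    the baseline F₀.
    """

    intensities: np.ndarray
    frame_interval_s: float = 5.0
    n_baseline_frames: int = 10
    cell_id: str = ""
    epochs: tuple[Epoch, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "intensities", arr)
        object.__setattr__(self, "epochs", tuple(self.epochs))
        if self.n_baseline_frames < 1:
            raise ValueError("need at least one baseline frame")
        if len(arr) < self.n_baseline_frames:
            raise ValueError("trace shorter than the baseline period")
        if np.any(arr <= 0):
            raise ValueError("fluorescence intensities must be positive")
        baseline_end = self.n_baseline_frames * self.frame_interval_s
        for ep in self.epochs:
            if ep.start_s < baseline_end:
                raise ValueError(f"epoch {ep.label!r} overlaps the baseline period")
        spans = sorted((ep.start_s, ep.end_s, ep.label) for ep in self.epochs)
        for (s0, e0, l0), (s1, e1, l1) in zip(spans, spans[1:]):
            if s1 < e0:
                raise ValueError(f"epochs {l0!r} and {l1!r} overlap")

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.intensities)) * self.frame_interval_s


@dataclass(frozen=True)
class EpochScore:
    cell_id: str
    epoch: Epoch
    responder: bool
    peak_dff: float
    threshold: float


def delta_f_over_f(trace: FluorescenceTrace) -> np.ndarray:
    """Baseline-normalized fluorescence (F − F₀)/F₀ per frame.

    F₀ is the mean of the first ``n_baseline_frames`` intensities.
    """
    f0 = float(np.mean(trace.intensities[: trace.n_baseline_frames]))
    if f0 <= 0:
        raise ValueError("baseline fluorescence must be positive")
    return (trace.intensities - f0) / f0


def score_epoch(
    trace: FluorescenceTrace,
    epoch: Epoch,
    threshold: float | None = None,
    dff: np.ndarray | None = None,
) -> EpochScore:
    """Score one agonist epoch: peak ΔF/F and responder call.

    Default threshold is max(0.1, 5 × SD of the baseline ΔF/F) — a
    response must rise clearly above both photon noise and a fixed floor.
    """
    if dff is None:
        dff = delta_f_over_f(trace)
    t = trace.time_s
    if epoch.start_s < 0 or epoch.end_s > t[-1] + trace.frame_interval_s:
        raise ValueError(f"epoch {epoch.label!r} extends beyond the trace")
    if threshold is None:
        baseline_sd = float(np.std(dff[: trace.n_baseline_frames]))
        threshold = max(0.1, 5.0 * baseline_sd)
    mask = (t >= epoch.start_s) & (t < epoch.end_s)
    if not mask.any():
        raise ValueError(f"epoch {epoch.label!r} covers no frames")
    peak = float(np.max(dff[mask]))
    return EpochScore(trace.cell_id, epoch, peak > threshold, peak, threshold)


def score_cells(
    traces: Sequence[FluorescenceTrace],
    viability_label: str = "ATP",
    threshold: float | None = None,
) -> pd.DataFrame:
    """Score every epoch of every cell, gating on the viability epoch.

    Cells whose viability epoch (default label "ATP") fails the responder
    criterion are marked non-viable; their other epochs are still scored
    but flagged ``included = False`` so population statistics can exclude
    them, matching the convention that only ATP-responsive cells enter
    the agonist analysis.
    """
    rows = []
    for trace in traces:
        dff = delta_f_over_f(trace)
        scores = {ep.label: score_epoch(trace, ep, threshold, dff) for ep in trace.epochs}
        viable = (scores[viability_label].responder
                  if viability_label in scores else True)
        for label, sc in scores.items():
            rows.append({
                "cell_id": trace.cell_id, "epoch": label,
                "responder": sc.responder, "peak_dff": sc.peak_dff,
                "threshold": sc.threshold, "viable": viable,
                "included": viable or label == viability_label,
            })
    return pd.DataFrame(rows)


def population_trace(traces: Sequence[FluorescenceTrace]) -> pd.DataFrame:
    """Mean ± s.e.m. ΔF/F across cells, frame by frame."""
    dffs = np.vstack([delta_f_over_f(t) for t in traces])
    n = dffs.shape[0]
    return pd.DataFrame({
        "time_s": traces[0].time_s,
        "mean_dff": dffs.mean(axis=0),
        "sem_dff": dffs.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.nan,
        "n_cells": n,
    })
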