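"""Binned stimulus–response statistics, responder calls and thresholds.

Deflection stimuli vary from sweep to sweep, so current amplitudes are
compared across cells by grouping deflections into fixed bins
(default edges 0, 10, 50, 100, 250, 500, 1000 nm; intervals half-open
(lower, upper]).  Averaging is two-stage: within each cell the
amplitudes falling in a bin are averaged first, and those per-cell means
are then averaged across cells, so heavily stimulated cells do not
dominate.  Non-responding sweeps count as amplitude 0 in their bin.

A cell is a *responder* when at least one stimulus in the (0, 1000] nm
range gated a current; its *threshold* is the smallest deflection that
gated one.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .stats import ContingencyTable2x2, fisher_exact, mann_whitney

__all__ = [
    "BinningScheme",
    "BinnedStimulusResponse",
    "CellSummary",
    "bin_responses",
    "classify_responder",
    "summarize_cells",
    "compare_groups",
    "DEFAULT_BIN_EDGES",
]

#: Contiguous deflection-bin boundaries, nm.
DEFAULT_BIN_EDGES = (0.0, 10.0, 50.0, 100.0, 250.0, 500.0, 1000.0)


@dataclass(frozen=True)
class BinningScheme:
    """Ordered deflection-bin boundaries in nm, from 0 to 1000."""

    edges: tuple[float, ...] = DEFAULT_BIN_EDGES

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.edges)
        object.__setattr__(self, "edges", edges)
        if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("bin edges must be strictly increasing")
        if edges[0] != 0 or edges[-1] != 1000:
            raise ValueError("bins must span 0 to 1000 nm")

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(f"{lo:g}-{hi:g} nm" for lo, hi in zip(self.edges, self.edges[1:]))

    @property
    def n_bins(self) -> int:
        return len(self.edges) - 1

    def assign(self, deflection_nm: float) -> int | None:
        """Bin index for a deflection; None when outside (0, 1000]."""
        if not 0 < deflection_nm <= self.edges[-1]:
            return None
        # half-open (lower, upper]: searchsorted with side="left"
        return int(np.searchsorted(self.edges, deflection_nm, side="left")) - 1


@dataclass(frozen=True)
class BinnedStimulusResponse:
    """Two-stage binned averages of current amplitude vs deflection.

    ``per_cell_bin_means`` is a cells × bins frame (NaN where a cell
    contributed no measurement to a bin); group means and s.e.m. are
    taken over the contributing cells only, so the per-bin denominator
    equals the number of cells with at least one measurement there.
    """

    scheme: BinningScheme
    per_cell_bin_means: pd.DataFrame
    group_mean: pd.Series
    group_sem: pd.Series
    n_cells_per_bin: pd.Series
    n_measurements_per_bin: pd.Series
    n_cells: int
    n_measurements: int
    n_excluded: int = 0

    def table(self) -> pd.DataFrame:
        """Stimulus–response table: one row per bin."""
        return pd.DataFrame({
            "bin": list(self.scheme.labels),
            "mean_pA": self.group_mean.to_numpy(),
            "sem_pA": self.group_sem.to_numpy(),
            "n_cells": self.n_cells_per_bin.to_numpy(),
            "n_measurements": self.n_measurements_per_bin.to_numpy(),
        })

    def plot(self, ax=None, label: str | None = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = np.arange(self.scheme.n_bins)
        ax.errorbar(x, self.group_mean, yerr=self.group_sem, fmt="o-", capsize=3,
                    label=label)
        ax.set_xticks(x, self.scheme.labels, rotation=45)
        ax.set_ylabel("current amplitude (pA)")
        ax.set_xlabel("deflection bin")
        if label:
            ax.legend()
        return ax


@dataclass(frozen=True)
class CellSummary:
    """Responder call and gating threshold of one cell."""

    cell_id: str
    responder: bool
    threshold_nm: float | None
    n_stimulation_points: int
    n_measurements: int

    def __post_init__(self) -> None:
        if self.responder != (self.threshold_nm is not None):
            raise ValueError("threshold must be present exactly when the cell responded")


def bin_responses(
    measurements: pd.DataFrame | Iterable[tuple],
    scheme: BinningScheme | None = None,
) -> BinnedStimulusResponse:
    """Two-stage binned averaging of (cell, deflection, amplitude) sweeps.

    ``measurements`` is a frame with columns cell_id, deflection_nm,
    amplitude_pA (or an iterable of such triples).  Deflections outside
    (0, 1000] nm are excluded and counted in ``n_excluded``.  Zero
    amplitudes (non-responding sweeps) are averaged like any other
    value.
    """
    scheme = scheme or BinningScheme()
    if not isinstance(measurements, pd.DataFrame):
        measurements = pd.DataFrame(
            measurements, columns=["cell_id", "deflection_nm", "amplitude_pA"])
    bins = measurements["deflection_nm"].map(scheme.assign) if len(measurements) else pd.Series(dtype=object)
    in_range = bins.notna() if len(measurements) else pd.Series(dtype=bool)
    kept = measurements[in_range].assign(bin=bins[in_range].astype(int)) if len(measurements) else measurements

    labels = list(scheme.labels)
    if len(kept) == 0:
        empty = pd.Series(np.nan, index=labels)
        zero = pd.Series(0, index=labels)
        return BinnedStimulusResponse(
            scheme, pd.DataFrame(columns=labels), empty, empty, zero, zero,
            n_cells=0, n_measurements=0,
            n_excluded=int(len(measurements) - len(kept)))

    per_cell = (kept.groupby(["cell_id", "bin"])["amplitude_pA"].mean()
                .unstack("bin").reindex(columns=range(scheme.n_bins)))
    per_cell.columns = labels
    n_cells_per_bin = per_cell.notna().sum()
    group_mean = per_cell.mean(axis=0)
    group_sem = per_cell.std(axis=0, ddof=1) / np.sqrt(n_cells_per_bin.where(n_cells_per_bin > 0))
    group_sem = group_sem.where(n_cells_per_bin > 1)  # undefined for a single cell
    n_meas = (kept.groupby("bin").size().reindex(range(scheme.n_bins), fill_value=0))
    n_meas.index = labels

    return BinnedStimulusResponse(
        scheme=scheme, per_cell_bin_means=per_cell,
        group_mean=group_mean, group_sem=group_sem,
        n_cells_per_bin=n_cells_per_bin, n_measurements_per_bin=n_meas,
        n_cells=per_cell.shape[0], n_measurements=int(len(kept)),
        n_excluded=int(len(measurements) - len(kept)))


def classify_responder(
    cell_measurements: pd.DataFrame,
    deflection_range_nm: tuple[float, float] = (0.0, 1000.0),
) -> CellSummary:
    """Responder call and minimal gating deflection for one cell.

    A cell responds when at least one sweep with deflection in
    (range lower, range upper] gated a current (``responded`` True); the
    threshold is the smallest such gating deflection.
    """
    if len(cell_measurements) == 0:
        raise ValueError("cell has no measurements")
    ids = cell_measurements["cell_id"].unique()
    if len(ids) != 1:
        raise ValueError(f"expected one cell, got {list(ids)}")
    lo, hi = deflection_range_nm
    d = cell_measurements["deflection_nm"]
    in_range = (d > lo) & (d <= hi)
    gating = cell_measurements[in_range & cell_measurements["responded"]]
    responder = len(gating) > 0
    threshold = float(gating["deflection_nm"].min()) if responder else None
    return CellSummary(
        cell_id=str(ids[0]), responder=responder, threshold_nm=threshold,
        n_stimulation_points=int(d[in_range].nunique()),
        n_measurements=int(in_range.sum()))


def summarize_cells(measurements: pd.DataFrame) -> list[CellSummary]:
    """Per-cell responder calls for a whole measurement table."""
    return [classify_responder(g) for _, g in measurements.groupby("cell_id", sort=True)]


def compare_groups(
    group_a: tuple[BinnedStimulusResponse, Sequence[CellSummary]],
    group_b: tuple[BinnedStimulusResponse, Sequence[CellSummary]],
    labels: tuple[str, str] = ("A", "B"),
    mw_method: str = "normal",
) -> dict:
    """Compare two cohorts: per-bin amplitudes, responder fractions, thresholds.

    Per-bin amplitude distributions (the per-cell bin means) are compared
    with Mann-Whitney tests; bins where every contributing value in both
    groups is zero (or a group contributes nothing) are marked NA.
    Responder fractions are compared with Fisher's exact test and
    thresholds with a Mann-Whitney test.
    """
    binned_a, cells_a = group_a
    binned_b, cells_b = group_b
    if binned_a.n_cells == 0 or binned_b.n_cells == 0:
        raise ValueError("both groups must be non-empty")
    if binned_a.scheme != binned_b.scheme:
        raise ValueError("groups use different binning schemes")

    per_bin = []
    for label in binned_a.scheme.labels:
        a = binned_a.per_cell_bin_means[label].dropna().to_numpy()
        b = binned_b.per_cell_bin_means[label].dropna().to_numpy()
        if len(a) == 0 or len(b) == 0 or (np.all(a == 0) and np.all(b == 0)):
            per_bin.append({"bin": label, "p_value": None, "note": "NA",
                            f"n_{labels[0]}": len(a), f"n_{labels[1]}": len(b)})
            continue
        mw = mann_whitney(a, b, method=mw_method)
        per_bin.append({"bin": label, "p_value": mw.p_value, "note": "",
                        f"n_{labels[0]}": len(a), f"n_{labels[1]}": len(b)})

    ra = sum(c.responder for c in cells_a)
    rb = sum(c.responder for c in cells_b)
    fisher = fisher_exact(ContingencyTable2x2(
        a=ra, b=len(cells_a) - ra, c=rb, d=len(cells_b) - rb))

    ta = np.asarray([c.threshold_nm for c in cells_a if c.responder], dtype=float)
    tb = np.asarray([c.threshold_nm for c in cells_b if c.responder], dtype=float)
    threshold_test = (mann_whitney(ta, tb, method=mw_method)
                      if len(ta) and len(tb) else None)

    return {
        "labels": labels,
        "per_bin": pd.DataFrame(per_bin),
        "responders": {labels[0]: (ra, len(cells_a)), labels[1]: (rb, len(cells_b))},
        "fisher_p": fisher.p_value,
        "threshold_mean_nm": {
            labels[0]: float(np.mean(ta)) if len(ta) else None,
            labels[1]: float(np.mean(tb)) if len(tb) else None,
        },
        "threshold_p": threshold_test.p_value if threshold_test else None,
    }
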