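"""High-speed pressure-clamp (HSPC) stimulus–response analysis.

A pressure-step protocol applied to a membrane patch elicits
stretch-activated currents whose peak amplitudes grow sigmoidally with
pressure.  Each patch's normalized pressure–response curve is fitted to
a two-parameter Boltzmann

    y(P) = 1 / (1 + exp((P50 − P) / s))

where P50 is the pressure of half-maximal activation and s > 0 the
slope factor; the group P50 is the mean of the per-patch fits, not a
pooled fit.  Cell-attached protocols use suction (negative pressures) of
the same magnitudes; analysis operates on |P| throughout.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .stats import mann_whitney

__all__ = [
    "PressureFamily",
    "BoltzmannModel",
    "BoltzmannResults",
    "DEFAULT_PRESSURE_STEPS",
    "boltzmann",
    "normalize_family",
    "fit_boltzmann",
    "group_p50",
    "peak_current_summary",
]

#: Standard outside-out protocol: 10 to 150 mmHg in 20 mmHg steps.
DEFAULT_PRESSURE_STEPS = tuple(float(p) for p in range(10, 151, 20))


def boltzmann(pressure, p50: float, slope: float):
    """Normalized Boltzmann activation 1/(1 + exp((p50 − P)/slope))."""
    pressure = np.asarray(pressure, dtype=float)
    return 1.0 / (1.0 + np.exp((p50 - pressure) / slope))


@dataclass(frozen=True)
class PressureFamily:
    """Peak currents of one patch across a family of pressure steps."""

    pressures_mmHg: np.ndarray
    peak_currents_pA: np.ndarray
    patch_id: str = ""
    configuration: str = "outside-out"  # or "cell-attached"
    holding_potential_mV: float = -60.0

    def __post_init__(self) -> None:
        p = np.abs(np.asarray(self.pressures_mmHg, dtype=float))
        i = np.asarray(self.peak_currents_pA, dtype=float)
        if p.shape != i.shape or p.ndim != 1:
            raise ValueError("pressures and currents must be 1-D and equally long")
        if np.any(np.diff(p) <= 0):
            raise ValueError("pressure magnitudes must be strictly increasing")
        object.__setattr__(self, "pressures_mmHg", p)
        object.__setattr__(self, "peak_currents_pA", i)

    @property
    def max_current_pA(self) -> float:
        """Largest peak-current magnitude of the family."""
        return float(np.max(np.abs(self.peak_currents_pA)))

    @classmethod
    def from_csv(cls, path, **meta) -> "PressureFamily":
        frame = pd.read_csv(path)
        return cls(frame["pressure_mmHg"].to_numpy(), frame["peak_pA"].to_numpy(), **meta)


def normalize_family(fam: PressureFamily) -> np.ndarray:
    """Responses normalized to the family's maximal amplitude.

    Divides each peak-current magnitude by the family maximum so the
    normalized curve saturates at 1.  An all-zero family cannot be
    normalized and is rejected (flag such patches as non-responding
    upstream rather than fitting them).
    """
    if fam.max_current_pA == 0:
        raise ValueError(f"patch {fam.patch_id or '?'}: no current activation; "
                         "non-responding family excluded from fitting")
    return np.abs(fam.peak_currents_pA) / fam.max_current_pA


@dataclass(frozen=True)
class BoltzmannResults:
    """Per-patch Boltzmann fit: half-activation pressure and slope."""

    p50_mmHg: float
    slope_mmHg: float
    imax_pA: float
    fit_quality: float  # normalized RMS residual
    patch_id: str = ""
    n_points: int = 0
    converged: bool = True
    ymax: float = 1.0  # asymptote of the fit, in units of the observed maximum
    normalized: np.ndarray = field(default=None, repr=False, compare=False)
    pressures: np.ndarray = field(default=None, repr=False, compare=False)

    def predict(self, pressure) -> np.ndarray:
        """Fitted normalized response; equals ymax/2 at P = P50."""
        return self.ymax * boltzmann(pressure, self.p50_mmHg, self.slope_mmHg)

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("Boltzmann pressure-response fit\n")
        buf.write("-" * 35 + "\n")
        buf.write(f"{'patch':<22}{self.patch_id or '--'}\n")
        buf.write(f"{'P50 (mmHg)':<22}{self.p50_mmHg:.2f}\n")
        buf.write(f"{'slope (mmHg)':<22}{self.slope_mmHg:.2f}\n")
        buf.write(f"{'Imax (pA)':<22}{self.imax_pA:.2f}\n")
        buf.write(f"{'points':<22}{self.n_points}\n")
        buf.write(f"{'norm. RMS residual':<22}{self.fit_quality:.4g}\n")
        return buf.getvalue()

    def plot(self, ax=None):
        """Normalized responses with the fitted sigmoid overlaid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.pressures, self.normalized, "o", label="normalized peaks")
        grid = np.linspace(0, float(self.pressures[-1]) * 1.1, 200)
        ax.plot(grid, self.predict(grid), "-", label="Boltzmann fit")
        ax.axvline(self.p50_mmHg, ls=":", color="grey")
        ax.set_xlabel("pressure (mmHg)")
        ax.set_ylabel("I / Imax")
        ax.legend()
        return ax


class BoltzmannModel:
    """Boltzmann model of one patch's normalized pressure–response curve.

    Normalization to the family maximum happens inside ``fit``; fitted
    P50 is therefore invariant to rescaling the raw currents.  The
    saturating amplitude is a free parameter (y = ymax·Boltzmann): the
    observed maximum underestimates the asymptotic current whenever the
    protocol does not fully saturate the channel, and pinning the
    amplitude at 1 would bias P50 downward.
    """

    def __init__(self, family: PressureFamily):
        if len(family.pressures_mmHg) < 4:
            raise ValueError("need at least 4 pressure points for a Boltzmann fit")
        self.family = family

    def fit(self) -> BoltzmannResults:
        fam = self.family
        y = normalize_family(fam)
        p = fam.pressures_mmHg

        # initialization: P50 from the first half-maximum crossing,
        # slope from a fifth of the pressure span
        above = np.nonzero(y >= 0.5)[0]
        p50_0 = float(p[above[0]]) if len(above) else float(p[-1])
        span = float(p[-1] - p[0])
        slope_0 = max(span / 5.0, 1.0)

        def resid(theta):
            return theta[2] * boltzmann(p, theta[0], theta[1]) - y

        sol = least_squares(
            resid, [p50_0, slope_0, 1.0],
            bounds=([0.0, 1e-6, 0.1], [10.0 * float(p[-1]), 10.0 * span, 10.0]),
        )
        if not sol.success:
            return BoltzmannResults(np.nan, np.nan, fam.max_current_pA, np.inf,
                                    fam.patch_id, len(p), converged=False,
                                    normalized=y, pressures=p)
        p50, slope, ymax = (float(v) for v in sol.x)
        nrms = float(np.sqrt(np.mean(sol.fun**2)))
        return BoltzmannResults(p50, slope, fam.max_current_pA, nrms,
                                fam.patch_id, len(p), converged=True, ymax=ymax,
                                normalized=y, pressures=p)


def fit_boltzmann(family: PressureFamily) -> BoltzmannResults:
    """Convenience wrapper: ``BoltzmannModel(family).fit()``."""
    return BoltzmannModel(family).fit()


def group_p50(fits: Sequence[BoltzmannResults]) -> dict:
    """Group P50 as the mean of per-patch fits (± s.e.m.).

    Non-converged patches are excluded and counted.
    """
    ok = [f for f in fits if f.converged]
    values = np.asarray([f.p50_mmHg for f in ok], dtype=float)
    return {
        "p50_mean_mmHg": float(np.mean(values)) if len(values) else np.nan,
        "p50_sem_mmHg": (float(np.std(values, ddof=1) / np.sqrt(len(values)))
                         if len(values) > 1 else None),
        "n_patches": len(values),
        "n_excluded": len(fits) - len(ok),
    }


def peak_current_summary(groups: dict[str, Sequence[PressureFamily]]) -> pd.DataFrame:
    """Maximal peak current per patch, summarized per group with pairwise tests.

    For each named condition the per-patch maximal current magnitudes are
    averaged (mean ± s.e.m.); every pair of conditions is compared with a
    Mann-Whitney test.  Returns a frame with one row per group followed by
    one row per pairwise comparison.
    """
    if not groups:
        raise ValueError("no groups supplied")
    per_group = {name: np.asarray([f.max_current_pA for f in fams], dtype=float)
                 for name, fams in groups.items()}
    for name, v in per_group.items():
        if len(v) == 0:
            raise ValueError(f"group {name!r} has no patches")

    rows = []
    for name, v in per_group.items():
        rows.append({
            "kind": "group", "group": name, "n_patches": len(v),
            "mean_pA": float(np.mean(v)),
            "sem_pA": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else None,
            "p_value": None, "comparison": None,
        })
    names = list(per_group)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            mw = mann_whitney(per_group[names[i]], per_group[names[j]])
            rows.append({
                "kind": "comparison", "group": None, "n_patches": None,
                "mean_pA": None, "sem_pA": None,
                "p_value": mw.p_value,
                "comparison": f"{names[i]} vs {names[j]} (Mann-Whitney)",
            })
    return pd.DataFrame(rows)
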