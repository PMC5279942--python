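"""Kinetics of mechanically gated whole-cell currents.

A deflection or pressure stimulus applied to a mechanosensitive cell
elicits an inward current whose timing carries mechanistic information:
the *latency* between stimulus onset and current onset, the
mono-exponential *activation* time constant τ1 of the rising phase and
the *decay* constant τ2 of the relaxing phase.  Short latencies (< 5 ms)
together with fast activation (τ1 < 1 ms) are the accepted signature of
a channel gated directly by the mechanical stimulus rather than through
a second messenger.

The module provides the individual operations (event detection,
activation and decay fits, the rapid-gating classifier) and a
:class:`CurrentKineticsModel` that bundles them statsmodels-style:
``CurrentKineticsModel(trace).fit()`` returns a :class:`CurrentKinetics`
results object with a ``summary()`` table.

Sign convention: inward currents are negative in raw traces; every
reported amplitude is a positive magnitude, with the sign retained in
``amplitude_sign``.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.optimize import least_squares

from .stats import mann_whitney

__all__ = [
    "CurrentTrace",
    "CurrentKinetics",
    "CurrentKineticsModel",
    "EventDetection",
    "detect_event",
    "fit_activation",
    "fit_decay",
    "classify_rapid",
    "rectification_summary",
    "RAPID_LATENCY_MS",
    "RAPID_TAU1_MS",
]

#: Latency bound (ms) below which a current is classed as rapidly gated.
RAPID_LATENCY_MS = 5.0
#: Activation bound (ms) for the stricter direct-gating flag.
RAPID_TAU1_MS = 1.0


@dataclass(frozen=True)
class CurrentTrace:
    """Sampled whole-cell current with a stimulus-onset annotation.

    Parameters
    ----------
    samples : ndarray
        Current samples, pA.  Inward currents are negative.
    sampling_rate : float
        Hz; acquisition default is 10 kHz.
    stimulus_onset : float
        Time of stimulus application, ms from the first sample.
    holding_potential : float
        mV (−40 for chondrocytes, −60 for HEK-style recordings).
    """

    samples: np.ndarray
    sampling_rate: float
    stimulus_onset: float
    holding_potential: float = -40.0
    cell_id: str = ""
    stimulus_id: str = ""
    pilus_id: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not 0 <= self.stimulus_onset <= self.duration_ms:
            raise ValueError("stimulus_onset must lie within the trace")

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate

    @property
    def duration_ms(self) -> float:
        return len(self.samples) * 1000.0 / self.sampling_rate

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt_ms

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.time_ms, "current_pA": self.samples})

    @classmethod
    def from_csv(cls, path, *, stimulus_onset: float, holding_potential: float = -40.0,
                 **ids) -> "CurrentTrace":
        """Read a (time_ms, current_pA) CSV; the time column sets the rate."""
        frame = pd.read_csv(path)
        t = frame["time_ms"].to_numpy(dtype=float)
        dt = float(np.median(np.diff(t)))
        return cls(samples=frame["current_pA"].to_numpy(dtype=float),
                   sampling_rate=1000.0 / dt, stimulus_onset=stimulus_onset,
                   holding_potential=holding_potential, **ids)


@dataclass(frozen=True)
class EventDetection:
    responded: bool
    onset_ms: float | None
    latency_ms: float | None
    baseline_mean: float
    baseline_sd: float
    threshold_pA: float


@dataclass(frozen=True)
class CurrentKinetics:
    """Extracted kinetics of one stimulus-evoked current.

    Amplitude is a positive magnitude (pA); ``amplitude_sign`` records
    the polarity of the underlying deflection from baseline.  ``tau1`` /
    ``tau2`` are None when the corresponding fit was infeasible even
    though the cell responded (sparse or truncated currents).
    """

    responded: bool
    latency_ms: float | None = None
    tau1_ms: float | None = None
    tau2_ms: float | None = None
    peak_amplitude_pA: float = 0.0
    amplitude_sign: int = 0
    rapid_gating: bool = False
    direct_gating: bool = False
    fit_quality_tau1: float | None = None
    fit_quality_tau2: float | None = None
    peak_time_ms: float | None = None
    detection: EventDetection | None = None
    trace: CurrentTrace | None = field(default=None, repr=False, compare=False)

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write("Mechanically gated current kinetics\n")
        buf.write("-" * 39 + "\n")
        rows = [
            ("responded", self.responded),
            ("latency (ms)", _fmt(self.latency_ms)),
            ("tau1 activation (ms)", _fmt(self.tau1_ms)),
            ("tau2 decay (ms)", _fmt(self.tau2_ms)),
            ("peak amplitude (pA)", _fmt(self.peak_amplitude_pA)),
            ("rapid gating (latency < 5 ms)", self.rapid_gating),
            ("direct gating (+ tau1 < 1 ms)", self.direct_gating),
        ]
        for name, value in rows:
            buf.write(f"{name:<32}{value}\n")
        return buf.getvalue()

    def to_dict(self) -> dict:
        return {
            "responded": self.responded,
            "latency_ms": self.latency_ms,
            "tau1_ms": self.tau1_ms,
            "tau2_ms": self.tau2_ms,
            "peak_amplitude_pA": self.peak_amplitude_pA,
            "rapid_gating": self.rapid_gating,
            "direct_gating": self.direct_gating,
        }


def _fmt(x) -> str:
    return "--" if x is None else f"{x:.3f}"


def detect_event(
    trace: CurrentTrace,
    baseline_window_ms: float = 10.0,
    k_sd: float = 5.0,
    sustained_ms: float = 0.3,
    min_amplitude_pA: float = 0.0,
) -> EventDetection:
    """Detect a stimulus-evoked current and measure its latency.

    The baseline is the ``baseline_window_ms`` immediately preceding the
    stimulus.  The onset is the first post-stimulus time at which the
    current deviates from the baseline mean by more than
    ``k_sd`` × baseline SD (but at least ``min_amplitude_pA``) and stays
    beyond that threshold for ``sustained_ms``.
    """
    dt = trace.dt_ms
    n_base = int(round(baseline_window_ms / dt))
    i_stim = int(round(trace.stimulus_onset / dt))
    if n_base < 10:
        raise ValueError("baseline window must span at least 10 samples")
    if i_stim - n_base < 0:
        raise ValueError("baseline window precedes the start of the trace")

    baseline = trace.samples[i_stim - n_base : i_stim]
    mu, sd = float(np.mean(baseline)), float(np.std(baseline))
    thresh = max(k_sd * sd, min_amplitude_pA)
    if thresh == 0.0:
        thresh = np.finfo(float).tiny  # noiseless baseline: any deviation counts

    dev = np.abs(trace.samples[i_stim:] - mu)
    n_sustain = max(1, int(round(sustained_ms / dt)))
    above = dev > thresh
    # first run of >= n_sustain consecutive threshold crossings
    run = 0
    onset_idx = None
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= n_sustain:
            onset_idx = i - n_sustain + 1
            break
    if onset_idx is None:
        return EventDetection(False, None, None, mu, sd, thresh)
    onset_ms = (i_stim + onset_idx) * dt
    return EventDetection(True, onset_ms, onset_ms - trace.stimulus_onset, mu, sd, thresh)


def _peak_index(trace: CurrentTrace, onset_idx: int, end_idx: int | None,
                baseline_mean: float) -> int:
    """Extremum of |I − baseline| between onset and window end."""
    if end_idx is None:
        end_idx = len(trace.samples)
    seg = np.abs(trace.samples[onset_idx:end_idx] - baseline_mean)
    return onset_idx + int(np.argmax(seg))


@dataclass(frozen=True)
class ActivationFit:
    tau1_ms: float | None
    fit_quality: float | None
    onset_ms: float | None  # fitted onset t0 (equals the input when not refined)


def fit_activation(
    trace: CurrentTrace,
    onset_ms: float,
    peak_time_ms: float,
    baseline_mean: float = 0.0,
    refine_onset: bool = False,
    pre_window_ms: float = 2.0,
) -> ActivationFit:
    """Mono-exponential activation fit I(t) = A·(1 − exp(−(t−t0)/τ1)).

    Fits the magnitude of the baseline-subtracted current on
    [onset, peak].  With ``refine_onset`` the window is extended back by
    ``pre_window_ms`` (not before the stimulus) and the onset time t0 is
    a free parameter: a threshold detector necessarily reports the onset
    late (the current must first clear the noise band), and pinning t0
    there biases τ1 downward.  Returns τ1 = None when the window holds
    fewer than 5 samples.
    """
    if onset_ms >= peak_time_ms:
        raise ValueError("onset must precede the peak")
    dt = trace.dt_ms
    start_ms = (max(trace.stimulus_onset, onset_ms - pre_window_ms)
                if refine_onset else onset_ms)
    i0, i1 = int(round(start_ms / dt)), int(round(peak_time_ms / dt)) + 1
    t = trace.time_ms[i0:i1]
    raw = trace.samples[i0:i1] - baseline_mean
    sign = np.sign(raw[-1]) or 1.0  # event polarity from the peak end
    y = sign * raw
    if len(t) < 5:
        return ActivationFit(None, None, None)

    a0 = max(float(y[-1]), 1e-12)
    tau0 = max((peak_time_ms - onset_ms) / 3.0, dt)

    if refine_onset:
        def resid(p):
            a, tau, t0 = p
            return a * -np.expm1(-np.clip(t - t0, 0, None) / tau) - y
        p_init = [a0, tau0, onset_ms]
        bounds = ([0, dt / 100, start_ms], [np.inf, np.inf, peak_time_ms - dt])
    else:
        def resid(p):
            a, tau = p
            return a * -np.expm1(-(t - onset_ms) / tau) - y
        p_init = [a0, tau0]
        bounds = ([0, dt / 100], [np.inf, np.inf])

    sol = least_squares(resid, p_init, bounds=bounds)
    if not sol.success:
        return ActivationFit(None, None, None)
    tau1 = float(sol.x[1])
    t0 = float(sol.x[2]) if refine_onset else onset_ms
    nrms = float(np.sqrt(np.mean(sol.fun**2)) / max(sol.x[0], 1e-12))
    return ActivationFit(tau1, nrms, t0)


def fit_decay(
    trace: CurrentTrace,
    peak_time_ms: float,
    window_end_ms: float | None = None,
    baseline_mean: float = 0.0,
) -> tuple[float | None, float | None]:
    """Mono-exponential decay fit I(t) = A·exp(−(t−t_peak)/τ2) + C.

    The window runs from the peak to ``window_end_ms`` (default: first
    baseline re-crossing after the peak, or the end of the trace).
    Returns (tau2_ms, normalized RMS residual) or (None, None) when
    unfittable.
    """
    dt = trace.dt_ms
    i0 = int(round(peak_time_ms / dt))
    raw = trace.samples - baseline_mean
    sign = np.sign(raw[i0]) or 1.0  # event polarity at the peak
    y_full = sign * raw
    if window_end_ms is None:
        below = np.nonzero(y_full[i0:] <= 0)[0]
        i1 = i0 + int(below[0]) + 1 if len(below) else len(y_full)
    else:
        if window_end_ms <= peak_time_ms:
            raise ValueError("window end must follow the peak")
        i1 = int(round(window_end_ms / dt)) + 1
    t = trace.time_ms[i0:i1]
    y = y_full[i0:i1]
    if len(t) < 5:
        return None, None

    a0 = max(float(y[0] - y[-1]), 1e-12)
    span = t[-1] - t[0]

    def resid(p):
        a, tau, c = p
        return a * np.exp(-(t - t[0]) / tau) + c - y

    sol = least_squares(
        resid, [a0, max(span / 3.0, dt), float(y[-1])],
        bounds=([0, dt / 100, -np.inf], [np.inf, np.inf, np.inf]),
    )
    if not sol.success:
        return None, None
    tau2 = float(sol.x[1])
    nrms = float(np.sqrt(np.mean(sol.fun**2)) / max(sol.x[0], 1e-12))
    return tau2, nrms


def classify_rapid(
    kin: CurrentKinetics,
    latency_bound_ms: float = RAPID_LATENCY_MS,
    tau1_bound_ms: float = RAPID_TAU1_MS,
) -> CurrentKinetics:
    """Apply the rapid/direct-gating classification to measured kinetics.

    ``rapid_gating`` requires latency strictly below ``latency_bound_ms``;
    ``direct_gating`` additionally requires τ1 strictly below
    ``tau1_bound_ms``.  Returns an updated results object.
    """
    if not kin.responded:
        raise ValueError("classification requires a responding current")
    rapid = kin.latency_ms is not None and kin.latency_ms < latency_bound_ms
    direct = rapid and kin.tau1_ms is not None and kin.tau1_ms < tau1_bound_ms
    return replace(kin, rapid_gating=rapid, direct_gating=direct)


class CurrentKineticsModel:
    """Kinetics extraction for one stimulus-annotated current trace.

    ``fit()`` runs event detection, locates the peak, fits the
    activation and decay exponentials and applies the gating classifier,
    returning a :class:`CurrentKinetics` results object.

    Parameters mirror the individual operations; ``stimulus_end_ms``
    bounds the peak search (default: end of trace).
    """

    def __init__(
        self,
        trace: CurrentTrace,
        baseline_window_ms: float = 10.0,
        k_sd: float = 5.0,
        sustained_ms: float = 0.3,
        stimulus_end_ms: float | None = None,
        refine_onset: bool = True,
    ):
        self.trace = trace
        self.baseline_window_ms = baseline_window_ms
        self.k_sd = k_sd
        self.sustained_ms = sustained_ms
        self.stimulus_end_ms = stimulus_end_ms
        self.refine_onset = refine_onset

    #: samples in the boxcar used only to locate the peak and the decay
    #: end under noise; raw samples feed every fit and the amplitude.
    _SMOOTH_SAMPLES = 5

    def fit(self) -> CurrentKinetics:
        trace = self.trace
        det = detect_event(trace, self.baseline_window_ms, self.k_sd, self.sustained_ms)
        if not det.responded:
            return CurrentKinetics(responded=False, detection=det, trace=trace)

        dt = trace.dt_ms
        onset_idx = int(round(det.onset_ms / dt))
        end_idx = (int(round(self.stimulus_end_ms / dt))
                   if self.stimulus_end_ms is not None else len(trace.samples))

        dev = np.abs(trace.samples - det.baseline_mean)
        smooth_dev = ndimage.uniform_filter1d(dev, self._SMOOTH_SAMPLES)
        peak_idx = onset_idx + int(np.argmax(smooth_dev[onset_idx:end_idx]))
        peak_time = peak_idx * dt
        # amplitude from the raw extremum (exact on clean traces)
        amp_idx = onset_idx + int(np.argmax(dev[onset_idx:end_idx]))
        amplitude = float(dev[amp_idx])
        sign = int(np.sign(trace.samples[amp_idx] - det.baseline_mean)) or 1

        tau1 = q1 = tau2 = q2 = None
        latency = det.latency_ms
        if peak_idx > onset_idx:
            act = fit_activation(trace, det.onset_ms, peak_time,
                                 det.baseline_mean, self.refine_onset)
            tau1, q1 = act.tau1_ms, act.fit_quality
            if self.refine_onset and act.onset_ms is not None:
                latency = act.onset_ms - trace.stimulus_onset

        # decay window ends where the smoothed current has relaxed to
        # within 5% of the peak deviation (sustained), or at the trace end
        floor = 0.05 * smooth_dev[peak_idx]
        relaxed = smooth_dev[peak_idx:] < floor
        window_end = None
        run = 0
        for i, flag in enumerate(relaxed):
            run = run + 1 if flag else 0
            if run >= self._SMOOTH_SAMPLES:
                window_end = (peak_idx + i - run + 1) * dt
                break
        if window_end is not None and window_end - peak_time < 5 * dt:
            window_end = None
        tau2, q2 = fit_decay(trace, peak_time, window_end, det.baseline_mean)

        kin = CurrentKinetics(
            responded=True, latency_ms=latency, tau1_ms=tau1, tau2_ms=tau2,
            peak_amplitude_pA=amplitude, amplitude_sign=sign,
            fit_quality_tau1=q1, fit_quality_tau2=q2,
            peak_time_ms=peak_time, detection=det, trace=trace,
        )
        return classify_rapid(kin)


def kinetics_table(results: Sequence[CurrentKinetics], group: str = "") -> pd.DataFrame:
    """Per-event kinetics as a tidy frame (one row per stimulus)."""
    rows = [dict(group=group, **k.to_dict()) for k in results]
    return pd.DataFrame(rows)


def summarize_kinetics(results: Sequence[CurrentKinetics]) -> pd.DataFrame:
    """Group mean ± s.e.m. and median of each kinetic parameter.

    Non-responding sweeps are excluded; τ columns additionally drop
    unfittable events, mirroring how sparse currents are reported.
    """
    resp = [k for k in results if k.responded]
    out = []
    for name, values in [
        ("latency_ms", [k.latency_ms for k in resp]),
        ("tau1_ms", [k.tau1_ms for k in resp if k.tau1_ms is not None]),
        ("tau2_ms", [k.tau2_ms for k in resp if k.tau2_ms is not None]),
        ("peak_amplitude_pA", [k.peak_amplitude_pA for k in resp]),
    ]:
        v = np.asarray([x for x in values if x is not None], dtype=float)
        out.append({
            "parameter": name,
            "n": len(v),
            "mean": float(np.mean(v)) if len(v) else np.nan,
            "sem": float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else np.nan,
            "median": float(np.median(v)) if len(v) else np.nan,
        })
    return pd.DataFrame(out)


def rectification_summary(
    events_neg: Sequence[CurrentKinetics],
    events_pos: Sequence[CurrentKinetics],
    labels: tuple[str, str] = ("-60 mV", "+60 mV"),
) -> pd.DataFrame:
    """Voltage dependence of amplitude and decay across two holding potentials.

    Compares peak-amplitude magnitudes and τ2 between events recorded at
    negative and positive potentials (Mann-Whitney).  A channel whose
    decay and amplitude are voltage independent shows non-significant
    contrasts; an outwardly rectifying decay shows larger τ2 at the
    positive potential.
    """
    rows = []
    for param, getter in [("peak_amplitude_pA", lambda k: k.peak_amplitude_pA),
                          ("tau2_ms", lambda k: k.tau2_ms)]:
        a = np.asarray([getter(k) for k in events_neg
                        if k.responded and getter(k) is not None], dtype=float)
        b = np.asarray([getter(k) for k in events_pos
                        if k.responded and getter(k) is not None], dtype=float)
        if len(a) < 3 or len(b) < 3:
            raise ValueError(f"need at least 3 events per potential for {param}")
        mw = mann_whitney(a, b)
        rows.append({
            "parameter": param,
            f"mean {labels[0]}": float(np.mean(a)),
            f"sem {labels[0]}": float(np.std(a, ddof=1) / np.sqrt(len(a))),
            f"n {labels[0]}": len(a),
            f"mean {labels[1]}": float(np.mean(b)),
            f"sem {labels[1]}": float(np.std(b, ddof=1) / np.sqrt(len(b))),
            f"n {labels[1]}": len(b),
            "contrast": float(np.mean(b) - np.mean(a)),
            "U": mw.u_statistic,
            "p_value": mw.p_value,
        })
    return pd.DataFrame(rows)
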