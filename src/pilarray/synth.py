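"""Seeded synthetic-data generators for every input class of the pipeline.

Wet-lab recordings of pillar-array mechanotransduction experiments are
not redistributable, so the pipeline ships generators that emulate each
input with the statistical structure the analysis expects:

* bright-field pillar-array scenes (before/during/after frames) with a
  known sub-pixel deflection of one designated pilus;
* whole-cell current traces with mechanically gated events of known
  latency, activation (τ1) and decay (τ2) kinetics;
* pressure-clamp step families following a Boltzmann pressure dependence;
* cell populations with per-cell responder outcomes and gating
  thresholds;
* calcium-imaging fluorescence traces with agonist-epoch transients.

Every generator is driven by a :class:`numpy.random.Generator` (or an
integer seed) and returns the exact ground truth alongside the data, so
each analysis stage can be validated by recovery.  Identical spec + seed
gives bit-identical output.

Per-event kinetic and amplitude parameters are drawn log-normally around
the phenotype means (the quantities are positive and their empirical
distributions are right-skewed); a zero SD collapses the draw to the
mean exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .calcium import Epoch, FluorescenceTrace
from .kinetics import CurrentTrace
from .pressure import DEFAULT_PRESSURE_STEPS, PressureFamily, boltzmann

__all__ = [
    "ImageSceneSpec",
    "PillarScene",
    "ChannelPhenotype",
    "TraceSpec",
    "PHENOTYPES",
    "generate_pillar_scene",
    "generate_current_trace",
    "generate_pressure_family",
    "generate_population",
    "generate_fluorescence_trace",
    "default_calcium_epochs",
    "write_scene",
    "read_scene",
    "child_seed",
]

FRAME_ROLES = ("before", "during", "after")


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def child_seed(seed: int, stage: str) -> int:
    """Stable per-stage child seed (< 2³¹) from a global seed and stage name."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def _lognormal_draw(rng: np.random.Generator, mean: float, sd: float, size=None):
    """Log-normal with the given arithmetic mean and SD; sd = 0 → the mean."""
    if mean <= 0:
        raise ValueError("log-normal mean must be positive")
    if sd == 0:
        return mean if size is None else np.full(size, mean)
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, np.sqrt(sigma2), size=size)


# ---------------------------------------------------------------------------
# pillar-array image scenes


@dataclass(frozen=True)
class ImageSceneSpec:
    """Parameters of one synthetic before/during/after pillar-array scene.

    Defaults model a 40× bright-field view of a PDMS array: camera pixel
    161 nm on the specimen, spot σ 600 nm, square pitch 4.16 µm (chosen
    so neighbouring spots are separated by more than 3σ).  Exactly one
    pilus (the central one) carries the true deflection, applied in the
    *during* frame only.
    """

    grid_pitch_nm: float = 4160.0
    spot_sigma_nm: float = 600.0
    pixel_size_nm: float = 161.0
    peak_amplitude: float = 2000.0
    background: float = 200.0
    read_noise_sd: float = 15.0
    shot_noise: bool = False
    true_deflection_nm: tuple[float, float] = (0.0, 0.0)
    n_pillars_side: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if self.spot_sigma_nm <= self.pixel_size_nm / 2:
            raise ValueError("spot_sigma_nm must exceed half a pixel (resolvable spots)")
        if self.grid_pitch_nm <= 0 or self.n_pillars_side < 1:
            raise ValueError("invalid grid")
        d = np.hypot(*self.true_deflection_nm)
        if d > self.grid_pitch_nm / 2:
            raise ValueError(
                f"deflection {d:.0f} nm exceeds half the pitch "
                f"({self.grid_pitch_nm / 2:.0f} nm): pillar collision")


@dataclass(frozen=True)
class PillarScene:
    """Generated frames plus the exact ground truth."""

    frames: dict  # role -> 2-D ndarray
    truth: dict
    spec: ImageSceneSpec

    @property
    def designated_roi_center(self) -> tuple[float, float]:
        return tuple(self.truth["centers_px"]["before"][self.truth["designated_pilus"]])


def generate_pillar_scene(spec: ImageSceneSpec) -> PillarScene:
    """Render one before/during/after scene of Gaussian pillar spots.

    Each pilus appears as an isotropic 2D Gaussian of the given σ and
    peak amplitude on a constant background; optional Poisson shot noise
    and Gaussian read noise are added independently per frame.  The
    central pilus is displaced by ``true_deflection_nm`` in the *during*
    frame only; the truth record stores every exact center in pixels.
    """
    rng = np.random.default_rng(spec.seed)
    pitch_px = spec.grid_pitch_nm / spec.pixel_size_nm
    sigma_px = spec.spot_sigma_nm / spec.pixel_size_nm
    n = spec.n_pillars_side
    margin = pitch_px / 2.0
    extent = (n - 1) * pitch_px + 2 * margin
    shape = (int(np.ceil(extent)), int(np.ceil(extent)))

    base_centers = {}
    for i in range(n):
        for j in range(n):
            base_centers[f"p{i}{j}"] = np.array(
                [margin + i * pitch_px, margin + j * pitch_px])
    designated = f"p{n // 2}{n // 2}"
    shift_px = np.asarray(spec.true_deflection_nm, dtype=float) / spec.pixel_size_nm

    rr, cc = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    frames, centers_px = {}, {}
    for role in FRAME_ROLES:
        img = np.full(shape, float(spec.background))
        role_centers = {}
        for pid, c in base_centers.items():
            center = c + shift_px if (role == "during" and pid == designated) else c
            role_centers[pid] = (float(center[0]), float(center[1]))
            img += spec.peak_amplitude * np.exp(
                -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma_px**2))
        if spec.shot_noise:
            img = rng.poisson(np.clip(img, 0, None)).astype(float)
        if spec.read_noise_sd > 0:
            img = img + rng.normal(0.0, spec.read_noise_sd, size=shape)
        frames[role] = img
        centers_px[role] = role_centers

    truth = {
        "designated_pilus": designated,
        "true_deflection_nm": tuple(float(v) for v in spec.true_deflection_nm),
        "true_deflection_magnitude_nm": float(np.hypot(*spec.true_deflection_nm)),
        "centers_px": centers_px,
        "pixel_size_nm": spec.pixel_size_nm,
        "spot_sigma_px": sigma_px,
    }
    return PillarScene(frames=frames, truth=truth, spec=spec)


def write_scene(scene: PillarScene, tiff_path) -> None:
    """Multi-page TIFF (one page per frame role) plus a sidecar truth JSON."""
    import tifffile

    tiff_path = Path(tiff_path)
    tifffile.imwrite(tiff_path,
                     np.stack([scene.frames[r] for r in FRAME_ROLES]).astype(np.float32),
                     photometric="minisblack", planarconfig="contig",
                     metadata={"frame_roles": list(FRAME_ROLES)})
    sidecar = {"truth": scene.truth, "spec": asdict(scene.spec)}
    tiff_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_scene(tiff_path) -> PillarScene:
    """Read a scene written by :func:`write_scene`."""
    import tifffile

    tiff_path = Path(tiff_path)
    stack = tifffile.imread(tiff_path)
    meta = json.loads(tiff_path.with_suffix(".json").read_text())
    spec_dict = meta["spec"]
    spec_dict["true_deflection_nm"] = tuple(spec_dict["true_deflection_nm"])
    frames = {role: stack[i].astype(float) for i, role in enumerate(FRAME_ROLES)}
    return PillarScene(frames=frames, truth=meta["truth"],
                       spec=ImageSceneSpec(**spec_dict))


# ---------------------------------------------------------------------------
# current traces


@dataclass(frozen=True)
class ChannelPhenotype:
    """Statistical phenotype of a mechanosensitive cell population.

    Means and SDs describe the *population* distributions from which
    per-event kinetics and per-cell properties are drawn:
    latency and τ1/τ2 of the gated current, peak amplitude, the
    probability that a cell responds to any deflection at all, and the
    distribution of per-cell gating thresholds.  ``rectifying_tau2``
    marks channels whose decay slows at positive potentials.
    """

    name: str
    latency_mean_ms: float = 3.6
    latency_sd_ms: float = 3.0
    tau1_mean_ms: float = 1.7
    tau1_sd_ms: float = 3.0
    tau2_mean_ms: float = 12.2
    tau2_sd_ms: float = 10.0
    peak_amp_mean_pA: float = 150.0
    peak_amp_sd_pA: float = 100.0
    responder_prob: float = 24 / 27
    threshold_mean_nm: float = 252.0
    threshold_sd_nm: float = 333.0
    rectifying_tau2: bool = False
    holding_potential_mV: float = -40.0

    def __post_init__(self) -> None:
        for name in ("latency_mean_ms", "tau1_mean_ms", "tau2_mean_ms",
                     "peak_amp_mean_pA", "threshold_mean_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 <= self.responder_prob <= 1:
            raise ValueError("responder_prob must lie in [0, 1]")


#: Reference phenotypes.  SDs are population SDs reconstructed from the
#: reported s.e.m. and n of each cohort; amplitudes for the HEK-style
#: phenotypes follow the reported voltage-(in)dependence contrasts.
PHENOTYPES: dict[str, ChannelPhenotype] = {
    "chondrocyte-WT": ChannelPhenotype(
        name="chondrocyte-WT", latency_mean_ms=3.6, latency_sd_ms=3.0,
        tau1_mean_ms=1.7, tau1_sd_ms=3.0, tau2_mean_ms=12.0, tau2_sd_ms=10.0,
        peak_amp_mean_pA=150.0, peak_amp_sd_pA=100.0,
        responder_prob=24 / 27, threshold_mean_nm=252.0, threshold_sd_nm=333.0,
        holding_potential_mV=-40.0),
    "dedifferentiated": ChannelPhenotype(
        name="dedifferentiated", latency_mean_ms=3.1, latency_sd_ms=2.6,
        tau1_mean_ms=1.4, tau1_sd_ms=2.6, tau2_mean_ms=15.0, tau2_sd_ms=30.0,
        peak_amp_mean_pA=150.0, peak_amp_sd_pA=100.0,
        responder_prob=15 / 17, threshold_mean_nm=59.0, threshold_sd_nm=50.0,
        holding_potential_mV=-40.0),
    "TRPV4-like": ChannelPhenotype(
        name="TRPV4-like", latency_mean_ms=2.0, latency_sd_ms=1.0,
        tau1_mean_ms=0.5, tau1_sd_ms=0.3, tau2_mean_ms=12.2, tau2_sd_ms=15.0,
        peak_amp_mean_pA=147.0, peak_amp_sd_pA=110.0,
        responder_prob=1.0, threshold_mean_nm=150.0, threshold_sd_nm=80.0,
        rectifying_tau2=False, holding_potential_mV=-60.0),
    "PIEZO1-like": ChannelPhenotype(
        name="PIEZO1-like", latency_mean_ms=2.5, latency_sd_ms=1.2,
        tau1_mean_ms=2.5, tau1_sd_ms=1.5, tau2_mean_ms=20.0, tau2_sd_ms=15.0,
        peak_amp_mean_pA=120.0, peak_amp_sd_pA=80.0,
        responder_prob=1.0, threshold_mean_nm=150.0, threshold_sd_nm=80.0,
        rectifying_tau2=True, holding_potential_mV=-60.0),
}


@dataclass(frozen=True)
class TraceSpec:
    """Acquisition parameters of one synthetic current trace.

    Defaults follow the recording conditions: 10 kHz sampling with a
    3 kHz low-pass (4-pole Bessel, causal).  ``filter_cutoff_hz = None``
    disables filtering.
    """

    sampling_rate_hz: float = 10_000.0
    filter_cutoff_hz: float | None = 3000.0
    filter_order: int = 4
    duration_ms: float = 200.0
    baseline_noise_sd_pA: float = 0.0
    holding_potential_mV: float = -40.0
    stimulus_onset_ms: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if (self.filter_cutoff_hz is not None
                and not 0 < self.filter_cutoff_hz < self.sampling_rate_hz / 2):
            raise ValueError("filter_cutoff_hz must lie below Nyquist")
        if not 0 <= self.stimulus_onset_ms < self.duration_ms:
            raise ValueError("stimulus_onset_ms must lie within the trace")


def _event_waveform(t_ms, onset_ms, amp, tau1, tau2, rise_span=5.0):
    """Rise A(1−exp(−t/τ1)) for ``rise_span``·τ1, then decay A_eff·exp(−t/τ2).

    Returns (waveform, achieved peak amplitude, peak time).
    """
    peak_ms = onset_ms + rise_span * tau1
    a_eff = amp * -np.expm1(-rise_span)
    wave = np.zeros_like(t_ms)
    rising = (t_ms >= onset_ms) & (t_ms < peak_ms)
    wave[rising] = amp * -np.expm1(-(t_ms[rising] - onset_ms) / tau1)
    decaying = t_ms >= peak_ms
    wave[decaying] = a_eff * np.exp(-(t_ms[decaying] - peak_ms) / tau2)
    return wave, a_eff, peak_ms


def generate_current_trace(
    spec: TraceSpec,
    phen: ChannelPhenotype,
    deflection_nm: float,
    rng=None,
    *,
    responder: bool | None = None,
    threshold_nm: float | None = None,
) -> tuple[CurrentTrace, dict]:
    """One whole-cell current trace for a deflection stimulus, plus truth.

    The cell's responder status and gating threshold are drawn from the
    phenotype unless supplied (as they are when a population table drives
    the simulation).  A gated event appears only when the cell responds
    and the deflection reaches its threshold; the event is an inward
    deflection from baseline at negative holding potentials and outward
    at positive ones.  The clean waveform is low-pass filtered causally;
    baseline noise of the specified SD is then added, so the trace
    baseline SD equals ``baseline_noise_sd_pA`` exactly.

    The truth record holds the drawn latency, τ1, τ2 and the achieved
    peak amplitude (the rise is truncated at 5·τ1, reaching 99.3% of the
    asymptotic amplitude).
    """
    if deflection_nm < 0:
        raise ValueError("deflection must be non-negative")
    rng = _rng(spec.seed if rng is None else rng)

    if responder is None:
        responder = bool(rng.random() < phen.responder_prob)
    if threshold_nm is None:
        threshold_nm = float(_lognormal_draw(rng, phen.threshold_mean_nm,
                                             phen.threshold_sd_nm))

    n = int(round(spec.duration_ms * spec.sampling_rate_hz / 1000.0))
    t_ms = np.arange(n) * 1000.0 / spec.sampling_rate_hz
    sign = -1.0 if spec.holding_potential_mV < 0 else 1.0

    truth: dict = {"responded": False, "responder_cell": responder,
                   "threshold_nm": threshold_nm}
    clean = np.zeros(n)
    if responder and deflection_nm >= threshold_nm:
        latency = float(_lognormal_draw(rng, phen.latency_mean_ms, phen.latency_sd_ms))
        tau1 = float(_lognormal_draw(rng, phen.tau1_mean_ms, phen.tau1_sd_ms))
        tau2_mean = phen.tau2_mean_ms
        if phen.rectifying_tau2 and spec.holding_potential_mV > 0:
            tau2_mean *= 2.0  # decay slows at depolarized potentials
        tau2 = float(_lognormal_draw(rng, tau2_mean, phen.tau2_sd_ms))
        amp = float(_lognormal_draw(rng, phen.peak_amp_mean_pA, phen.peak_amp_sd_pA))
        onset = spec.stimulus_onset_ms + latency
        wave, a_eff, peak_ms = _event_waveform(t_ms, onset, amp, tau1, tau2)
        clean = sign * wave
        truth.update(responded=True, latency_ms=latency, tau1_ms=tau1,
                     tau2_ms=tau2, amplitude_pA=a_eff, onset_ms=onset,
                     peak_time_ms=peak_ms, sign=int(sign))

    if spec.filter_cutoff_hz is not None:
        sos = _signal.bessel(spec.filter_order, spec.filter_cutoff_hz,
                             fs=spec.sampling_rate_hz, output="sos", norm="mag")
        clean = _signal.sosfilt(sos, clean)
    if spec.baseline_noise_sd_pA > 0:
        clean = clean + rng.normal(0.0, spec.baseline_noise_sd_pA, size=n)

    trace = CurrentTrace(samples=clean, sampling_rate=spec.sampling_rate_hz,
                         stimulus_onset=spec.stimulus_onset_ms,
                         holding_potential=spec.holding_potential_mV)
    return trace, truth


# ---------------------------------------------------------------------------
# pressure-clamp families


def generate_pressure_family(
    p50_mmHg: float,
    slope_mmHg: float,
    imax_pA: float,
    steps_mmHg=DEFAULT_PRESSURE_STEPS,
    noise_sd_pA: float = 0.0,
    rng=None,
    seed: int = 0,
    patch_id: str = "",
    configuration: str = "outside-out",
) -> tuple[PressureFamily, dict]:
    """Peak currents of one patch across a pressure-step family.

    Per-step peak current is imax / (1 + exp((p50 − P)/slope)) plus
    Gaussian noise.  The default protocol is 10–150 mmHg in 20 mmHg
    steps; cell-attached families use the same magnitudes as suction.
    """
    if slope_mmHg <= 0:
        raise ValueError("Boltzmann slope must be positive")
    steps = np.asarray(steps_mmHg, dtype=float)
    if np.any(np.diff(steps) <= 0):
        raise ValueError("pressure steps must be strictly increasing")
    rng = _rng(seed if rng is None else rng)
    clean = imax_pA * boltzmann(steps, p50_mmHg, slope_mmHg)
    noisy = clean + (rng.normal(0.0, noise_sd_pA, size=len(steps))
                     if noise_sd_pA > 0 else 0.0)
    fam = PressureFamily(steps, noisy, patch_id=patch_id, configuration=configuration)
    truth = {"p50_mmHg": p50_mmHg, "slope_mmHg": slope_mmHg, "imax_pA": imax_pA,
             "clean_currents_pA": clean}
    return fam, truth


# ---------------------------------------------------------------------------
# cell populations


def _draw_threshold(rng, phen: ChannelPhenotype, upper_nm: float) -> float:
    """Per-cell gating threshold, truncated to (0, upper] by redraw."""
    if phen.threshold_sd_nm == 0:
        return min(phen.threshold_mean_nm, upper_nm)
    for _ in range(1000):
        value = float(_lognormal_draw(rng, phen.threshold_mean_nm, phen.threshold_sd_nm))
        if value <= upper_nm:
            return value
    return upper_nm


def generate_population(
    phenotypes: dict[str, ChannelPhenotype],
    n_cells: dict[str, int],
    seed: int = 0,
    *,
    n_stimuli: int = 12,
    stim_range_nm: tuple[float, float] = (10.0, 1000.0),
    stim_jitter: float = 0.1,
    amp_d50_nm: float = 150.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate stimulation campaigns over cohorts of cells.

    For each cell: a responder flag (Bernoulli with the phenotype's
    responder probability) and a gating threshold (log-normal, truncated
    to the stimulated range).  Each cell receives an increasing series of
    ``n_stimuli`` deflections spanning ``stim_range_nm`` geometrically
    with multiplicative jitter, the largest always equal to the range
    maximum, emulating an experimenter probing up to the top of the
    range.  A stimulus at or above the cell's threshold gates a current
    whose amplitude is drawn from the phenotype and scaled by a
    saturating function of deflection (half-saturation ``amp_d50_nm``).

    Returns ``(measurements, cells)``: one row per individual deflection
    (group, cell_id, deflection_nm, responded, amplitude_pA) and one row
    per cell with the ground-truth responder flag and threshold.
    """
    if set(phenotypes) != set(n_cells):
        raise ValueError("phenotypes and n_cells must share group names")
    rng = np.random.default_rng(seed)
    lo, hi = stim_range_nm
    base_series = np.geomspace(lo, hi, n_stimuli)
    amp_norm = hi / (hi + amp_d50_nm)

    meas_rows, cell_rows = [], []
    for group in sorted(phenotypes):
        phen = phenotypes[group]
        if n_cells[group] < 1:
            raise ValueError(f"group {group!r} needs at least one cell")
        for ci in range(n_cells[group]):
            cell_id = f"{group}-c{ci:04d}"
            is_responder = bool(rng.random() < phen.responder_prob)
            threshold = _draw_threshold(rng, phen, hi) if is_responder else np.nan
            series = base_series * rng.lognormal(0.0, stim_jitter, size=n_stimuli)
            series = np.clip(np.sort(series), lo / 10, hi)
            series[-1] = hi  # the campaign always reaches the top of the range
            for d in series:
                gated = bool(is_responder and d >= threshold)
                if gated:
                    amp = float(_lognormal_draw(rng, phen.peak_amp_mean_pA,
                                                phen.peak_amp_sd_pA))
                    amp *= (d / (d + amp_d50_nm)) / amp_norm
                else:
                    amp = 0.0
                meas_rows.append({"group": group, "cell_id": cell_id,
                                  "deflection_nm": float(d), "responded": gated,
                                  "amplitude_pA": amp})
            cell_rows.append({"group": group, "cell_id": cell_id,
                              "responder": is_responder,
                              "threshold_nm": threshold})
    return pd.DataFrame(meas_rows), pd.DataFrame(cell_rows)


# ---------------------------------------------------------------------------
# fluorescence traces


def default_calcium_epochs(
    atp_amplitude: float,
    yoda1_amplitude: float,
    gsk_amplitude: float,
) -> list[tuple[Epoch, float]]:
    """Standard agonist schedule: ATP viability test (60 s, an assumed
    duration), 5 min washout, Yoda1 90 s, 5 min washout, GSK101 15 s."""
    atp = Epoch("ATP", 60.0, 60.0)
    yoda = Epoch("Yoda1", atp.end_s + 300.0, 90.0)
    gsk = Epoch("GSK101", yoda.end_s + 300.0, 15.0)
    return [(atp, atp_amplitude), (yoda, yoda1_amplitude), (gsk, gsk_amplitude)]


def generate_fluorescence_trace(
    baseline: float,
    epochs_with_amplitudes,
    frame_interval_s: float = 5.0,
    n_baseline_frames: int = 10,
    noise_sd: float = 0.0,
    rng=None,
    seed: int = 0,
    cell_id: str = "",
    decay_tau_s: float = 30.0,
    tail_s: float = 120.0,
) -> tuple[FluorescenceTrace, dict]:
    """Fluorescence intensity series with step-plus-decay transients.

    During each responding epoch the intensity steps to
    baseline + amplitude (so the noiseless peak ΔF/F equals
    amplitude / baseline exactly) and decays exponentially after the
    epoch ends, modelling agonist washout.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    rng = _rng(seed if rng is None else rng)
    epochs = [ep for ep, _ in epochs_with_amplitudes]
    end = max(ep.end_s for ep in epochs) + tail_s
    n_frames = int(np.ceil(end / frame_interval_s)) + 1
    t = np.arange(n_frames) * frame_interval_s

    f = np.full(n_frames, float(baseline))
    for ep, amp in epochs_with_amplitudes:
        if amp == 0:
            continue
        plateau = (t >= ep.start_s) & (t < ep.end_s)
        f[plateau] = baseline + amp
        washout = t >= ep.end_s
        f[washout] = np.maximum(
            f[washout],
            baseline + amp * np.exp(-(t[washout] - ep.end_s) / decay_tau_s))
    if noise_sd > 0:
        f = np.clip(f + rng.normal(0.0, noise_sd, size=n_frames), 1e-9, None)

    trace = FluorescenceTrace(f, frame_interval_s, n_baseline_frames,
                              cell_id=cell_id, epochs=tuple(epochs))
    truth = {"baseline": baseline,
             "epoch_amplitudes": {ep.label: amp for ep, amp in epochs_with_amplitudes},
             "peak_dff": {ep.label: amp / baseline for ep, amp in epochs_with_amplitudes}}
    return trace, truth
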