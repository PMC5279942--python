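"""Run configuration: schema, validation and defaults for the pipeline.

A run is configured by a YAML/JSON mapping; :func:`validate_config`
checks it exhaustively (every violation is reported, not only the
first), injects defaults, and returns a :class:`RunConfig`.  The
defaults encode the standard experimental conditions: the pillar-array
calibration (PDMS at 2.1 MPa, pili 1.79 µm × 5.87 µm), the deflection
bins, the 5×SD / 0.3 ms event detector and the reference phenotypes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .mechanics import PillarGeometry, DEFAULT_GEOMETRY
from .response import BinningScheme
from .synth import PHENOTYPES, ChannelPhenotype

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config"]


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every violation."""

    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("invalid configuration:\n" + "\n".join(f"- {e}" for e in errors))


@dataclass(frozen=True)
class CohortSpec:
    phenotype: str
    n_cells: int


@dataclass(frozen=True)
class DetectorSettings:
    """Event-detector and fit tolerances, all configurable."""

    baseline_window_ms: float = 10.0
    k_sd: float = 5.0
    sustained_ms: float = 0.3
    rapid_latency_ms: float = 5.0
    rapid_tau1_ms: float = 1.0
    roi_half_width_px: int = 8
    detection_k_noise: float = 5.0
    recovery_limit_nm: float = 50.0
    calcium_dff_threshold: float = 0.1


@dataclass(frozen=True)
class RunConfig:
    seed: int = 0
    calibration: PillarGeometry = DEFAULT_GEOMETRY
    binning: BinningScheme = field(default_factory=BinningScheme)
    detector: DetectorSettings = field(default_factory=DetectorSettings)
    cohorts: dict = field(default_factory=lambda: {
        "chondrocyte-WT": CohortSpec("chondrocyte-WT", 24),
        "dedifferentiated": CohortSpec("dedifferentiated", 15),
    })
    n_hspc_patches: int = 12
    hspc_p50_mmHg: float = 87.1
    hspc_slope_mmHg: float = 10.0
    hspc_imax_pA: float = 45.2
    n_calcium_cells: int = 50
    output_dir: str = "pilarray-run"

    def to_dict(self) -> dict:
        d = asdict(self)
        d["calibration"] = asdict(self.calibration)
        d["binning"] = {"edges": list(self.binning.edges)}
        return d


_KNOWN_KEYS = {"seed", "calibration", "binning", "detector", "cohorts",
               "n_hspc_patches", "hspc_p50_mmHg", "hspc_slope_mmHg",
               "hspc_imax_pA", "n_calcium_cells", "output_dir"}
_CAL_KEYS = {"E_MPa", "r_um", "L_um"}


def validate_config(raw: dict) -> RunConfig:
    """Validate a configuration mapping exhaustively and fill defaults."""
    errors: list[str] = []
    raw = dict(raw or {})

    for key in sorted(set(raw) - _KNOWN_KEYS):
        errors.append(f"unknown key: {key!r}")

    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or seed < 0:
        errors.append(f"seed must be a non-negative integer, got {seed!r}")

    calibration = DEFAULT_GEOMETRY
    cal_raw = raw.get("calibration")
    if cal_raw is not None:
        for key in sorted(set(cal_raw) - _CAL_KEYS):
            errors.append(f"calibration: unknown key {key!r}")
        merged = {**asdict(DEFAULT_GEOMETRY), **{k: cal_raw[k] for k in _CAL_KEYS & set(cal_raw)}}
        try:
            calibration = PillarGeometry(**merged)
        except (ValueError, TypeError) as exc:
            errors.append(f"calibration: {exc}")

    binning = BinningScheme()
    if "binning" in raw:
        try:
            binning = BinningScheme(tuple(raw["binning"]["edges"]))
        except (ValueError, TypeError, KeyError) as exc:
            errors.append(f"binning: {exc!r}")

    detector = DetectorSettings()
    if "detector" in raw:
        known = set(DetectorSettings.__dataclass_fields__)
        for key in sorted(set(raw["detector"]) - known):
            errors.append(f"detector: unknown key {key!r}")
        try:
            detector = DetectorSettings(**{k: v for k, v in raw["detector"].items()
                                           if k in known})
        except (ValueError, TypeError) as exc:
            errors.append(f"detector: {exc}")

    cohorts = RunConfig().cohorts
    if "cohorts" in raw:
        cohorts = {}
        for name, spec in raw["cohorts"].items():
            phen = spec.get("phenotype", name)
            n = spec.get("n_cells", 0)
            if phen not in PHENOTYPES:
                errors.append(f"cohorts[{name!r}]: unknown phenotype {phen!r} "
                              f"(choose from {sorted(PHENOTYPES)})")
            if not isinstance(n, int) or n < 0:
                errors.append(f"cohorts[{name!r}]: n_cells must be a non-negative "
                              f"integer, got {n!r}")
            cohorts[name] = CohortSpec(phen, n)

    scalars = {}
    for key, default, positive in [
        ("n_hspc_patches", 12, True), ("hspc_p50_mmHg", 87.1, True),
        ("hspc_slope_mmHg", 15.0, True), ("hspc_imax_pA", 45.2, True),
        ("n_calcium_cells", 50, False),
    ]:
        value = raw.get(key, default)
        if positive and not (isinstance(value, (int, float)) and value > 0):
            errors.append(f"{key} must be positive, got {value!r}")
        scalars[key] = value

    if errors:
        raise ConfigError(errors)
    return RunConfig(seed=seed, calibration=calibration, binning=binning,
                     detector=detector, cohorts=cohorts,
                     output_dir=raw.get("output_dir", "pilarray-run"), **scalars)


def load_config(path) -> RunConfig:
    """Read a YAML or JSON configuration file and validate it."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return validate_config(raw or {})
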