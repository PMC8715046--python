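"""Pipeline configuration.

Every fixed constant of the analysis lives here with its published default:
the 250-Hz sampling rate, the 20-ms smoothing window, the 500-ms blink
pairing window with 40/80-ms mask padding, the 1-s epoch margins, the 100-ms
baseline window, the 0.5-1.48-s early phase, and the 25%/75% latency
extrapolation fractions.  A flat ``key: value`` text file can override any
field; CLI flags override the file.
"""

from __future__ import annotations

import ast
import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path


class ConfigError(ValueError):
    """Raised for invalid or inconsistent configuration values."""


@dataclass(frozen=True)
class PipelineConfig:
    """All tunable constants of the analysis pipeline.

    Units are seconds unless noted.  ``area_unit_scale`` converts the
    tracker's native area unit to mm^2 (1.0 if the export is already mm^2).
    """

    fs: float = 250.0                 # Hz
    smooth_window: float = 0.020
    blink_pair_window: float = 0.500
    blink_pad_pre: float = 0.040
    blink_pad_post: float = 0.080
    blink_velocity_k: float = 5.0     # robust-SD multiplier for "rapid"
    epoch_pre: float = 1.0
    epoch_post: float = 1.0
    baseline_window: float = 0.100
    early_phase: tuple[float, float] = (0.5, 1.48)
    late_phase_start: float = 1.48
    latency_fracs: tuple[float, float] = (0.25, 0.75)
    latency_search_window: tuple[float, float] = (0.0, 3.0)
    latency_peak_criterion_sd: float = 3.0  # peak must exceed k x baseline SD
    alpha: float = 0.05
    area_unit_scale: float = 1.0
    durations: tuple[float, ...] = (3.0, 6.0, 9.0)
    iti_bounds: tuple[float, float] = (5.0, 8.0)
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "fs", "smooth_window", "blink_pair_window", "blink_pad_pre",
            "blink_pad_post", "epoch_pre", "epoch_post", "baseline_window",
        )
        for name in positive:
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        lo, hi = self.latency_fracs
        if not (0 < lo < hi <= 1):
            raise ConfigError(f"latency_fracs must satisfy 0 < lo < hi <= 1, got {self.latency_fracs}")
        if not (0 < self.alpha < 1):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        e0, e1 = self.early_phase
        if not e0 < e1:
            raise ConfigError(f"early_phase window empty: {self.early_phase}")
        s0, s1 = self.latency_search_window
        if not s0 < s1:
            raise ConfigError(f"latency_search_window empty: {self.latency_search_window}")

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    def replace(self, **changes) -> "PipelineConfig":
        return dataclasses.replace(self, **changes)

    def hash(self) -> str:
        """Stable short hash of the full configuration, for provenance files."""
        text = repr(sorted(dataclasses.asdict(self).items()))
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _parse_value(raw: str):
    raw = raw.strip()
    try:
        value = ast.literal_eval(raw)
    except (ValueError, SyntaxError):
        return raw  # bare string label
    if isinstance(value, list):
        value = tuple(value)
    return value


def load_config(path: str | Path, base: PipelineConfig | None = None,
                **overrides) -> PipelineConfig:
    """Read a flat ``key: value`` (or ``key = value``) config file.

    Unknown keys raise; ``overrides`` (e.g. from CLI flags) win over the
    file, which wins over the built-in defaults.
    """
    base = base or PipelineConfig()
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    values: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        sep = ":" if ":" in line else "="
        if sep not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key: value', got {line!r}")
        key, raw = line.split(sep, 1)
        key = key.strip()
        if key not in known:
            raise ConfigError(f"{path}:{lineno}: unknown config key {key!r}")
        values[key] = _parse_value(raw)
    # literal tuples parsed from "(a, b)" strings come through literal_eval
    values.update({k: v for k, v in overrides.items() if v is not None})
    return dataclasses.replace(base, **values)
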