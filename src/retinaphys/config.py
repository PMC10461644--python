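"""Run configuration shared by the CLI subcommands.

A ``RunConfig`` carries every tunable default of the analysis stack.  The
acquisition/analysis constants (25 kHz digitization, 20 Hz mERG low-pass,
200 Hz spike high-pass, order-2 Butterworth, 5 kHz down-sampled rate, 50 ms
A-wave window, 1 s baseline) are the standard protocol values; the remaining
defaults (PSTH bin, onset criterion, detection threshold, burst ISI) are
explicit, documented analysis choices.

Configs can be loaded from a plain-text ``key = value`` file; unknown keys are
rejected so typos fail loudly before any computation.  CLI options override
file values.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path

__all__ = ["RunConfig", "ConfigError", "write_manifest"]


class ConfigError(ValueError):
    """Invalid or unknown configuration keys/values."""


@dataclass
class RunConfig:
    # acquisition / resampling
    acquisition_rate: float = 25000.0   # Hz, MEA digitization rate
    target_rate: float = 5000.0         # Hz, mERG down-sampled rate
    # mERG band and A-wave windows
    merg_lowpass: float = 20.0          # Hz
    filter_order: int = 2
    zero_phase: bool = True
    baseline_window: float = 1.0        # s before light onset
    a_window: float = 0.05              # s after light onset
    # spike band and detection
    spike_highpass: float = 200.0       # Hz
    threshold_k: float = 4.0            # x robust noise SD
    refractory: float = 0.001           # s
    # PSTH / response classification
    psth_bin: float = 0.05              # s
    pre_window: float = 1.0             # s
    post_window: float = 0.5            # s
    onset_k: float = 3.0                # x SD of basal bin rates
    # intrinsic pipeline
    isi_max: float = 0.010              # s, burst ISI threshold
    dvdt_thresh: float = 10.0           # mV/ms, spike-threshold criterion
    # randomness
    seed: int = 0

    def validate(self) -> "RunConfig":
        nyq_acq = self.acquisition_rate / 2.0
        if not (0 < self.merg_lowpass < nyq_acq):
            raise ConfigError(
                f"merg_lowpass {self.merg_lowpass} Hz outside (0, {nyq_acq}) Hz"
            )
        if not (0 < self.spike_highpass < nyq_acq):
            raise ConfigError(
                f"spike_highpass {self.spike_highpass} Hz outside (0, {nyq_acq}) Hz"
            )
        factor = self.acquisition_rate / self.target_rate
        if abs(factor - round(factor)) > 1e-9:
            raise ConfigError("target_rate must divide acquisition_rate evenly")
        if self.filter_order < 1:
            raise ConfigError("filter_order must be >= 1")
        return self

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        values: dict = {}
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
            key, _, raw = (s.strip() for s in line.partition("="))
            if key not in fields:
                raise ConfigError(f"{path}:{lineno}: unknown key {key!r}")
            values[key] = _coerce(raw, fields[key])
        unknown = set(overrides) - set(fields)
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        values.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**values).validate()


def _coerce(raw: str, typ) -> object:
    name = typ if isinstance(typ, str) else getattr(typ, "__name__", str(typ))
    if "bool" in str(name):
        if raw.lower() in ("true", "1", "yes"):
            return True
        if raw.lower() in ("false", "0", "no"):
            return False
        raise ConfigError(f"bad boolean {raw!r}")
    if "int" in str(name):
        return int(raw)
    return float(raw)


def write_manifest(out_dir: str | Path, stage: str, config: RunConfig,
                   inputs: list[str | Path] | None = None,
                   outputs: list[str | Path] | None = None) -> Path:
    """Write a JSON provenance manifest beside a run's outputs."""
    from . import __version__

    def digest(p):
        p = Path(p)
        return hashlib.sha256(p.read_bytes()).hexdigest()[:16] if p.exists() else None

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "stage": stage,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "version": __version__,
        "python": platform.python_version(),
        "config": dataclasses.asdict(config),
        "inputs": {str(p): digest(p) for p in (inputs or [])},
        "outputs": [str(p) for p in (outputs or [])],
    }
    path = out_dir / f"manifest_{stage}.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
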