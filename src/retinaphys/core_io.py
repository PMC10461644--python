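"""Core data model and file I/O for multi-electrode and patch-clamp recordings.

The on-disk formats are deliberately minimal and vendor-neutral:

* a **columnar text** trace file — one header line (``rate=<Hz>`` followed by
  tab-separated channel names), one row of tab-separated voltages per sample;
* a **chunked binary** container (HDF5) — one chunked 1-D dataset per channel
  under ``/channels``, with ``rate``, ``t0`` and channel order stored as
  attributes.  Round-trips are bit-exact;
* a **stimulus log** — a tab-separated table with columns
  ``onset  duration  wavelength  flux  background``.

Times are seconds from recording start, samples are 0-based, and all windows
are half-open ``[start, end)``.  Extracellular voltages are µV; intracellular
voltages (SweepSet) are mV.  No implicit unit conversion is performed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Recording",
    "StimulusEpoch",
    "SpikeTrain",
    "SweepSet",
    "FormatError",
    "RangeError",
    "read_recording",
    "write_recording",
    "read_stimulus_log",
    "write_stimulus_log",
    "slice_epoch",
    "michelson_contrast",
    "validate_contrast",
]


class FormatError(ValueError):
    """A file violates the trace/stimulus-log format contract."""


class RangeError(ValueError):
    """A requested window falls outside the recording span."""


@dataclass(frozen=True)
class Recording:
    """Multi-channel voltage trace with uniform sampling.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)``, in µV.
    rate
        Sampling frequency in Hz; must be positive.
    channels
        Ordered channel identifiers, one per row of ``samples``.
    t0
        Time of the first sample, in seconds from the recording start.
    """

    samples: np.ndarray
    rate: float
    channels: tuple[str, ...]
    t0: float = 0.0

    def __post_init__(self) -> None:
        samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        object.__setattr__(self, "samples", samples)
        object.__setattr__(self, "channels", tuple(str(c) for c in self.channels))
        if self.rate <= 0:
            raise FormatError(f"sampling rate must be positive, got {self.rate}")
        if samples.ndim != 2:
            raise FormatError("samples must be a 2-D (channels x time) array")
        if samples.shape[0] != len(self.channels):
            raise FormatError(
                f"{samples.shape[0]} sample rows for {len(self.channels)} channels"
            )
        if samples.shape[1] < 1:
            raise FormatError("recording must contain at least one sample")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Span of the recording in seconds (n_samples / rate)."""
        return self.n_samples / self.rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_samples) / self.rate

    def channel(self, name: str) -> np.ndarray:
        return self.samples[self.channels.index(name)]

    def with_samples(self, samples: np.ndarray, rate: float | None = None,
                     t0: float | None = None) -> "Recording":
        return Recording(
            samples=samples,
            rate=self.rate if rate is None else rate,
            channels=self.channels,
            t0=self.t0 if t0 is None else t0,
        )


@dataclass(frozen=True)
class StimulusEpoch:
    """One full-field light step.

    ``flux`` is the stimulus photon flux L_max and ``background`` the ambient
    flux L_min, both in photons/cm²/s; ``wavelength`` in nm.
    """

    onset: float
    duration: float
    wavelength: float = 550.0
    flux: float = 0.0
    background: float = 0.0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError(f"epoch duration must be positive, got {self.duration}")
        if not (self.flux >= self.background >= 0):
            raise ValueError(
                f"need flux >= background >= 0, got flux={self.flux}, "
                f"background={self.background}"
            )

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class SpikeTrain:
    """Spike times of one sorted unit, in seconds from recording start."""

    times: np.ndarray
    unit_id: str = "unit0"
    channel: str | None = None

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=np.float64)
        object.__setattr__(self, "times", times)
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError(f"spike times of {self.unit_id} must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


@dataclass(frozen=True)
class SweepSet:
    """Current-clamp sweeps indexed by injected current level.

    ``sweeps`` maps each injected current (pA) to a voltage trace (mV); all
    traces share ``rate`` and length.  ``step_window`` is the half-open
    ``[start, end)`` interval of current injection in seconds.
    """

    sweeps: tuple[tuple[float, np.ndarray], ...]
    rate: float
    step_window: tuple[float, float]

    def __post_init__(self) -> None:
        sweeps = tuple(
            (float(i), np.asarray(v, dtype=np.float64)) for i, v in self.sweeps
        )
        object.__setattr__(self, "sweeps", sweeps)
        if not sweeps:
            raise ValueError("SweepSet requires at least one sweep")
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        n = sweeps[0][1].size
        if any(v.size != n for _, v in sweeps):
            raise ValueError("all sweeps must share one trace length")
        t_end = n / self.rate
        lo, hi = self.step_window
        if not (0 <= lo < hi <= t_end + 0.5 / self.rate):
            raise ValueError(
                f"step_window {self.step_window} outside trace span [0, {t_end:g})"
            )

    @property
    def currents(self) -> np.ndarray:
        return np.array([i for i, _ in self.sweeps])

    @property
    def n_samples(self) -> int:
        return self.sweeps[0][1].size

    def trace(self, current: float) -> np.ndarray:
        for i, v in self.sweeps:
            if i == current:
                return v
        raise KeyError(f"no sweep at {current} pA")


# ---------------------------------------------------------------------------
# trace file I/O
# ---------------------------------------------------------------------------

def write_recording(rec: Recording, path: str | Path,
                    dialect: str = "chunked-binary") -> None:
    """Write a Recording in the columnar-text or chunked-binary dialect."""
    path = Path(path)
    if dialect == "columnar-text":
        with open(path, "w") as fh:
            fh.write("rate=%.17g\tt0=%.17g\t%s\n" % (rec.rate, rec.t0, "\t".join(rec.channels)))
            np.savetxt(fh, rec.samples.T, fmt="%.17g", delimiter="\t")
    elif dialect == "chunked-binary":
        with h5py.File(path, "w") as fh:
            fh.attrs["rate"] = rec.rate
            fh.attrs["t0"] = rec.t0
            fh.attrs["channels"] = list(rec.channels)
            grp = fh.create_group("channels")
            for name, row in zip(rec.channels, rec.samples):
                grp.create_dataset(name, data=row, chunks=True)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_recording(path: str | Path, dialect: str | None = None) -> Recording:
    """Read a trace file; the dialect is sniffed from the file when omitted."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        dialect = "chunked-binary" if h5py.is_hdf5(path) else "columnar-text"
    if dialect == "chunked-binary":
        with h5py.File(path, "r") as fh:
            channels = [str(c) for c in fh.attrs["channels"]]
            rows = [fh["channels"][c][()] for c in channels]
            lengths = {r.size for r in rows}
            if len(lengths) > 1:
                raise FormatError("ragged channels in binary container")
            return Recording(
                samples=np.vstack(rows), rate=float(fh.attrs["rate"]),
                channels=tuple(channels), t0=float(fh.attrs["t0"]),
            )
    if dialect != "columnar-text":
        raise ValueError(f"unknown dialect {dialect!r}")
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        meta = {}
        channels = []
        for tok in header:
            if "=" in tok:
                key, _, val = tok.partition("=")
                meta[key.strip()] = val.strip()
            else:
                channels.append(tok)
        if "rate" not in meta:
            raise FormatError(f"{path}: header declares no sampling rate")
        try:
            rate = float(meta["rate"])
        except ValueError as exc:
            raise FormatError(f"{path}: bad rate {meta['rate']!r}") from exc
        if rate <= 0:
            raise FormatError(f"{path}: non-positive rate {rate}")
        if not channels:
            raise FormatError(f"{path}: header declares no channels")
        body = []
        for lineno, line in enumerate(fh, start=2):
            line = line.strip()
            if not line:
                continue
            vals = line.split("\t")
            if len(vals) != len(channels):
                raise FormatError(
                    f"{path}:{lineno}: {len(vals)} values for {len(channels)} channels"
                )
            body.append([float(v) for v in vals])
    if not body:
        raise FormatError(f"{path}: no samples")
    return Recording(
        samples=np.asarray(body).T, rate=rate,
        channels=tuple(channels), t0=float(meta.get("t0", 0.0)),
    )


def write_stimulus_log(epochs: Sequence[StimulusEpoch], path: str | Path) -> None:
    pd.DataFrame(
        [dataclasses.asdict(e) for e in epochs],
        columns=["onset", "duration", "wavelength", "flux", "background"],
    ).to_csv(path, sep="\t", index=False)


def read_stimulus_log(path: str | Path) -> list[StimulusEpoch]:
    df = pd.read_csv(path, sep="\t")
    required = {"onset", "duration", "wavelength", "flux", "background"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: stimulus log missing {required - set(df.columns)}")
    return [
        StimulusEpoch(
            onset=row.onset, duration=row.duration, wavelength=row.wavelength,
            flux=row.flux, background=row.background,
        )
        for row in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# epoch handling
# ---------------------------------------------------------------------------

def slice_epoch(rec: Recording, epoch: StimulusEpoch,
                pre: float = 0.0, post: float = 0.0) -> Recording:
    """Cut the window ``[onset - pre, onset + duration + post)`` out of ``rec``.

    The returned Recording keeps absolute time: its ``t0`` is the window start.
    Sample values are unchanged.
    """
    start = epoch.onset - pre
    end = epoch.offset + post
    i0 = int(round((start - rec.t0) * rec.rate))
    i1 = int(round((end - rec.t0) * rec.rate))
    if i0 < 0 or i1 > rec.n_samples:
        raise RangeError(
            f"window [{start:g}, {end:g}) s outside recording span "
            f"[{rec.t0:g}, {rec.t0 + rec.duration:g}) s"
        )
    return rec.with_samples(rec.samples[:, i0:i1], t0=rec.t0 + i0 / rec.rate)


def michelson_contrast(epoch: StimulusEpoch) -> float:
    """Michelson contrast C = (L_max - L_min) / (L_max + L_min) of a light step."""
    total = epoch.flux + epoch.background
    if total == 0:
        raise ValueError("contrast undefined: flux and background are both zero")
    return (epoch.flux - epoch.background) / total


def validate_contrast(epoch: StimulusEpoch, lo: float = 0.8, hi: float = 0.9) -> float:
    """Check a stimulus against the protocol's contrast band (default 0.8–0.9)."""
    c = michelson_contrast(epoch)
    if not (lo <= c <= hi):
        raise ValueError(f"stimulus contrast {c:.3f} outside protocol band [{lo}, {hi}]")
    return c
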