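"""Intrinsic membrane properties from whole-cell current-clamp sweep sets.

One sweep set per cell — voltage responses (mV) to a family of 1-s current
steps (pA) spanning hyperpolarizing through suprathreshold levels — yields the
nine-parameter profile used to compare ganglion cells across species:

=================  ====================================================
parameter          definition
=================  ====================================================
``vm``             resting potential: mean pre-injection voltage (mV)
``rn``             input resistance: slope of steady-state ΔV vs I over
                   hyperpolarizing sweeps (MΩ)
``tau``            membrane time constant: single-exponential fit to the
                   charging trajectory of a small hyperpolarizing step (ms)
``sag``            trough minus steady-state voltage during the strongest
                   hyperpolarizing step (mV; negative when the
                   hyperpolarization-activated rectification is present)
``steady_freq``    firing rate over the final 500 ms of the maximal-rate
                   sweep (Hz)
``max_freq``       maximal spike count / step duration across sweeps (Hz)
``fa``             frequency adaptation index 1 - f_last/f_first at the
                   maximal-rate sweep (first/last inter-spike intervals)
``amplitude``      spike peak minus threshold on the averaged spike (mV;
                   threshold = first point where dV/dt exceeds 10 mV/ms)
``sw``             full width at half amplitude of the averaged spike (ms)
=================  ====================================================

Steady state is always measured over the last 20 % of the current step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .core_io import SpikeTrain, StimulusEpoch, SweepSet

__all__ = [
    "IntrinsicProfile",
    "Burst",
    "FitError",
    "InsufficientDataError",
    "resting_vm",
    "input_resistance",
    "time_constant",
    "sag",
    "firing_rates",
    "spike_shape",
    "detect_bursts",
    "onset_latency",
    "extract_profile",
]

PARAM_ORDER = ("vm", "rn", "tau", "sag", "steady_freq", "max_freq",
               "fa", "amplitude", "sw")


class InsufficientDataError(ValueError):
    """The sweep set lacks the levels or spikes the estimator requires."""


class FitError(RuntimeError):
    """A model fit failed to converge or is unusable."""


@dataclass(frozen=True)
class IntrinsicProfile:
    """The nine intrinsic membrane parameters of one cell."""

    vm: float
    rn: float
    tau: float
    sag: float
    steady_freq: float
    max_freq: float
    fa: float
    amplitude: float
    sw: float
    cell_id: str = ""
    fa_accelerating: bool = False

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in PARAM_ORDER}


@dataclass(frozen=True)
class Burst:
    """A run of spikes whose consecutive intervals stay below threshold."""

    start: float
    n_spikes: int
    isis: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.n_spikes < 2:
            raise ValueError("a burst has at least 2 spikes")


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _step_indices(sweeps: SweepSet) -> tuple[int, int]:
    lo, hi = sweeps.step_window
    return int(round(lo * sweeps.rate)), int(round(hi * sweeps.rate))

def _steady_slice(sweeps: SweepSet) -> slice:
    i0, i1 = _step_indices(sweeps)
    return slice(i1 - max((i1 - i0) // 5, 1), i1)

def detect_sweep_spikes(v: np.ndarray, rate: float,
                        v_cross: float = -20.0) -> np.ndarray:
    """Sample indices of spike peaks (local maxima above ``v_cross``)."""
    from scipy.signal import find_peaks
    distance = max(int(round(0.0008 * rate)), 1)
    peaks, _ = find_peaks(v, height=v_cross, distance=distance)
    return peaks


# ---------------------------------------------------------------------------
# passive parameters
# ---------------------------------------------------------------------------

def resting_vm(sweeps: SweepSet) -> float:
    """Resting potential: pre-injection mean voltage averaged across sweeps."""
    i0, _ = _step_indices(sweeps)
    if i0 < int(0.2 * sweeps.rate):
        raise InsufficientDataError("need >= 200 ms of pre-injection trace")
    return float(np.mean([np.mean(v[:i0]) for _, v in sweeps.sweeps]))


def input_resistance(sweeps: SweepSet) -> float:
    """Input resistance from the I–V slope of hyperpolarizing steady states.

    Least-squares line through (I, steady-state ΔV) over all hyperpolarizing
    sweeps plus the implicit (0, 0) point; slope returned in MΩ
    (mV per nA).
    """
    vm = resting_vm(sweeps)
    steady = _steady_slice(sweeps)
    pts = [(i, float(np.mean(v[steady]) - vm))
           for i, v in sweeps.sweeps if i < 0]
    if len(pts) < 2:
        raise InsufficientDataError(
            "input resistance needs >= 2 hyperpolarizing sweeps"
        )
    pts.append((0.0, 0.0))
    i_na = np.array([p[0] for p in pts]) / 1000.0
    dv = np.array([p[1] for p in pts])
    slope = np.polyfit(i_na, dv, 1)[0]
    return float(slope)


def time_constant(sweeps: SweepSet, current: float | None = None) -> float:
    """Membrane time constant from a single-exponential charging fit (ms).

    Fits ``V(t) = V_inf + (V_0 - V_inf) exp(-t/tau)`` to the trajectory from
    step onset of the designated (default: weakest) hyperpolarizing sweep.
    """
    hyper = sorted([i for i in sweeps.currents if i < 0], reverse=True)
    if not hyper:
        raise InsufficientDataError("time constant needs a hyperpolarizing sweep")
    level = current if current is not None else hyper[0]
    v = sweeps.trace(level)
    i0, i1 = _step_indices(sweeps)
    vm = float(np.mean(v[:i0]))
    seg = v[i0:i1]
    t_ms = np.arange(seg.size) * 1000.0 / sweeps.rate
    v_inf0 = float(np.mean(seg[-max(seg.size // 5, 1):]))
    # initial tau guess: time to reach 63% of the total deflection
    total = v_inf0 - vm
    if total == 0:
        raise FitError("no voltage deflection to fit")
    # initial tau from the 63% crossing of a smoothed trajectory (a raw-noise
    # blip would otherwise collapse the fit window to a handful of samples)
    win = max(int(0.002 * sweeps.rate), 1)
    smooth = np.convolve(seg, np.ones(win) / win, mode="same")
    frac = (smooth - vm) / total
    crossed = np.flatnonzero(frac >= 0.632)
    tau0 = t_ms[crossed[0]] if crossed.size else t_ms[-1] / 3
    tau0 = max(tau0, 1.0)
    fit_end = np.searchsorted(t_ms, min(max(5 * tau0, 50.0), t_ms[-1]))
    model = lambda t, v_inf, dv, tau: v_inf + dv * np.exp(-t / tau)
    try:
        popt, pcov = curve_fit(
            model, t_ms[:fit_end], seg[:fit_end],
            p0=(v_inf0, vm - v_inf0, tau0), maxfev=5000,
        )
    except RuntimeError as exc:
        raise FitError(f"exponential fit did not converge: {exc}") from exc
    tau = float(popt[2])
    tau_se = float(np.sqrt(np.diag(pcov))[2])
    if tau <= 0 or not np.isfinite(tau_se) or tau_se > abs(tau):
        raise FitError(
            f"unreliable time-constant fit: tau={tau:.3g} ms, SE={tau_se:.3g} ms"
        )
    resid_sd = float(np.std(seg[:fit_end] - model(t_ms[:fit_end], *popt)))
    if resid_sd > 0.5 * abs(total):
        raise FitError(
            f"charging trajectory buried in noise: residual SD {resid_sd:.2g} mV "
            f"vs deflection {abs(total):.2g} mV"
        )
    return tau


def sag(sweeps: SweepSet) -> float:
    """Sag amplitude at the strongest hyperpolarizing step (mV).

    ``trough - steady``: negative when the membrane relaxes back toward rest
    during sustained hyperpolarization (I_h-type rectification).
    """
    hyper = [i for i in sweeps.currents if i < 0]
    if not hyper:
        raise InsufficientDataError("sag needs a hyperpolarizing sweep")
    v = sweeps.trace(min(hyper))
    i0, i1 = _step_indices(sweeps)
    trough = float(np.min(v[i0:i1]))
    steady = float(np.mean(v[_steady_slice(sweeps)]))
    return trough - steady


# ---------------------------------------------------------------------------
# active parameters
# ---------------------------------------------------------------------------

def firing_rates(sweeps: SweepSet, steady_window: float = 0.5,
                 v_cross: float = -20.0) -> tuple[float, float, float, bool]:
    """(steady_freq, max_freq, fa, accelerating) from the spiking sweeps.

    max_freq is spike count / step duration, maximized over sweeps;
    steady_freq is the rate over the final ``steady_window`` seconds of that
    sweep; fa = 1 - f_last/f_first with f from the first/last inter-spike
    interval, clipped to [0, 1] (``accelerating`` flags clipping at 0).
    """
    i0, i1 = _step_indices(sweeps)
    step_dur = (i1 - i0) / sweeps.rate
    best = None
    for i_pa, v in sweeps.sweeps:
        peaks = detect_sweep_spikes(v[i0:i1], sweeps.rate, v_cross)
        freq = peaks.size / step_dur
        if best is None or freq > best[0]:
            best = (freq, peaks, i_pa)
    max_freq, peaks, _ = best
    if peaks.size < 3:
        raise InsufficientDataError(
            "firing rates need >= 3 spikes at the maximal level"
        )
    t = peaks / sweeps.rate
    n_steady = int(np.sum(t >= step_dur - steady_window))
    steady_freq = n_steady / steady_window
    isis = np.diff(t)
    ratio = isis[0] / isis[-1]  # f_last / f_first
    accelerating = ratio > 1.0
    fa = float(np.clip(1.0 - ratio, 0.0, 1.0))
    return float(steady_freq), float(max_freq), fa, accelerating


def spike_shape(sweeps: SweepSet, dvdt_thresh: float = 10.0,
                max_spikes: int = 100, v_cross: float = -20.0,
                window_ms: float = 4.0) -> tuple[float, float]:
    """(amplitude mV, half-width ms) of the peak-aligned averaged spike.

    Up to ``max_spikes`` spikes from all sweeps are aligned at their peaks and
    averaged.  Threshold is the voltage where dV/dt first exceeds
    ``dvdt_thresh`` (mV/ms) ahead of the peak; amplitude = peak - threshold;
    half-width = full width at half amplitude by linear interpolation.
    """
    i0, i1 = _step_indices(sweeps)
    half = int(round(window_ms / 2 * sweeps.rate / 1000.0))
    waves = []
    for _, v in sweeps.sweeps:
        for p in detect_sweep_spikes(v[i0:i1], sweeps.rate, v_cross):
            p += i0
            if p - half >= 0 and p + half < v.size:
                waves.append(v[p - half:p + half + 1])
            if len(waves) >= max_spikes:
                break
        if len(waves) >= max_spikes:
            break
    if len(waves) < 10:
        raise InsufficientDataError(
            f"spike shape needs >= 10 spikes, found {len(waves)}"
        )
    mean_wave = np.mean(waves, axis=0)
    peak_idx = int(np.argmax(mean_wave))
    dvdt = np.gradient(mean_wave) * sweeps.rate / 1000.0  # mV/ms
    pre = np.flatnonzero(dvdt[:peak_idx] > dvdt_thresh)
    thr_idx = pre[0] if pre.size else 0
    threshold = float(mean_wave[thr_idx])
    peak = float(mean_wave[peak_idx])
    amplitude = peak - threshold
    half_level = threshold + amplitude / 2.0
    above = mean_wave >= half_level

    def _interp_cross(i_lo: int, i_hi: int) -> float:
        v0, v1 = mean_wave[i_lo], mean_wave[i_hi]
        return i_lo + (half_level - v0) / (v1 - v0) if v1 != v0 else float(i_lo)

    rise = np.flatnonzero(above[: peak_idx + 1])
    left = _interp_cross(rise[0] - 1, rise[0]) if rise.size and rise[0] > 0 else 0.0
    fall = np.flatnonzero(~above[peak_idx:])
    if fall.size:
        j = peak_idx + fall[0]
        right = _interp_cross(j - 1, j)
    else:
        right = float(mean_wave.size - 1)
    sw_ms = (right - left) * 1000.0 / sweeps.rate
    return amplitude, float(sw_ms)


# ---------------------------------------------------------------------------
# burst structure and light-locked latency
# ---------------------------------------------------------------------------

def detect_bursts(train: SpikeTrain, isi_max: float = 0.010) -> list[Burst]:
    """Maximal runs of consecutive inter-spike intervals <= ``isi_max``."""
    t = train.times
    if t.size < 2:
        return []
    isis = np.diff(t)
    bursts = []
    i = 0
    while i < isis.size:
        if isis[i] <= isi_max:
            j = i
            while j < isis.size and isis[j] <= isi_max:
                j += 1
            bursts.append(Burst(start=float(t[i]), n_spikes=j - i + 1,
                                isis=tuple(isis[i:j])))
            i = j + 1
        else:
            i += 1
    return bursts


def onset_latency(train: SpikeTrain,
                  epoch: StimulusEpoch) -> tuple[float | None, float | None]:
    """First-spike latencies after light onset and after light offset (s).

    A missing component (no spike in the respective interval) is returned as
    None.  The ON latency considers spikes in [onset, offset); the OFF latency
    spikes at or after the offset.
    """
    t = train.times
    on_spikes = t[(t >= epoch.onset) & (t < epoch.offset)]
    off_spikes = t[t >= epoch.offset]
    on_lat = float(on_spikes[0] - epoch.onset) if on_spikes.size else None
    off_lat = float(off_spikes[0] - epoch.offset) if off_spikes.size else None
    return on_lat, off_lat


# ---------------------------------------------------------------------------
# full profile
# ---------------------------------------------------------------------------

def extract_profile(sweeps: SweepSet, cell_id: str = "",
                    dvdt_thresh: float = 10.0) -> IntrinsicProfile:
    """Run all nine extractors on one cell's sweep set."""
    steady_freq, max_freq, fa, accel = firing_rates(sweeps)
    amplitude, sw = spike_shape(sweeps, dvdt_thresh=dvdt_thresh)
    return IntrinsicProfile(
        vm=resting_vm(sweeps),
        rn=input_resistance(sweeps),
        tau=time_constant(sweeps),
        sag=sag(sweeps),
        steady_freq=steady_freq,
        max_freq=max_freq,
        fa=fa,
        amplitude=amplitude,
        sw=sw,
        cell_id=cell_id,
        fa_accelerating=accel,
    )
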