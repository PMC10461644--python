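"""Synthetic electrophysiology with known ground truth.

Three generators mirror the three recording modalities the analysis pipelines
consume, so every stage can be validated against parameters it should recover:

``simulate_merg``
    Field potentials whose A-wave (initial negative deflection after a light
    step) scales with an unbleached-photopigment state variable *u*.  A bright
    "bleach" epoch collapses *u* to a floor; in darkness *u* relaxes
    exponentially toward a recoverable ceiling.  With an intact visual cycle
    (RPE present) the ceiling is 1; without it only a small fraction of
    pigment regenerates.  The kernel shapes are phenomenological — only the
    amplitude–bleach-state coupling is meaningful ground truth.

``simulate_spike_train``
    Inhomogeneous-Poisson spike trains (thinning with an absolute refractory
    period) whose rate is baseline plus exponentially decaying transients
    locked to stimulus onset and/or offset — the ON / OFF / ON-OFF phenotypes
    of retinal ganglion cells.

``simulate_current_clamp``
    A leaky integrate-and-fire membrane with a slow sag conductance
    (hyperpolarization-activated rectification), spike-triggered adaptation,
    and stereotyped triangular spike rendering, producing sweep sets from
    which all nine intrinsic membrane parameters can be extracted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_io import Recording, SpikeTrain, StimulusEpoch, SweepSet

__all__ = [
    "MERGModel",
    "RGCRateModel",
    "MembraneModel",
    "ProtocolError",
    "simulate_merg",
    "simulate_spike_train",
    "simulate_current_clamp",
    "TRIANGULAR_SPIKE_HALF_WIDTH_MS",
]

#: Rendered action potentials are symmetric triangles with a 1 ms base, so
#: their full width at half amplitude is analytically 0.5 ms.
TRIANGULAR_SPIKE_HALF_WIDTH_MS = 0.5


class ProtocolError(ValueError):
    """The requested stimulation protocol is internally inconsistent."""


# ---------------------------------------------------------------------------
# mERG forward model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MERGModel:
    """Parameters of the micro-ERG forward model.

    ``a_depth`` is the dark-adapted A-wave trough depth (µV, negative) reached
    ``a_latency`` seconds after light onset; ``a_width`` sets the trough's
    sharpness.  ``b_gain`` adds a cosmetic positive late component.  The
    bleach state *u* starts at ``u0``, recovers toward ``rec_ceiling`` with
    time constant ``tau_rec`` (seconds), collapses to ``bleach_floor`` after
    any epoch with flux above ``bleach_flux``.
    """

    a_depth: float = -77.2
    a_latency: float = 0.030
    a_width: float = 0.025
    b_gain: float = 25.0
    noise_sd: float = 5.0
    u0: float = 1.0
    tau_rec: float = 240.0
    rec_ceiling: float = 1.0
    bleach_flux: float = 1e17
    bleach_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.a_depth >= 0:
            raise ValueError("a_depth is a trough depth and must be negative")
        if not 0 <= self.u0 <= 1:
            raise ValueError("u0 must lie in [0, 1]")
        if self.tau_rec <= 0:
            raise ValueError("tau_rec must be positive")
        if not 0 <= self.rec_ceiling <= 1:
            raise ValueError("rec_ceiling must lie in [0, 1]")


def _gamma_kernel(t: np.ndarray, t_peak: float, width: float) -> np.ndarray:
    """Gamma-like bump, zero for t < 0, unit peak at ``t_peak``."""
    shape = max((t_peak / width) ** 2, 1.01)
    out = np.zeros_like(t)
    pos = t > 0
    x = t[pos] / t_peak
    out[pos] = x ** shape * np.exp(shape * (1.0 - x))
    return out


def _recover(u: float, dt: float, model: MERGModel) -> float:
    """Dark recovery of the unbleached fraction over an interval ``dt``.

    Exponential relaxation toward ``rec_ceiling``; pigment does not bleach in
    darkness, so a state above the ceiling is left untouched.
    """
    if u >= model.rec_ceiling:
        return u
    return model.rec_ceiling + (u - model.rec_ceiling) * np.exp(-dt / model.tau_rec)


def simulate_merg(model: MERGModel, epochs: Sequence[StimulusEpoch], rate: float,
                  seed: int, n_channels: int = 1) -> tuple[Recording, pd.DataFrame]:
    """Render a multi-epoch mERG sweep plus its per-epoch ground truth.

    Returns the Recording and a table with one row per epoch: ``onset``, the
    unbleached fraction ``u`` at that onset, the noiseless trough depth
    ``depth`` (µV) and whether the epoch was a bleaching flash.
    """
    if rate < 2000:
        raise ValueError("mERG simulation requires rate >= 2 kHz")
    epochs = sorted(epochs, key=lambda e: e.onset)
    for a, b in zip(epochs, epochs[1:]):
        if b.onset < a.offset:
            raise ProtocolError(
                f"epochs overlap: one ends at {a.offset:g} s, next starts at {b.onset:g} s"
            )
    duration = (epochs[-1].offset + 1.0) if epochs else 1.0
    n = int(round(duration * rate))
    t = np.arange(n) / rate
    rng = np.random.default_rng(seed)

    clean = np.zeros(n)
    u = model.u0
    t_prev = 0.0
    truth = []
    for ep in epochs:
        u = _recover(u, ep.onset - t_prev, model)
        bleaching = ep.flux >= model.bleach_flux
        depth = model.a_depth * u
        rel = t - ep.onset
        clean += depth * _gamma_kernel(rel, model.a_latency, model.a_width)
        # cosmetic positive late component (B-wave-like), also pigment-scaled
        clean += model.b_gain * u * _gamma_kernel(rel, 4 * model.a_latency,
                                                 4 * model.a_width)
        truth.append({"onset": ep.onset, "u": u, "depth": depth,
                      "bleaching": bleaching})
        if bleaching:
            u = model.bleach_floor
        t_prev = ep.offset
    noisy = clean[None, :] + rng.normal(0.0, model.noise_sd, size=(n_channels, n))
    rec = Recording(samples=noisy, rate=rate,
                    channels=tuple(f"el{i}" for i in range(n_channels)))
    return rec, pd.DataFrame(truth, columns=["onset", "u", "depth", "bleaching"])


# ---------------------------------------------------------------------------
# RGC spike-train model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RGCRateModel:
    """Rate model of a ganglion cell's light response.

    ``base`` is the spontaneous rate; ``on_gain`` / ``off_gain`` are the peak
    rate increments of transients locked to stimulus onset / offset, delayed
    by ``on_latency`` / ``off_latency`` and decaying with time constant
    ``decay`` (all seconds).  ``refractory`` is the absolute dead time.
    """

    base: float = 10.0
    on_gain: float = 60.0
    off_gain: float = 0.0
    on_latency: float = 0.050
    off_latency: float = 0.080
    decay: float = 0.150
    refractory: float = 0.002

    def __post_init__(self) -> None:
        if min(self.base, self.on_gain, self.off_gain) < 0:
            raise ValueError("rates must be non-negative")
        if self.refractory <= 0:
            raise ValueError("refractory period must be positive")

    @property
    def rclass(self) -> str:
        """Ground-truth response class implied by the gains."""
        if self.on_gain > 0 and self.off_gain > 0:
            return "ON_OFF"
        if self.on_gain > 0:
            return "ON"
        if self.off_gain > 0:
            return "OFF"
        return "none"

    def rate_at(self, t: np.ndarray, epochs: Sequence[StimulusEpoch]) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        r = np.full(t.shape, self.base, dtype=float)
        for ep in epochs:
            d_on = t - ep.onset - self.on_latency
            r += self.on_gain * np.where(d_on >= 0, np.exp(-np.maximum(d_on, 0) / self.decay), 0.0)
            d_off = t - ep.offset - self.off_latency
            r += self.off_gain * np.where(d_off >= 0, np.exp(-np.maximum(d_off, 0) / self.decay), 0.0)
        return r


def simulate_spike_train(model: RGCRateModel, epochs: Sequence[StimulusEpoch],
                         duration: float, seed: int,
                         unit_id: str = "sim0") -> tuple[SpikeTrain, dict]:
    """Draw one spike train by thinning a homogeneous Poisson process.

    Candidate events are drawn at the rate envelope's maximum, accepted with
    probability rate(t)/rate_max, and then filtered by the absolute refractory
    period (an accepted spike suppresses candidates within ``refractory``).
    Returns the train and a ground-truth dict (class label, true latencies).
    """
    for ep in epochs:
        if ep.offset > duration:
            raise ProtocolError("duration does not cover all epochs")
    rng = np.random.default_rng(seed)
    rate_max = model.base + model.on_gain + model.off_gain
    times: list[float] = []
    if rate_max > 0:
        n_cand = rng.poisson(rate_max * duration)
        cand = np.sort(rng.uniform(0.0, duration, size=n_cand))
        accept = rng.uniform(size=n_cand) * rate_max < model.rate_at(cand, epochs)
        last = -np.inf
        for tc in cand[accept]:
            if tc - last >= model.refractory:
                times.append(tc)
                last = tc
    truth = {
        "rclass": model.rclass,
        "on_latency": model.on_latency,
        "off_latency": model.off_latency,
        "base": model.base,
    }
    return SpikeTrain(times=np.asarray(times), unit_id=unit_id), truth


# ---------------------------------------------------------------------------
# integrate-and-fire membrane
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MembraneModel:
    """Leaky integrate-and-fire cell with sag and spike-frequency adaptation.

    Units: ``e_leak``, ``v_thresh``, ``v_reset``, ``spike_peak`` in mV;
    ``r_in`` in MΩ; ``tau_m``, ``sag_tau``, ``adapt_tau`` in ms;
    ``adapt_incr`` in mV of equivalent hyperpolarizing drive per spike;
    ``sag_gain`` dimensionless (fraction of the hyperpolarizing deflection
    cancelled at sag steady state); ``noise_sd`` in mV of additive white
    measurement noise on the recorded trace.
    """

    e_leak: float = -56.5
    r_in: float = 141.0
    tau_m: float = 35.2
    sag_gain: float = 0.15
    sag_tau: float = 120.0
    v_thresh: float = -45.0
    v_reset: float = -60.0
    adapt_incr: float = 1.0
    adapt_tau: float = 250.0
    spike_peak: float = 30.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_m <= 0 or self.adapt_tau <= 0 or self.sag_tau <= 0:
            raise ValueError("time constants must be positive")
        if self.v_thresh <= self.v_reset:
            raise ValueError("v_thresh must exceed v_reset")


def simulate_current_clamp(model: MembraneModel, currents: Sequence[float],
                           step_window: tuple[float, float], rate: float,
                           seed: int) -> tuple[SweepSet, dict]:
    """Integrate the membrane for each injected current level.

    Sub-threshold dynamics are the RC response ``tau_m dV/dt = -(V - E_L) +
    R_in*I + s - a`` with sag variable ``s`` (first-order relaxation toward
    ``sag_gain * (E_L - V)`` during hyperpolarization) and adaptation drive
    ``a`` incremented at each spike.  Spikes are rendered as 1-ms triangles
    from threshold to ``spike_peak`` followed by reset.

    Returns the SweepSet and the ground-truth parameter record.
    """
    if len(currents) == 0:
        raise ProtocolError("currents list is empty")
    rng = np.random.default_rng(seed)
    dt_ms = 1000.0 / rate
    lo, hi = step_window
    t_total = hi + lo  # symmetric tail after the step
    n = int(round(t_total * rate))
    t = np.arange(n) / rate
    in_step = (t >= lo) & (t < hi)
    spike_halfwidth_samples = max(int(round(0.0005 * rate)), 1)

    sweeps = []
    for i_pa in currents:
        i_na = i_pa / 1000.0
        v = np.empty(n)
        v[0] = model.e_leak
        s = 0.0
        a = 0.0
        k = 1
        vk = model.e_leak
        decay_m = np.exp(-dt_ms / model.tau_m)
        decay_s = np.exp(-dt_ms / model.sag_tau)
        decay_a = np.exp(-dt_ms / model.adapt_tau)
        while k < n:
            drive = model.r_in * i_na if in_step[k - 1] else 0.0
            s_target = model.sag_gain * max(model.e_leak - vk, 0.0)
            s = s_target + (s - s_target) * decay_s
            a *= decay_a
            # exponential integrator: exact for drive held over the step
            v_inf = model.e_leak + drive + s - a
            vk = v_inf + (vk - v_inf) * decay_m
            if vk >= model.v_thresh and in_step[k - 1]:
                # render stereotyped triangular spike, then reset
                up = np.linspace(model.v_thresh, model.spike_peak,
                                 spike_halfwidth_samples + 1)
                down = np.linspace(model.spike_peak, model.v_thresh,
                                   spike_halfwidth_samples + 1)[1:]
                wave = np.concatenate([up, down])
                stop = min(k + wave.size, n)
                v[k:stop] = wave[: stop - k]
                k = stop
                vk = model.v_reset
                a += model.adapt_incr
                continue
            v[k] = vk
            k += 1
        if model.noise_sd > 0:
            v = v + rng.normal(0.0, model.noise_sd, n)
        sweeps.append((float(i_pa), v))

    truth = {
        "vm": model.e_leak,
        "rn": model.r_in,
        "tau": model.tau_m,
        "sag_gain": model.sag_gain,
        "adapt_incr": model.adapt_incr,
        "spike_amplitude": model.spike_peak - model.v_thresh,
        "spike_half_width_ms": TRIANGULAR_SPIKE_HALF_WIDTH_MS,
    }
    return SweepSet(sweeps=tuple(sweeps), rate=rate, step_window=step_window), truth
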