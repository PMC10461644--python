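"""Ganglion-cell spike extraction and light-response characterization.

Raw MEA traces are high-pass filtered (second-order Butterworth, 200 Hz) to
isolate the spike band.  Detection uses a per-channel negative threshold at
``-k`` times the robust noise estimate sigma = median(|v|)/0.6745, one event
per refractory window, timestamped at the trough (extracellular somatic spikes
are negative-going).  Unit separation is a deliberately simple, documented
sorter: waveform snippets are projected onto two principal axes and k-means
clustered, with the cluster count chosen by silhouette score (single-unit
fallback when separation is poor or events are scarce).

Light responses are summarized by a trial-averaged PSTH: basal rate from the
pre-stimulus window, peak rate and time-to-peak from the PSTH maximum, and the
response onset as the first bin whose rate exceeds the basal mean by a
multiple of the basal bin-rate SD.  Cells are classed ON, OFF or ON-OFF by
whether supra-criterion activity is locked to light onset, offset, or both.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_score

from .core_io import Recording, SpikeTrain, StimulusEpoch

__all__ = [
    "PSTH",
    "ResponseMetrics",
    "detect_spikes",
    "extract_waveforms",
    "sort_units",
    "compute_psth",
    "response_metrics",
    "cohort_table",
]

CLASSES = ("ON", "OFF", "ON_OFF", "none")


@dataclass(frozen=True)
class PSTH:
    """Peri-stimulus time histogram (uniform bins, trial-averaged)."""

    bin_edges: np.ndarray
    counts: np.ndarray
    n_trials: int

    def __post_init__(self) -> None:
        widths = np.diff(self.bin_edges)
        if not np.allclose(widths, widths[0]):
            raise ValueError("PSTH bins must be uniform")

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    @property
    def rate(self) -> np.ndarray:
        """Firing rate per bin in Hz (counts / (bin width x trials))."""
        return self.counts / (self.bin_width * self.n_trials)

    @property
    def centers(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0


@dataclass(frozen=True)
class ResponseMetrics:
    """Light-response summary of one unit.

    ``onset`` and ``time_to_peak`` are seconds relative to stimulus onset;
    either may be NaN when no bin crosses the response criterion.
    """

    unit_id: str
    basal_rate: float
    peak_rate: float
    onset: float
    time_to_peak: float
    rclass: str

    def __post_init__(self) -> None:
        if self.rclass not in CLASSES:
            raise ValueError(f"unknown response class {self.rclass!r}")


# ---------------------------------------------------------------------------
# detection & sorting
# ---------------------------------------------------------------------------

def detect_spikes(rec: Recording, threshold_k: float = 4.0,
                  refractory: float = 0.001) -> list[SpikeTrain]:
    """Threshold-based spike detection on the high-pass band, per channel.

    The threshold is ``-threshold_k * sigma`` with the robust noise scale
    sigma = median(|v|)/0.6745.  Events closer than ``refractory`` to the
    previous accepted event are merged; each event is stamped at its trough.
    """
    if threshold_k <= 0:
        raise ValueError("threshold_k must be positive")
    ref_n = max(int(round(refractory * rec.rate)), 1)
    trains = []
    for name, v in zip(rec.channels, rec.samples):
        sigma = np.median(np.abs(v)) / 0.6745
        if sigma == 0:
            trains.append(SpikeTrain(times=np.array([]), unit_id=f"{name}:mu",
                                     channel=name))
            continue
        thr = -threshold_k * sigma
        below = v < thr
        # rising edges of the below-threshold mask = candidate events
        starts = np.flatnonzero(below & ~np.r_[False, below[:-1]])
        times = []
        last_idx = -np.inf
        for s in starts:
            if s - last_idx < ref_n:
                continue
            seg_end = min(s + ref_n, v.size)
            trough = s + int(np.argmin(v[s:seg_end]))
            times.append(rec.t0 + trough / rec.rate)
            last_idx = trough
        trains.append(SpikeTrain(times=np.asarray(times), unit_id=f"{name}:mu",
                                 channel=name))
    return trains


def extract_waveforms(rec: Recording, train: SpikeTrain,
                      window: float = 0.002) -> np.ndarray:
    """Cut trough-aligned snippets (±window/2) around each spike."""
    half = max(int(round(window * rec.rate / 2)), 1)
    v = rec.channel(train.channel) if train.channel else rec.samples[0]
    waves = []
    for t in train.times:
        i = int(round((t - rec.t0) * rec.rate))
        if i - half < 0 or i + half >= v.size:
            continue
        waves.append(v[i - half:i + half + 1])
    return np.asarray(waves)


def sort_units(rec: Recording, trains: Sequence[SpikeTrain], k_max: int = 3,
               min_events: int = 10, min_silhouette: float = 0.5,
               random_state: int = 0) -> list[SpikeTrain]:
    """Split each channel's multi-unit train into putative single units.

    Snippets are projected onto 2 principal axes; k-means is run for k up to
    ``k_max`` and k is chosen by silhouette score (accepted only above
    ``min_silhouette``, otherwise single-unit fallback).  Channels with fewer
    than ``min_events`` events are passed through as one unit with a warning.
    """
    out: list[SpikeTrain] = []
    for train in trains:
        waves = extract_waveforms(rec, train)
        if len(waves) < min_events or len(train) < min_events:
            if len(train):
                warnings.warn(
                    f"channel {train.channel}: {len(train)} events < "
                    f"{min_events}; assigned to a single unit"
                )
            out.append(train)
            continue
        feats = PCA(n_components=2, random_state=random_state).fit_transform(waves)
        best_k, best_score, best_labels = 1, -1.0, np.zeros(len(waves), dtype=int)
        for k in range(2, k_max + 1):
            if len(waves) <= k:
                break
            labels = KMeans(n_clusters=k, n_init=10,
                            random_state=random_state).fit_predict(feats)
            if np.unique(labels).size < 2:
                continue
            # a putative unit needs a minimum event count; singleton or
            # near-empty clusters are outliers, not cells
            if np.bincount(labels).min() < min_events:
                continue
            score = silhouette_score(feats, labels)
            if score > best_score:
                best_k, best_score, best_labels = k, score, labels
        if best_k == 1 or best_score < min_silhouette:
            out.append(train)
            continue
        # events skipped at the trace edges keep chronological alignment
        kept = [t for t in train.times
                if int(round((t - rec.t0) * rec.rate)) - len(waves[0]) // 2 >= 0]
        kept = np.asarray(kept[: len(waves)])
        for k in range(best_k):
            out.append(SpikeTrain(times=kept[best_labels == k],
                                  unit_id=f"{train.channel}:u{k}",
                                  channel=train.channel))
    return out


# ---------------------------------------------------------------------------
# response metrics
# ---------------------------------------------------------------------------

def compute_psth(train: SpikeTrain, trials: Sequence[StimulusEpoch],
                 bin_width: float, window: tuple[float, float]) -> PSTH:
    """Histogram spike times relative to each trial's onset over ``window``."""
    lo, hi = window
    n_bins = int(round((hi - lo) / bin_width))
    edges = lo + bin_width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins)
    for ep in trials:
        rel = train.times - ep.onset
        counts += np.histogram(rel, bins=edges)[0]
    return PSTH(bin_edges=edges, counts=counts, n_trials=len(trials))


def response_metrics(train: SpikeTrain, trials: Sequence[StimulusEpoch],
                     bin_width: float = 0.05, pre_window: float = 1.0,
                     post_window: float = 0.5, onset_k: float = 3.0,
                     min_run: int = 2) -> ResponseMetrics:
    """Characterize one unit's light response over repeated identical trials.

    * ``basal_rate``: spikes in ``[-pre_window, 0)`` per trial-second.
    * response window: ``[0, duration + post_window)`` binned at
      ``bin_width``; criterion = basal mean + ``onset_k`` x SD of the basal
      bin rates (at least one basal bin-count quantum to avoid a zero
      criterion for silent baselines).  A response component must hold the
      criterion for ``min_run`` consecutive bins: genuine transients outlast
      one bin, while isolated supra-criterion bins are Poisson flukes of the
      baseline.
    * ``onset``: left edge of the first qualifying run; ``peak_rate`` /
      ``time_to_peak`` from the PSTH maximum (bin center).
    * class: ON if activity is locked to light onset only, OFF if only to
      offset, ON-OFF if qualifying runs occur both during the stimulus and
      within 0.5 s after offset.
    """
    if not trials:
        raise ValueError("response_metrics needs at least one trial")
    duration = trials[0].duration
    basal = compute_psth(train, trials, bin_width, (-pre_window, 0.0))
    basal_rate = float(np.sum(basal.counts) / (pre_window * len(trials)))
    if len(train) == 0:
        return ResponseMetrics(unit_id=train.unit_id, basal_rate=0.0,
                               peak_rate=0.0, onset=np.nan,
                               time_to_peak=np.nan, rclass="none")
    resp = compute_psth(train, trials, bin_width, (0.0, duration + post_window))
    basal_sd = float(np.std(basal.rate, ddof=1)) if basal.rate.size > 1 else 0.0
    quantum = 1.0 / (bin_width * len(trials))  # one spike in one bin
    criterion = basal_rate + max(onset_k * basal_sd, quantum)
    supra = resp.rate > criterion
    # keep only runs of >= min_run consecutive supra-criterion bins
    above = np.zeros_like(supra)
    i = 0
    while i < supra.size:
        if supra[i]:
            j = i
            while j < supra.size and supra[j]:
                j += 1
            if j - i >= min_run:
                above[i:j] = True
            i = j
        else:
            i += 1
    peak_idx = int(np.argmax(resp.rate))
    peak_rate = float(resp.rate[peak_idx])
    if not above.any():
        return ResponseMetrics(unit_id=train.unit_id, basal_rate=basal_rate,
                               peak_rate=peak_rate, onset=np.nan,
                               time_to_peak=np.nan, rclass="none")
    onset = float(resp.bin_edges[:-1][above][0])
    time_to_peak = float(resp.centers[peak_idx])
    in_stim = resp.bin_edges[:-1] < duration
    post_off = (resp.bin_edges[:-1] >= duration) & (resp.bin_edges[:-1] < duration + 0.5)
    has_on = bool((above & in_stim).any())
    has_off = bool((above & post_off).any())
    if has_on and has_off:
        rclass = "ON_OFF"
    elif has_on:
        rclass = "ON"
    else:
        rclass = "OFF"
    return ResponseMetrics(unit_id=train.unit_id, basal_rate=basal_rate,
                           peak_rate=peak_rate, onset=onset,
                           time_to_peak=time_to_peak, rclass=rclass)


def cohort_table(metrics: Sequence[ResponseMetrics]) -> dict:
    """Per-class counts and fractions plus mean ± SD summaries per metric.

    Fractions are over classified cells (class != none) and sum to 1.
    """
    if not metrics:
        raise ValueError("cohort_table needs at least one metrics row")
    df = pd.DataFrame([{
        "unit_id": m.unit_id, "basal_rate": m.basal_rate,
        "peak_rate": m.peak_rate, "onset": m.onset,
        "time_to_peak": m.time_to_peak, "rclass": m.rclass,
    } for m in metrics])
    classified = df[df["rclass"] != "none"]
    counts = {c: int((classified["rclass"] == c).sum())
              for c in ("ON", "OFF", "ON_OFF")}
    n_classified = len(classified)
    fractions = {c: (counts[c] / n_classified if n_classified else np.nan)
                 for c in counts}
    summaries = {
        col: {"mean": float(np.nanmean(df[col])), "sd": float(np.nanstd(df[col], ddof=1))}
        for col in ("basal_rate", "peak_rate", "onset", "time_to_peak")
        if np.isfinite(df[col]).any()
    }
    return {"n_total": len(df), "n_classified": n_classified,
            "counts": counts, "fractions": fractions,
            "summaries": summaries, "table": df}
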