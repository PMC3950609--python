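"""Electrophysiological measurements on recorded traces.

Spike detection uses the somatic overshoot criterion (first sample of each
upward crossing of 0 mV); resting potentials are spike-removed means (samples
within 2 ms of a dV/dt > 10 mV/ms upstroke excluded); oscillation detection
works on the de-spiked, detrended trace via a Welch periodogram.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .simulator import Recording, SimCell, SimulationConfig, StimStep, \
    StimulusProtocol, simulate

SPIKE_THRESHOLD_MV = 0.0
DVDT_THRESHOLD = 10.0   # mV/ms, spike-removal criterion
BLANK_MS = 2.0          # removal window after each upstroke


class InsufficientDataError(ValueError):
    """Raised when a statistic is undefined for the given trace."""


@dataclass
class SpikeTrain:
    spike_times: np.ndarray      # ms, strictly increasing
    detection_threshold: float = SPIKE_THRESHOLD_MV
    source_site: str = "soma"

    def __len__(self) -> int:
        return len(self.spike_times)


def detect_spikes(time: np.ndarray, v: np.ndarray,
                  threshold: float = SPIKE_THRESHOLD_MV,
                  refractory: float = 1.0,
                  site: str = "soma") -> SpikeTrain:
    """Times of upward threshold crossings, with a refractory window.

    The spike time is the first sample at or above threshold of each upward
    crossing; crossings within ``refractory`` ms of the previous spike are
    suppressed (they belong to the same action potential).  A trace that
    starts above threshold contributes a spike at its first sample.
    """
    v = np.asarray(v)
    above = v >= threshold
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        onsets = np.concatenate(([0], onsets))
    times = np.asarray(time)[onsets]
    kept = []
    last = -np.inf
    for t in times:
        if t - last >= refractory:
            kept.append(t)
            last = t
    return SpikeTrain(np.asarray(kept, dtype=float), threshold, site)


def firing_rate(train: SpikeTrain, window: tuple[float, float]) -> float:
    """Spike count in [t0, t1) divided by the window length, in Hz."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("empty measurement window")
    count = np.count_nonzero((train.spike_times >= t0)
                             & (train.spike_times < t1))
    return count / ((t1 - t0) * 1e-3)


def spike_mask(time: np.ndarray, v: np.ndarray,
               dvdt_threshold: float = DVDT_THRESHOLD,
               blank: float = BLANK_MS) -> np.ndarray:
    """Boolean mask of samples that belong to spikes (to be excluded).

    A sample is masked if it lies within ``blank`` ms at or after any point
    where the forward-difference dV/dt exceeds ``dvdt_threshold``.
    """
    time = np.asarray(time)
    v = np.asarray(v)
    dt = time[1] - time[0]
    dvdt = np.diff(v) / dt
    mask = np.zeros(len(v), dtype=bool)
    width = max(1, int(round(blank / dt)))
    for i in np.flatnonzero(dvdt > dvdt_threshold):
        mask[i:i + width + 1] = True
    return mask


@dataclass
class MeanVm:
    """Spike-removed mean membrane potential (mV) with a data-quantity flag."""
    value: float
    retained_ms: float
    ok: bool

    def __float__(self) -> float:
        return self.value


def mean_vm_spike_removed(time: np.ndarray, v: np.ndarray,
                          min_retained_ms: float = 1000.0) -> MeanVm:
    """Mean V_m after excising spikes (2 ms after each 10 mV/ms upstroke).

    The returned ``ok`` flag is false (and a warning is issued) when fewer
    than ``min_retained_ms`` of trace survive the excision.
    """
    time = np.asarray(time)
    v = np.asarray(v)
    mask = spike_mask(time, v)
    keep = ~mask
    dt = time[1] - time[0]
    retained = keep.sum() * dt
    if keep.sum() == 0:
        warnings.warn("entire trace excluded by spike removal")
        return MeanVm(np.nan, 0.0, False)
    value = float(v[keep].mean())
    ok = retained >= min_retained_ms
    if not ok:
        warnings.warn(
            f"only {retained:.0f} ms retained after spike removal")
    return MeanVm(value, retained, ok)


def cv_isi(train: SpikeTrain) -> float:
    """Coefficient of variation of interspike intervals (sample SD / mean)."""
    if len(train) < 3:
        raise InsufficientDataError(
            "CV of ISI requires at least 3 spikes (2 intervals)")
    isis = np.diff(train.spike_times)
    return float(np.std(isis, ddof=1) / np.mean(isis))


# ---------------------------------------------------------------------------
# Subthreshold oscillations
# ---------------------------------------------------------------------------

OSC_BAND = (0.5, 12.0)   # Hz, search band
OSC_PEAK_FACTOR = 3.0    # peak power must exceed this multiple of the median
OSC_MIN_P2P = 0.1        # mV, noise floor; real oscillations are 0.5-10 mV
SUSTAIN_RATIO = 0.5      # amplitude retention for "sustained"


@dataclass
class OscillationReport:
    present: bool
    sustained: bool
    frequency: float      # Hz (nan when absent)
    peak_to_peak: float    # mV (nan when absent)


def _despike_interpolate(time, v):
    mask = spike_mask(time, v)
    if mask.all():
        raise InsufficientDataError("no subthreshold data after despiking")
    if mask.any():
        v = v.copy()
        idx = np.arange(len(v))
        v[mask] = np.interp(idx[mask], idx[~mask], v[~mask])
    return v


def oscillation_report(time: np.ndarray, v: np.ndarray,
                       band: tuple[float, float] = OSC_BAND
                       ) -> OscillationReport:
    """Detect subthreshold membrane-potential oscillations.

    The trace is de-spiked (spike samples replaced by interpolation),
    linearly detrended, and a Welch periodogram computed.  An oscillation is
    *present* when the spectral peak inside ``band`` carries at least three
    times the median spectral power; it is *sustained* when the band-passed
    peak-to-peak amplitude of the final half of the window retains at least
    half that of the first half.  Requires >= 2 s of data.
    """
    time = np.asarray(time)
    v = np.asarray(v, dtype=float)
    span = time[-1] - time[0]
    if span < 2000.0:
        raise InsufficientDataError("oscillation analysis needs >= 2 s")
    dt = time[1] - time[0]
    fs = 1e3 / dt  # Hz
    x = signal.detrend(_despike_interpolate(time, v))
    nper = min(len(x), int(round(4.0 * fs)))  # 4 s windows, 0.25 Hz bins
    freqs, pxx = signal.welch(x, fs=fs, nperseg=nper)
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    if not in_band.any():
        return OscillationReport(False, False, np.nan, np.nan)
    peak_i = np.flatnonzero(in_band)[np.argmax(pxx[in_band])]
    median_power = np.median(pxx[freqs > 0])
    present = pxx[peak_i] >= OSC_PEAK_FACTOR * median_power and pxx[peak_i] > 0
    if not present:
        return OscillationReport(False, False, np.nan, np.nan)
    freq = float(freqs[peak_i])
    # band-pass around the search band for the amplitude measures
    nyq = fs / 2.0
    sos = signal.butter(3, [band[0] / nyq, min(band[1] / nyq, 0.99)],
                        btype="bandpass", output="sos")
    xb = signal.sosfiltfilt(sos, x)
    trim = len(xb) // 10  # drop filter edge transients
    xb = xb[trim:len(xb) - trim]
    if float(np.ptp(xb)) < OSC_MIN_P2P:
        # a spectral "peak" in an essentially flat trace is numerical noise
        return OscillationReport(False, False, np.nan, np.nan)
    half = len(xb) // 2
    p2p_first = float(np.ptp(xb[:half]))
    p2p_last = float(np.ptp(xb[half:]))
    sustained = p2p_last >= SUSTAIN_RATIO * p2p_first
    return OscillationReport(True, sustained, freq, float(np.ptp(xb)))


# ---------------------------------------------------------------------------
# Step-response metrics
# ---------------------------------------------------------------------------

@dataclass
class StepResponseMetrics:
    V_rest: float               # mV, spike-removed pre-step mean
    V_hyp: float                # mV, mean over the last 20 % of the step
    hyp_depth: float            # mV, V_rest - V_hyp
    sag: float                  # mV, early minimum below the steady level
    spikes_during_step: int
    rebound_burst_rate: float   # Hz over 200 ms after step offset
    latent_period: float        # ms, offset to first rebound spike (nan)

    REBOUND_WINDOW_MS = 200.0


def step_response_metrics(recording: Recording, step: StimStep | None = None,
                          site: str = "soma") -> StepResponseMetrics:
    """Measure the response to a hyperpolarizing current step.

    ``step`` defaults to the first stimulus step of the recording's
    protocol.  The sag is the depth of the early hyperpolarization minimum
    (first 200 ms of the step) below the steady-state level (mean of the
    last 20 % of the step), reported as a non-negative magnitude.
    """
    if step is None:
        if not recording.protocol.steps:
            raise ValueError("recording has no stimulus step")
        step = recording.protocol.steps[0]
    t = recording.time
    v = recording[site]
    t_on = step.t_start
    t_off = step.t_start + step.duration
    if t_on < t[0] or t_off > t[-1]:
        raise ValueError("step not contained in the recording")
    pre = t < t_on
    rest = mean_vm_spike_removed(t[pre], v[pre])
    in_step = (t >= t_on) & (t < t_off)
    tail = (t >= t_off - 0.2 * step.duration) & (t < t_off)
    v_hyp = float(v[tail].mean())
    early = (t >= t_on) & (t < min(t_on + 200.0, t_off))
    sag = max(0.0, v_hyp - float(v[early].min()))
    spikes_step = detect_spikes(t[in_step], v[in_step])
    post = (t >= t_off) & (t < t_off + StepResponseMetrics.REBOUND_WINDOW_MS)
    rebound = detect_spikes(t[post], v[post])
    post_all = t >= t_off
    first_rebound = detect_spikes(t[post_all], v[post_all])
    latent = (float(first_rebound.spike_times[0] - t_off)
              if len(first_rebound) else np.nan)
    return StepResponseMetrics(
        V_rest=rest.value,
        V_hyp=v_hyp,
        hyp_depth=rest.value - v_hyp,
        sag=sag,
        spikes_during_step=len(spikes_step),
        rebound_burst_rate=len(rebound)
        / (StepResponseMetrics.REBOUND_WINDOW_MS * 1e-3),
        latent_period=latent,
    )


# ---------------------------------------------------------------------------
# Input resistance
# ---------------------------------------------------------------------------

def input_resistance(cell: SimCell, config: SimulationConfig | None = None,
                     probe_nA: float = -0.02, mode: str = "somatic",
                     window_ms: float = 1000.0) -> float:
    """Steady-state input resistance in MOhm from a small somatic step.

    Primary (``somatic``) definition: spike-removed mean somatic V over the
    last ``window_ms`` of a baseline period and of an equally long probe
    step; R_in = dV/dI.  On spontaneously firing cells the spike-removed
    means of the two limit cycles are compared, which is intrinsically
    noisier; the probe default (-20 pA) keeps dV above that noise while
    staying in the near-linear regime.  The ``dendritic`` mode instead
    averages dV/dI measured at the first compartment of each primary
    dendrite.
    """
    config = config or cell.config
    base = window_ms + 500.0
    hold = window_ms + 500.0
    protocol = StimulusProtocol(
        steps=(StimStep(base, hold, probe_nA),), duration=base + hold,
        name="rin_probe")
    if mode == "somatic":
        sites = ("soma",)
    elif mode == "dendritic":
        prim = cell.sites.get("_primary_dendrites", ())
        if not prim:
            raise ValueError("cell has no primary dendrites")
        sites = tuple(f"_pd{i}" for i in range(len(prim)))
        cell.sites.update(dict(zip(sites, prim)))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    from dataclasses import replace as _replace
    rec = simulate(cell, protocol, _replace(config, record_sites=sites))
    t = rec.time
    pre = (t >= base - window_ms) & (t < base)
    during = (t >= base + hold - window_ms) & (t < base + hold)
    values = []
    for s in sites:
        v = rec[s]
        v0 = mean_vm_spike_removed(t[pre], v[pre], min_retained_ms=100.0)
        v1 = mean_vm_spike_removed(t[during], v[during], min_retained_ms=100.0)
        if v0.retained_ms < 100.0 or v1.retained_ms < 100.0:
            raise InsufficientDataError(
                "too little spike-free data for input resistance")
        values.append((v1.value - v0.value) / probe_nA)  # mV / nA = MOhm
    return float(np.mean(values))
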