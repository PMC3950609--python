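"""Canned single-cell experiments on a morphology.

Each function runs one of the standard protocols end to end (build, settle,
simulate, measure) and returns the headline quantity.  They are the units
the analysis drivers and the reproduction script are built from.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .analysis import (OscillationReport, StepResponseMetrics, detect_spikes,
                       firing_rate, input_resistance, mean_vm_spike_removed,
                       oscillation_report, step_response_metrics)
from .membrane import DEFAULT_DISTRIBUTION, DistributionTable
from .morphology import Morphology
from .simulator import (SimulationConfig, StimStep, StimulusProtocol,
                        build_cell, make_protocol, simulate)

SOMA_ONLY = ("soma",)


def _soma_cfg(config: SimulationConfig) -> SimulationConfig:
    return replace(config, record_sites=SOMA_ONLY)


def spontaneous_rate(morph: Morphology, triple, config=SimulationConfig(),
                     table: DistributionTable = DEFAULT_DISTRIBUTION,
                     duration: float = 1500.0,
                     window: float = 1000.0) -> float:
    """Somatic firing rate (Hz) over the final ``window`` of a free run."""
    cfg = _soma_cfg(config)
    cell = build_cell(morph, table, triple, cfg)
    rec = simulate(cell, make_protocol("spontaneous", duration=duration),
                   cfg)
    return firing_rate(detect_spikes(rec.time, rec["soma"]),
                       (duration - window, duration))


def spontaneous_threshold(morph: Morphology, g_t: float, g_h: float,
                          config=SimulationConfig(),
                          bracket=(0.0, 5e-5), resolution: float = 1e-6,
                          duration: float = 1500.0) -> float:
    """Smallest g_NaP producing spontaneous spiking, by bisection.

    Spiking means rate > 0 (overshooting spikes) over the final second of a
    ``duration`` run after settling.  Returns 0.0 when the cell is already
    active with g_NaP = 0 (possible at high g_T, which can activate the cell
    on its own), and ``inf`` when even the upper bracket stays silent.
    """
    lo, hi = bracket
    if spontaneous_rate(morph, (lo, g_t, g_h), config,
                        duration=duration) > 0:
        return lo
    if spontaneous_rate(morph, (hi, g_t, g_h), config,
                        duration=duration) == 0:
        return np.inf
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if spontaneous_rate(morph, (mid, g_t, g_h), config,
                            duration=duration) > 0:
            hi = mid
        else:
            lo = mid
    return hi


def resting_potential(morph: Morphology, triple,
                      config=SimulationConfig(),
                      duration: float = 2000.0) -> float:
    """Spike-removed mean somatic potential over the final second (mV)."""
    cfg = _soma_cfg(config)
    cell = build_cell(morph, DEFAULT_DISTRIBUTION, triple, cfg)
    rec = simulate(cell, make_protocol("spontaneous", duration=duration),
                   cfg)
    t, v = rec.time, rec["soma"]
    sel = t >= duration - 1000.0
    return mean_vm_spike_removed(t[sel], v[sel],
                                 min_retained_ms=500.0).value


def hyperpolarizing_step_response(morph: Morphology, triple,
                                  config=SimulationConfig()
                                  ) -> StepResponseMetrics:
    """Response to the standard -0.2 nA / 500 ms somatic step."""
    cfg = _soma_cfg(config)
    cell = build_cell(morph, DEFAULT_DISTRIBUTION, triple, cfg)
    rec = simulate(cell, make_protocol("hyp_step_200pA"), cfg)
    return step_response_metrics(rec)


def holding_current_oscillations(morph: Morphology, triple,
                                 hold_nA: float = -0.06,
                                 config=SimulationConfig(),
                                 settle: float = 500.0,
                                 hold: float = 5500.0,
                                 analyze_last: float = 4000.0
                                 ) -> OscillationReport:
    """Oscillation analysis under a sustained holding current.

    The cell is held at ``hold_nA`` for ``hold`` ms after ``settle`` ms of
    free running; the report covers the final ``analyze_last`` ms of the
    de-spiked somatic trace.
    """
    cfg = _soma_cfg(config)
    cell = build_cell(morph, DEFAULT_DISTRIBUTION, triple, cfg)
    prot = StimulusProtocol(steps=(StimStep(settle, hold, hold_nA),),
                            duration=settle + hold, name="hold")
    rec = simulate(cell, prot, cfg)
    t, v = rec.time, rec["soma"]
    sel = t >= settle + hold - analyze_last
    return oscillation_report(t[sel], v[sel])


def input_resistance_vs_leak(morph: Morphology, triple,
                             leak_multipliers=(1.0, 15.0, 25.0),
                             config=SimulationConfig(),
                             probe_nA: float = -0.2) -> list:
    """R_in (MOhm) of the cell at each uniform leak multiplier.

    On spontaneously firing cells the -0.2 nA step (the companion protocol
    of the leak sweep) is used as the probe; the distal axon keeps its 25x
    multiplier throughout.
    """
    cfg = _soma_cfg(config)
    out = []
    for mult in leak_multipliers:
        table = DEFAULT_DISTRIBUTION.with_overrides(
            leak_multiplier=(float(mult),) * 5 + (25.0,))
        cell = build_cell(morph, table, triple, cfg)
        out.append((mult * 8e-6,
                    input_resistance(cell, cfg, probe_nA=probe_nA)))
    return out
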