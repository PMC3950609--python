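"""Constraint evaluation, phenotype classification, and conductance search.

A conductance triple (g_NaP, g_T, g_h) is evaluated against the
electrophysiological constraints that define the three alpha-like phenotypes:

* C0 - action potentials must overshoot 0 mV (cells whose spike-like events
  stay below 0 mV fail outright);
* C1 - resting potential in [-70, -62] mV (ON) or [-62, -50] mV (OFF);
* C2 - spontaneous rate 0 Hz (ON), 15-23 Hz (OFF transient) or
  40-48 Hz (OFF sustained);
* C3 - no spikes during a -0.2 nA / 500 ms step;
* C4 - no rebound burst (ON) or rebound rate >= 2x the spontaneous rate
  (OFF), measured over 200 ms after step offset.

Valid sets are connected components (6-neighbor face adjacency by default)
of identically-labelled points on the search lattice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage, signal, stats

from .analysis import (InsufficientDataError, cv_isi, detect_spikes,
                       firing_rate, mean_vm_spike_removed,
                       oscillation_report, step_response_metrics)
from .membrane import DEFAULT_DISTRIBUTION, DistributionTable
from .morphology import Morphology, scale_morphology
from .simulator import (Recording, SimulationConfig, build_cell,
                        make_protocol, simulate)

PHENOTYPES = ("none", "ON", "OFF_T", "OFF_S")

ON_REST = (-70.0, -62.0)
OFF_REST = (-62.0, -50.0)
OFF_T_RATE = (15.0, 23.0)
OFF_S_RATE = (40.0, 48.0)


@dataclass(frozen=True)
class ConstraintReport:
    c0_pass: bool
    rest_mV: float
    spont_Hz: float
    spikes_during_hyp: int
    rebound_rate_Hz: float

    @property
    def on_pass(self) -> bool:
        return (self.c0_pass
                and ON_REST[0] <= self.rest_mV <= ON_REST[1]
                and self.spont_Hz == 0.0
                and self.spikes_during_hyp == 0
                and self.rebound_rate_Hz == 0.0)

    @property
    def _off_common(self) -> bool:
        return (self.c0_pass
                and OFF_REST[0] <= self.rest_mV <= OFF_REST[1]
                and self.spikes_during_hyp == 0
                and self.spont_Hz > 0.0
                and self.rebound_rate_Hz >= 2.0 * self.spont_Hz)

    @property
    def offT_pass(self) -> bool:
        return self._off_common and OFF_T_RATE[0] <= self.spont_Hz <= OFF_T_RATE[1]

    @property
    def offS_pass(self) -> bool:
        return self._off_common and OFF_S_RATE[0] <= self.spont_Hz <= OFF_S_RATE[1]


def _c0_overshoot(v: np.ndarray) -> bool:
    """The cell's action potentials overshoot 0 mV.

    Spike-like events are voltage peaks of at least 20 mV prominence rising
    above -40 mV.  A cell fails only when it produces such events but none
    of them reaches 0 mV (its spikes top out subthreshold); a quiescent
    trace passes, and decaying late-burst spikelets below 0 mV do not fail a
    cell that otherwise fires overshooting spikes.
    """
    peaks, _ = signal.find_peaks(v, height=-40.0, prominence=20.0)
    return bool((v[peaks] > 0.0).any()) if peaks.size else True


def evaluate_point(morph: Morphology, triple: tuple[float, float, float],
                   config: SimulationConfig = SimulationConfig(),
                   table: DistributionTable = DEFAULT_DISTRIBUTION,
                   spont_duration: float = 1500.0) -> ConstraintReport:
    """Run the spontaneous and hyperpolarizing-step protocols on one triple.

    Resting potential and spontaneous rate are measured over the final
    1000 ms of the spontaneous run (after the configured settling); the step
    protocol is -0.2 nA for 500 ms with 1 s pre and 500 ms post.
    Deterministic for fixed inputs.
    """
    cfg = replace(config, record_sites=("soma",))
    cell = build_cell(morph, table, triple, cfg)
    spont = simulate(cell, make_protocol("spontaneous",
                                         duration=spont_duration), cfg)
    t, v = spont.time, spont["soma"]
    window = (max(0.0, spont_duration - 1000.0), spont_duration)
    sel = (t >= window[0]) & (t <= window[1])
    spont_rate = firing_rate(detect_spikes(t, v), window)
    rest = mean_vm_spike_removed(t[sel], v[sel], min_retained_ms=500.0)

    step_rec = simulate(cell, make_protocol("hyp_step_200pA"), cfg)
    metrics = step_response_metrics(step_rec)
    return ConstraintReport(
        c0_pass=_c0_overshoot(v) and _c0_overshoot(step_rec["soma"]),
        rest_mV=rest.value,
        spont_Hz=spont_rate,
        spikes_during_hyp=metrics.spikes_during_step,
        rebound_rate_Hz=metrics.rebound_burst_rate,
    )


def classify_point(report: ConstraintReport) -> str:
    """Phenotype label for a constraint report (pure, idempotent).

    The ON / OFF_T / OFF_S conditions are mutually exclusive by construction
    (disjoint resting and rate ranges); C0 failure forces ``none``.
    """
    if not report.c0_pass:
        return "none"
    if report.on_pass:
        return "ON"
    if report.offT_pass:
        return "OFF_T"
    if report.offS_pass:
        return "OFF_S"
    return "none"


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

DEFAULT_BOUNDS = (1e-15, 1e-1)  # S/cm^2


@dataclass(frozen=True)
class GridSpec:
    """Lattice of conductance triples (values in S/cm^2, each axis sorted)."""
    gnap_values: tuple
    gt_values: tuple
    gh_values: tuple

    @classmethod
    def logarithmic(cls, bounds=DEFAULT_BOUNDS, step: float = 10.0
                    ) -> "GridSpec":
        lo, hi = np.log10(bounds[0]), np.log10(bounds[1])
        n = int(round((hi - lo) / np.log10(step))) + 1
        vals = tuple(np.logspace(lo, hi, n))
        return cls(vals, vals, vals)

    @property
    def shape(self):
        return (len(self.gnap_values), len(self.gt_values),
                len(self.gh_values))

    def points(self):
        for i, gnap in enumerate(self.gnap_values):
            for j, gt in enumerate(self.gt_values):
                for k, gh in enumerate(self.gh_values):
                    yield (i, j, k), (gnap, gt, gh)


@dataclass
class ConductanceGrid:
    spec: GridSpec
    labels: np.ndarray            # object array of phenotype strings
    reports: dict                 # (i,j,k) -> ConstraintReport | Exception
    failures: dict = field(default_factory=dict)

    def label_counts(self) -> dict:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


def grid_search(morph: Morphology, grid_spec: GridSpec,
                config: SimulationConfig = SimulationConfig(),
                table: DistributionTable = DEFAULT_DISTRIBUTION,
                evaluate_fn=None, cache: dict | None = None
                ) -> ConductanceGrid:
    """Evaluate and classify every lattice point.

    Results depend only on the triple, never on evaluation order; a ``cache``
    dict (triple -> report) makes the search resumable.  Individual point
    failures are recorded in ``failures`` rather than aborting the search.
    ``evaluate_fn(triple) -> ConstraintReport`` may replace the simulation
    (used by logic tests and by refinement passes sharing a cache).
    """
    if evaluate_fn is None:
        def evaluate_fn(triple):
            return evaluate_point(morph, triple, config, table)
    cache = cache if cache is not None else {}
    labels = np.empty(grid_spec.shape, dtype=object)
    reports = {}
    failures = {}
    for idx, triple in grid_spec.points():
        key = tuple(float(x) for x in triple)
        try:
            report = cache.get(key)
            if report is None:
                report = evaluate_fn(triple)
                cache[key] = report
            reports[idx] = report
            labels[idx] = classify_point(report)
        except Exception as exc:  # pragma: no cover - defensive
            failures[idx] = exc
            labels[idx] = "none"
    grid = ConductanceGrid(grid_spec, labels, reports, failures)
    _assert_disjoint(grid)
    return grid


def _assert_disjoint(grid: ConductanceGrid) -> None:
    # each point carries exactly one label by construction; the phenotype
    # rules themselves are mutually exclusive, asserted here for safety
    for idx, report in grid.reports.items():
        if isinstance(report, ConstraintReport):
            assert (int(report.on_pass) + int(report.offT_pass)
                    + int(report.offS_pass)) <= 1


def refine_spec(grid: ConductanceGrid, label: str, n_linear: int = 5
                ) -> GridSpec | None:
    """Linear-step refinement lattice over the bounding box of a label.

    g_NaP and g_T get linear steps across the labelled bounding box
    (extended one coarse step outward); g_h keeps the coarse logarithmic
    values inside the box.
    """
    hits = np.argwhere(grid.labels == label)
    if hits.size == 0:
        return None
    spec = grid.spec

    def axis_range(values, lo_i, hi_i):
        lo = values[max(0, lo_i - 1)]
        hi = values[min(len(values) - 1, hi_i + 1)]
        return lo, hi

    lo_nap, hi_nap = axis_range(spec.gnap_values, hits[:, 0].min(),
                                hits[:, 0].max())
    lo_t, hi_t = axis_range(spec.gt_values, hits[:, 1].min(),
                            hits[:, 1].max())
    gh = tuple(spec.gh_values[hits[:, 2].min():hits[:, 2].max() + 1])
    return GridSpec(
        tuple(np.linspace(lo_nap, hi_nap, n_linear)),
        tuple(np.linspace(lo_t, hi_t, n_linear)),
        gh)


@dataclass(frozen=True)
class ValidSet:
    phenotype: str
    members: tuple                # lattice index triples
    bounding_box: tuple           # ((i0,i1),(j0,j1),(k0,k1)) inclusive
    is_singleton: bool


def extract_valid_sets(grid: ConductanceGrid,
                       connectivity: int = 6) -> list[ValidSet]:
    """Connected components of each phenotype label on the lattice.

    Face adjacency (6 neighbors) is the default, matching the strictest
    reading of "connected"; ``connectivity=26`` allows edge and corner
    neighbors.  Singleton components are flagged (the search discards
    distributions producing only isolated points).
    """
    if connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 26:
        structure = ndimage.generate_binary_structure(3, 3)
    else:
        raise ValueError("connectivity must be 6 or 26")
    out = []
    for phen in ("ON", "OFF_T", "OFF_S"):
        mask = grid.labels == phen
        lab, n = ndimage.label(mask, structure=structure)
        for comp in range(1, n + 1):
            members = tuple(map(tuple, np.argwhere(lab == comp)))
            arr = np.asarray(members)
            bbox = tuple((int(arr[:, ax].min()), int(arr[:, ax].max()))
                         for ax in range(3))
            out.append(ValidSet(phen, members, bbox, len(members) == 1))
    return out


# ---------------------------------------------------------------------------
# Validation protocols (V1-V3)
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    phenotype: str
    v1: dict                      # step amplitude (nA) -> OscillationReport
    v2: list                      # regime sequence as observed, in order
    v3_table: list                # (amplitude, mean_vm, cv) rows
    v3_slope: float               # d(CV)/d(mean Vm), least squares


def _regime(train, window_ms: float) -> str:
    """Classify a spiking regime within one stimulus level.

    Artifact definitions: silent = no spikes; regular = CV < 0.3;
    irregular = CV >= 0.3; burst = irregular with clustered intervals
    (>= half of the ISIs shorter than 20 ms while the span of spikes covers
    less than half the window, i.e. rebound-style clusters).
    """
    if len(train) == 0:
        return "silent"
    times = train.spike_times
    if len(train) < 3:
        span = times[-1] - times[0]
        return "burst" if span < 0.25 * window_ms else "irregular"
    cv = cv_isi(train)
    isis = np.diff(times)
    clustered = (np.mean(isis < 20.0) >= 0.5
                 and (times[-1] - times[0]) < 0.5 * window_ms)
    if clustered and cv >= 0.3:
        return "burst"
    if cv >= 0.3:
        return "irregular"
    return "regular"


def validate_point(morph: Morphology, triple: tuple[float, float, float],
                   config: SimulationConfig = SimulationConfig(),
                   table: DistributionTable = DEFAULT_DISTRIBUTION,
                   phenotype: str | None = None,
                   step_duration: float = 2000.0,
                   hold_duration: float = 10000.0) -> ValidationReport:
    """Run the V1-V3 validation protocols on an OFF-classified triple.

    V1: oscillation analysis per staircase hyperpolarization level;
    V2: the observed regime sequence across increasing step amplitudes;
    V3: CV of ISI versus spike-removed mean potential under -20 pA
    increments, with its least-squares slope.
    """
    if phenotype is None:
        phenotype = classify_point(evaluate_point(morph, triple, config,
                                                  table))
    if phenotype not in ("OFF_T", "OFF_S"):
        raise ValueError(
            f"validation applies only to OFF cells, got {phenotype!r}")
    cfg = replace(config, record_sites=("soma",))
    cell = build_cell(morph, table, triple, cfg)

    stair = make_protocol("staircase_fig9", step_duration=step_duration)
    rec = simulate(cell, stair, cfg)
    t, v = rec.time, rec["soma"]
    v1 = {}
    v2 = []
    for s in rec.protocol.steps:
        t0, t1 = s.t_start, s.t_start + s.duration
        sel = (t >= t0) & (t < t1)
        train = detect_spikes(t[sel], v[sel])
        regime = _regime(train, s.duration)
        if not v2 or v2[-1] != regime:
            v2.append(regime)
        if s.duration >= 2000.0:
            try:
                v1[s.amplitude] = oscillation_report(t[sel], v[sel])
            except InsufficientDataError:
                pass

    cv_prot = make_protocol("cv_steps", hold_duration=hold_duration)
    rec_cv = simulate(cell, cv_prot, cfg)
    t, v = rec_cv.time, rec_cv["soma"]
    rows = []
    for s in rec_cv.protocol.steps:
        # drop the first fifth of each hold as the adaptation transient
        sel = (t >= s.t_start + 0.2 * s.duration) & (t < s.t_start + s.duration)
        train = detect_spikes(t[sel], v[sel])
        mean_vm = mean_vm_spike_removed(t[sel], v[sel],
                                        min_retained_ms=200.0)
        try:
            cv = cv_isi(train)
        except InsufficientDataError:
            cv = np.nan
        rows.append((s.amplitude, mean_vm.value, cv))
    ok = [(vm, cv) for _, vm, cv in rows
          if np.isfinite(vm) and np.isfinite(cv)]
    if len(ok) >= 2:
        slope = float(stats.linregress([r[0] for r in ok],
                                       [r[1] for r in ok]).slope)
    else:
        slope = np.nan
    return ValidationReport(phenotype, v1, v2, rows, slope)


# ---------------------------------------------------------------------------
# Morphology-reduction experiment
# ---------------------------------------------------------------------------

REDUCTION_FACTORS = (1.0, 0.9, 0.8, 0.7, 0.6, 0.5)
REDUCTION_TARGETS = ("dendrite_diameter", "dendrite_length", "soma")


def morphology_reduction_experiment(
        morph: Morphology, triple: tuple[float, float, float],
        config: SimulationConfig = SimulationConfig(),
        table: DistributionTable = DEFAULT_DISTRIBUTION,
        factors=REDUCTION_FACTORS, targets=REDUCTION_TARGETS,
        spont_duration: float = 1500.0):
    """Shrink dendrites or soma stepwise and record the response changes.

    For each scaling target and factor: spontaneous rate, rebound burst
    rate, spike peak amplitude, and maximal dV/dt, as a tidy DataFrame.
    Channel densities (per area) are untouched, so shrinking membrane
    removes total conductance.
    """
    import pandas as pd

    cfg = replace(config, record_sites=("soma",))
    rows = []
    for target in targets:
        for factor in factors:
            scaled = scale_morphology(morph, target, factor)
            cell = build_cell(scaled, table, triple, cfg)
            spont = simulate(cell, make_protocol(
                "spontaneous", duration=spont_duration), cfg)
            t, v = spont.time, spont["soma"]
            window = (max(0.0, spont_duration - 1000.0), spont_duration)
            rate = firing_rate(detect_spikes(t, v), window)
            step = simulate(cell, make_protocol("hyp_step_200pA"), cfg)
            metrics = step_response_metrics(step)
            vs = step["soma"]
            rows.append({
                "target": target,
                "factor": factor,
                "spont_rate_Hz": rate,
                "rebound_rate_Hz": metrics.rebound_burst_rate,
                "spike_peak_mV": float(max(v.max(), vs.max())),
                "max_dvdt_mV_ms": float(
                    max(np.diff(v).max(), np.diff(vs).max()) / cfg.dt),
            })
    return pd.DataFrame(rows)
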