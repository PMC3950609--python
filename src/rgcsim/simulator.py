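"""Current-clamp simulation of a compartmental cell.

``build_cell`` turns a morphology plus the regional channel distribution and
the free conductance triple (g_NaP, g_T, g_h) into flat per-compartment
arrays (Hines-ordered, parents before children); ``simulate`` integrates the
coupled cable/channel/calcium system under a stimulus protocol with an
implicit tree solve per step.  Output is bit-reproducible for identical
inputs.

Named recording sites: ``soma``, ``socb`` (midpoint of the sodium-channel
band), ``distal_axon`` (distal end of the axon), ``dendrite`` (a distal
dendritic tip), ``proximal_axon``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernel
from .membrane import (DEFAULT_CONSTANTS, DEFAULT_DISTRIBUTION,
                       DistributionTable, GatingState, MembraneConstants,
                       ht_d_equilibrium)
from .morphology import Morphology, Region, discretize

CURRENT_NAMES = ("L", "Na", "Ca", "K", "KA", "KCa", "h", "T", "NaP")


class NumericalError(RuntimeError):
    """Solver produced a non-finite voltage."""


@dataclass(frozen=True)
class SimulationConfig:
    dt: float = 0.025                  # ms
    axial_resistivity: float = 110.0   # Ohm cm
    settle_time: float = 500.0         # ms simulated before t = 0
    initial_V: float = -65.0           # mV
    solver: str = "backward_euler"     # or "crank_nicolson"
    record_sites: tuple = ("soma", "socb", "distal_axon")
    record_currents: bool = False
    max_segment_length: float = 40.0   # um, spatial discretization

    def __post_init__(self):
        if self.dt <= 0 or self.axial_resistivity <= 0:
            raise ValueError("dt and axial_resistivity must be positive")
        if self.solver not in ("backward_euler", "crank_nicolson"):
            raise ValueError(f"unknown solver {self.solver!r}")


@dataclass(frozen=True)
class StimStep:
    t_start: float      # ms, relative to protocol start
    duration: float     # ms
    amplitude: float    # nA (negative = hyperpolarizing)
    site: str = "soma"


@dataclass(frozen=True)
class StimulusProtocol:
    steps: tuple
    duration: float     # total simulated time, ms
    name: str = "custom"

    def __post_init__(self):
        by_site: dict[str, list[StimStep]] = {}
        for s in self.steps:
            if not np.isfinite(s.amplitude):
                raise ValueError("stimulus amplitude must be finite")
            by_site.setdefault(s.site, []).append(s)
        for site, steps in by_site.items():
            steps = sorted(steps, key=lambda s: s.t_start)
            for a, b in zip(steps[:-1], steps[1:]):
                if a.t_start + a.duration > b.t_start + 1e-9:
                    raise ValueError(f"overlapping stimulus steps at {site}")


def make_protocol(name: str, **params) -> StimulusProtocol:
    """Construct one of the standard current-clamp protocols.

    ``spontaneous``
        no stimulus, 1500 ms (``duration``).
    ``hyp_step_200pA``
        -0.2 nA for 500 ms, with >= 1 s pre-stimulus and 500 ms post.
    ``staircase_fig9``
        seven increasing hyperpolarizing steps of -0.02 nA increments, each
        2 s (``step_duration``), then a single -0.2 nA step of 0.5 s.
    ``cv_steps``
        -20 pA increments to -80 pA, each held ``hold_duration`` (default
        10 s) for interspike-interval statistics.
    ``on_depolarize``
        sustained depolarizing holding current (default +50 pA).
    """
    if name == "spontaneous":
        dur = params.get("duration", 1500.0)
        return StimulusProtocol(steps=(), duration=dur, name=name)
    if name == "hyp_step_200pA":
        pre = params.get("pre", 1000.0)
        step = params.get("step_duration", 500.0)
        post = params.get("post", 500.0)
        amp = params.get("amplitude", -0.2)
        return StimulusProtocol(
            steps=(StimStep(pre, step, amp),),
            duration=pre + step + post, name=name)
    if name == "staircase_fig9":
        pre = params.get("pre", 500.0)
        step = params.get("step_duration", 2000.0)
        final = params.get("final_duration", 500.0)
        steps = [StimStep(pre + k * step, step, -0.02 * (k + 1))
                 for k in range(7)]
        steps.append(StimStep(pre + 7 * step, final, -0.2))
        return StimulusProtocol(
            steps=tuple(steps), duration=pre + 7 * step + final + 200.0,
            name=name)
    if name == "cv_steps":
        pre = params.get("pre", 1000.0)
        hold = params.get("hold_duration", 10000.0)
        amps = params.get("amplitudes", (-0.02, -0.04, -0.06, -0.08))
        steps = [StimStep(pre + k * hold, hold, a)
                 for k, a in enumerate(amps)]
        return StimulusProtocol(
            steps=tuple(steps), duration=pre + len(amps) * hold, name=name)
    if name == "on_depolarize":
        pre = params.get("pre", 500.0)
        hold = params.get("hold_duration", 10000.0)
        amp = params.get("amplitude", 0.05)
        return StimulusProtocol(
            steps=(StimStep(pre, hold, amp),), duration=pre + hold,
            name=name)
    raise ValueError(f"unknown protocol {name!r}")


@dataclass
class SimCell:
    """A morphology compiled to flat, Hines-ordered simulation arrays."""
    morph: Morphology              # discretized
    parent: np.ndarray             # int32, parent[0] = -1
    area: np.ndarray               # cm^2 per compartment
    gax: np.ndarray                # uS, coupling to parent
    cap: np.ndarray                # nF
    densities: dict                # channel -> S/cm^2 array
    conductances: dict             # channel -> uS array
    sites: dict                    # name -> compartment index
    triple: tuple
    table: DistributionTable
    constants: MembraneConstants
    config: SimulationConfig

    @property
    def n_compartments(self) -> int:
        return self.parent.shape[0]

    def morphology_hash(self) -> str:
        h = hashlib.sha256()
        for c in self.morph.topological():
            h.update(f"{c.region.value}:{c.length:.9g}:{c.diameter:.9g};"
                     .encode())
        return h.hexdigest()[:16]


def build_cell(morph: Morphology,
               table: DistributionTable = DEFAULT_DISTRIBUTION,
               triple: tuple[float, float, float] = (0.0, 0.0, 0.0),
               config: SimulationConfig = SimulationConfig(),
               constants: MembraneConstants = DEFAULT_CONSTANTS) -> SimCell:
    """Assign channel densities and axial couplings to every compartment.

    The morphology is discretized to ``config.max_segment_length`` here so
    the solver always sees compartments short enough for the cable
    resolution; axial conductances follow the cylinder closed form
    g = 1 / (R_half(child) + R_half(parent)) with
    R_half = rho * (L/2) / (pi d^2 / 4).
    """
    from .membrane import compartment_conductances

    if min(triple) < 0:
        raise ValueError("conductance triple must be non-negative")
    morph = discretize(morph, config.max_segment_length)
    comps = morph.topological()
    if comps[0].region is not Region.SOMA:
        raise ValueError("root must be the soma")
    index = {c.id: i for i, c in enumerate(comps)}
    N = len(comps)
    parent = np.full(N, -1, dtype=np.int32)
    area = np.empty(N)
    gax = np.zeros(N)
    rho = config.axial_resistivity * 1e4  # Ohm um

    def half_res(c):
        return rho * (c.length / 2.0) / (np.pi * c.diameter ** 2 / 4.0)

    dens = {ch: np.empty(N) for ch in
            ("g_Na", "g_Ca", "g_K", "g_KA", "g_KCa_max", "g_L", "g_h",
             "g_NaP", "g_T")}
    for i, c in enumerate(comps):
        area[i] = c.area * 1e-8  # um^2 -> cm^2
        if c.parent_id is not None:
            j = index[c.parent_id]
            parent[i] = j
            r = half_res(c) + half_res(comps[j])
            gax[i] = 1e6 / r  # uS
        cd = compartment_conductances(table, c.region, c.in_socb, triple)
        for ch in dens:
            dens[ch][i] = getattr(cd, ch)
    cond = {ch: dens[ch] * area * 1e6 for ch in dens}  # S/cm^2 -> uS
    cap = constants.C_m * area * 1e3                   # uF/cm^2 -> nF

    sites = {"soma": 0}
    axonal = [(i, c) for i, c in enumerate(comps) if c.region.is_axonal]
    socb = [(i, c) for i, c in axonal if c.in_socb]
    if socb:
        mid = 0.5 * (min(c.arc_from_soma for _, c in socb)
                     + max(c.arc_from_soma for _, c in socb))
        sites["socb"] = min(socb, key=lambda t: abs(t[1].arc_from_soma - mid))[0]
    if axonal:
        sites["distal_axon"] = max(axonal, key=lambda t: t[1].arc_from_soma)[0]
        sites["proximal_axon"] = min(axonal,
                                     key=lambda t: t[1].arc_from_soma)[0]
    dend = [(i, c) for i, c in enumerate(comps) if c.region is Region.DENDRITE]
    if dend:
        sites["dendrite"] = dend[-1][0]
        # first compartment of each primary dendrite (for the dendritic
        # input-resistance mode)
        sites["_primary_dendrites"] = tuple(
            i for i, c in dend if c.parent_id == comps[0].id)
    return SimCell(morph=morph, parent=parent, area=area, gax=gax, cap=cap,
                   densities=dens, conductances=cond, sites=sites,
                   triple=tuple(triple), table=table, constants=constants,
                   config=config)


@dataclass
class Recording:
    """Multi-site voltage traces with stimulus annotation."""
    time: np.ndarray               # ms, uniform at dt, starts at 0
    dt: float
    traces: dict                   # site name -> mV array
    stim: np.ndarray               # nA injected at the soma site, per sample
    protocol: StimulusProtocol
    currents: dict | None = None   # channel -> mA/cm^2 at the soma
    metadata: dict = field(default_factory=dict)

    def __getitem__(self, site: str) -> np.ndarray:
        return self.traces[site]

    def to_dataframe(self):
        import pandas as pd
        data = {"t_ms": self.time}
        data.update({f"V_{k}_mV": v for k, v in self.traces.items()})
        data["I_stim_nA"] = self.stim
        if self.currents:
            data.update({f"I_{k}_mA_cm2": v for k, v in self.currents.items()})
        return pd.DataFrame(data)

    def to_hdf5(self, path) -> None:
        """Write the recording to an HDF5 container (voltages under
        ``/voltage/<site>``, per-channel soma currents under ``/current``)."""
        import h5py
        with h5py.File(path, "w") as f:
            f.create_dataset("time_ms", data=self.time)
            f.create_dataset("stim_nA", data=self.stim)
            g = f.create_group("voltage")
            for site, v in self.traces.items():
                g.create_dataset(site, data=v)
            if self.currents:
                c = f.create_group("current")
                for name, v in self.currents.items():
                    c.create_dataset(name, data=v)
            for key, value in self.metadata.items():
                f.attrs[key] = str(value)


def _init_state(cell: SimCell, V0: float):
    N = cell.n_compartments
    V = np.full(N, V0)
    gs = GatingState.steady_state(V0)
    hT0, d0 = ht_d_equilibrium(V0)
    arrays = {g: np.full(N, getattr(gs, g))
              for g in ("m", "h", "c", "n", "a", "h_A", "l", "m_T", "p")}
    arrays["h_T"] = np.full(N, hT0)
    arrays["d"] = np.full(N, d0)
    Ca = np.full(N, cell.constants.Ca_res)
    return V, arrays, Ca


def _stim_arrays(protocol: StimulusProtocol, cell: SimCell, dt: float,
                 nsteps: int):
    sites = sorted({s.site for s in protocol.steps}) or ["soma"]
    comp_of = {}
    for name in sites:
        if name not in cell.sites:
            raise ValueError(f"unknown stimulus site {name!r}")
        comp_of[name] = cell.sites[name]
    amps = np.zeros((len(sites), nsteps))
    for s in protocol.steps:
        k = sites.index(s.site)
        i0 = int(round(s.t_start / dt))
        i1 = int(round((s.t_start + s.duration) / dt))
        amps[k, i0:min(i1, nsteps)] += s.amplitude
    comps = np.array([comp_of[name] for name in sites], dtype=np.int64)
    return comps, amps, sites


def simulate(cell: SimCell, protocol: StimulusProtocol,
             config: SimulationConfig | None = None) -> Recording:
    """Integrate the cell under a protocol and return the recording.

    The cell is initialized uniformly at ``initial_V`` with gates at their
    steady state and calcium at the residual level, then settled for
    ``settle_time`` with no stimulus before protocol time zero.  Recording
    covers t = 0 .. protocol.duration at every dt (sample 0 is the
    post-settle state).
    """
    config = config or cell.config
    k = cell.constants
    dt = config.dt
    V, g, Ca = _init_state(cell, config.initial_V)
    rt2f = 1e3 * k.R_gas * k.T_kelvin / (2.0 * k.F)
    ca_coef = 3.0 * 1e-3 / (2.0 * k.F * k.r_shell * 1e-4)  # (mA/cm^2) -> M/ms
    use_cn = config.solver == "crank_nicolson"

    missing = [s for s in config.record_sites if s not in cell.sites]
    if missing:
        raise ValueError(f"recording sites absent from this cell: {missing}")
    rec_sites = list(config.record_sites)
    rec_idx = np.array([cell.sites[s] for s in rec_sites], dtype=np.int64)

    def run(nsteps, stim_comps, stim_amps, record_currents):
        recV = np.empty((len(rec_idx), nsteps + 1))
        recV[:, 0] = V[rec_idx]
        cur = np.zeros((9, nsteps + 1)) if record_currents else np.zeros((9, 1))
        status = _kernel.integrate(
            V, g["m"], g["h"], g["c"], g["n"], g["a"], g["h_A"], g["l"],
            g["m_T"], g["h_T"], g["d"], g["p"], Ca,
            cell.parent, cell.gax, cell.cap,
            cell.conductances["g_Na"], cell.densities["g_Ca"],
            cell.conductances["g_K"], cell.conductances["g_KA"],
            cell.conductances["g_KCa_max"], cell.conductances["g_L"],
            cell.conductances["g_h"], cell.conductances["g_NaP"],
            cell.conductances["g_T"],
            cell.area, dt, nsteps, use_cn,
            stim_comps, stim_amps,
            rec_idx, recV, record_currents, cur,
            k.V_K, k.V_L, k.V_h, k.V_T, k.V_Na,
            k.Ca_e, k.Ca_diss, k.Ca_res, k.tau_Ca, ca_coef, rt2f)
        return status, recV, cur

    n_settle = int(round(config.settle_time / dt))
    if n_settle:
        empty = np.zeros((1, n_settle))
        comp0 = np.array([0], dtype=np.int64)
        status, _, _ = run(n_settle, comp0, empty, False)
        if status >= 0:
            raise NumericalError(
                f"non-finite voltage during settling at t = "
                f"{(status + 1) * dt - config.settle_time:.3f} ms")

    nsteps = int(round(protocol.duration / dt))
    stim_comps, stim_amps, stim_sites = _stim_arrays(protocol, cell, dt,
                                                     nsteps)
    status, recV, cur = run(nsteps, stim_comps, stim_amps,
                            config.record_currents)
    if status >= 0:
        raise NumericalError(
            f"non-finite voltage at t = {(status + 1) * dt:.3f} ms")

    time = np.arange(nsteps + 1) * dt
    stim_total = np.zeros(nsteps + 1)
    if stim_amps.size:
        soma_like = stim_amps.sum(axis=0)
        stim_total[1:] = soma_like
    return Recording(
        time=time, dt=dt,
        traces={s: recV[i] for i, s in enumerate(rec_sites)},
        stim=stim_total, protocol=protocol,
        currents=({c: cur[i] for i, c in enumerate(CURRENT_NAMES)}
                  if config.record_currents else None),
        metadata={"morphology_hash": cell.morphology_hash(),
                  "triple": cell.triple,
                  "solver": config.solver, "dt": dt,
                  "n_compartments": cell.n_compartments},
    )
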