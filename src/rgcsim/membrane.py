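"""Membrane dynamics: channel kinetics, calcium shell, conductance tables.

Nine currents make up the membrane model: leak, fast Na, high-voltage
activated (HVA) Ca, delayed-rectifier K, A-type K, Ca-activated K, the
hyperpolarization-activated mixed cation current (h), the low-voltage
activated T-type Ca current, and the persistent Na current (NaP).  The last
three carry the free maximal conductances (g_NaP, g_T, g_h) explored by the
tuning module; everything else is fixed.

Gating follows first-order Hodgkin-Huxley kinetics dx/dt = alpha(1-x) -
beta*x for all gates except the T-current inactivation pair (h_T, d), which
is a three-state linear scheme (available / closed-1 / closed-2) advanced
implicitly.  The HVA Ca current drives a sub-membrane calcium shell whose
concentration sets both the dynamic Ca reversal potential (Nernst) and the
Ca-activated K conductance (Hill coefficient 2).

Sign convention: ionic currents are g*(gating)*(V - E) in mA/cm^2, positive
outward; the voltage equation is C dV/dt = -sum(I_ion) + I_axial + I_stim.

Units: mV, ms, S/cm^2, mA/cm^2, uF/cm^2, M (molar), um.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MembraneConstants:
    """Fixed simulation constants (32 C throughout)."""
    C_m: float = 1.0          # uF/cm^2
    V_K: float = -70.0        # mV
    V_L: float = -60.0
    V_h: float = 0.0
    V_T: float = 120.0        # fixed reversal of the T-type current
    V_Na: float = 35.0
    Ca_e: float = 1.8e-3      # M, extracellular
    Ca_diss: float = 1e-6     # M, K(Ca) dissociation constant
    Ca_res: float = 1e-7      # M, residual intracellular level
    r_shell: float = 0.1      # um, depth of the sub-membrane shell
    tau_Ca: float = 1.5       # ms
    R_gas: float = 8.314      # J/(mol K)
    F: float = 9.684e4        # C/mol
    T_kelvin: float = 305.15  # 32 C
    gL0: float = 8e-6         # S/cm^2, unadjusted leak
    gKCa_max: float = 5e-5    # S/cm^2, generic K(Ca) ceiling


DEFAULT_CONSTANTS = MembraneConstants()

GATE_NAMES = ("m", "h", "c", "n", "a", "h_A", "l", "m_T", "h_T", "d", "p")


# ---------------------------------------------------------------------------
# Rate functions
# ---------------------------------------------------------------------------

def _ramp(x: float, a: float, b: float) -> float:
    """-a*x / (exp(-b*x) - 1) with the removable singularity at x = 0.

    Within 1e-6 mV of the singularity the second-order series
    (a/b)(1 + bx/2 + (bx)^2/12) is used.
    """
    if abs(x) < 1e-6:
        bx = b * x
        return (a / b) * (1.0 + 0.5 * bx + bx * bx / 12.0)
    return -a * x / math.expm1(-b * x)


def _rates_p(V: float) -> tuple[float, float]:
    # Persistent Na gate: sigmoidal steady state with a piecewise time
    # constant, continuous at V = -40 (both branches give 0.165 ms there).
    p_inf = 1.0 / (1.0 + math.exp(-(V + 48.0) / 10.0))
    if V < -40.0:
        tau = 0.025 + 0.14 * math.exp((V + 40.0) / 10.0)
    else:
        tau = 0.02 + 0.145 * math.exp(-(V + 40.0) / 10.0)
    return p_inf / tau, (1.0 - p_inf) / tau


def _gate_rates(gate: str, V: float) -> tuple[float, float]:
    if gate == "m":
        return _ramp(V + 30.0, 0.6, 0.1), 20.0 * math.exp(-(V + 55.0) / 18.0)
    if gate == "h":
        return (0.4 * math.exp(-(V + 50.0) / 20.0),
                6.0 / (1.0 + math.exp(-0.1 * (V + 20.0))))
    if gate == "c":
        return _ramp(V + 13.0, 0.3, 0.1), 10.0 * math.exp(-(V + 38.0) / 18.0)
    if gate == "n":
        return _ramp(V + 40.0, 0.02, 0.1), 0.4 * math.exp(-(V + 50.0) / 80.0)
    if gate == "a":
        return _ramp(V + 90.0, 0.006, 0.1), 0.1 * math.exp(-(V + 30.0) / 10.0)
    if gate == "h_A":
        return (0.04 * math.exp(-(V + 70.0) / 20.0),
                0.6 / (1.0 + math.exp(-0.1 * (V + 40.0))))
    if gate == "l":
        return (math.exp(0.08316 * (V + 75.0)),
                math.exp(0.033264 * (V + 75.0)))
    if gate == "m_T":
        denom = 1.7 + math.exp(-(V + 28.8) / 13.5)
        return 1.0 / denom, math.exp(-(V + 63.0) / 7.8) / denom
    if gate == "h_T":
        alpha = math.exp(-(V + 160.3) / 17.8)
        root = math.sqrt(0.25 + math.exp((V + 83.5) / 6.3))
        return alpha, alpha * (root - 0.5)
    if gate == "d":
        root = math.sqrt(0.25 + math.exp((V + 83.5) / 6.3))
        alpha = (1.0 + math.exp((V + 37.4) / 30.0)) / (240.0 * (0.5 + root))
        return alpha, alpha * root
    if gate == "p":
        return _rates_p(V)
    raise ValueError(f"unknown gate {gate!r}")


def gate_kinetics(gate: str, V: float) -> tuple[float, float, float, float]:
    """Return (alpha, beta, x_inf, tau) for one gate at a clamped voltage.

    For the coupled (h_T, d) pair the returned x_inf and tau are the
    single-gate reductions alpha/(alpha+beta) and 1/(alpha+beta); the true
    coupled equilibrium is available from :func:`ht_d_equilibrium`.
    """
    if not math.isfinite(V):
        raise ValueError("V must be finite")
    alpha, beta = _gate_rates(gate, V)
    s = alpha + beta
    return alpha, beta, alpha / s, 1.0 / s


# ---------------------------------------------------------------------------
# Gating state
# ---------------------------------------------------------------------------

@dataclass
class GatingState:
    """All eleven gating variables of one compartment (each in [0, 1])."""
    m: float = 0.0
    h: float = 1.0
    c: float = 0.0
    n: float = 0.0
    a: float = 0.0
    h_A: float = 1.0
    l: float = 0.5
    m_T: float = 0.0
    h_T: float = 1.0
    d: float = 0.0
    p: float = 0.0

    @classmethod
    def steady_state(cls, V: float) -> "GatingState":
        vals = {g: gate_kinetics(g, V)[2] for g in GATE_NAMES
                if g not in ("h_T", "d")}
        hT, d = ht_d_equilibrium(V)
        return cls(**vals, h_T=hT, d=d)

    def clamp(self) -> None:
        for g in GATE_NAMES:
            setattr(self, g, min(1.0, max(0.0, getattr(self, g))))


def ht_d_equilibrium(V: float) -> tuple[float, float]:
    """Stationary point of the three-state T-inactivation scheme at fixed V."""
    a_h, b_h = _gate_rates("h_T", V)
    a_d, b_d = _gate_rates("d", V)
    # detailed balance with the shared third state s = 1 - h_T - d
    s = 1.0 / (1.0 + a_h / b_h + b_d / a_d)
    return (a_h / b_h) * s, (b_d / a_d) * s


def advance_gates(state: GatingState, V: float, dt: float) -> GatingState:
    """Advance all gates one step at frozen voltage.

    First-order gates use the exact exponential update
    x <- x_inf + (x - x_inf) exp(-dt/tau); the coupled (h_T, d) pair takes
    one backward-Euler step of its 2x2 linear system.  All outputs are
    clamped to [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    new = replace(state)
    for g in GATE_NAMES:
        if g in ("h_T", "d"):
            continue
        _, _, x_inf, tau = gate_kinetics(g, V)
        x = getattr(state, g)
        setattr(new, g, x_inf + (x - x_inf) * math.exp(-dt / tau))
    new.h_T, new.d = advance_ht_d(state.h_T, state.d, V, dt)
    new.clamp()
    return new


def advance_ht_d(hT: float, d: float, V: float,
                 dt: float) -> tuple[float, float]:
    """One implicit (backward Euler) step of the (h_T, d) pair at frozen V."""
    a_h, b_h = _gate_rates("h_T", V)
    a_d, b_d = _gate_rates("d", V)
    # (1 + dt(a_h+b_h)) h' + dt a_h d' = h + dt a_h
    # dt b_d h' + (1 + dt(a_d+b_d)) d' = d + dt b_d
    a11 = 1.0 + dt * (a_h + b_h)
    a12 = dt * a_h
    a21 = dt * b_d
    a22 = 1.0 + dt * (a_d + b_d)
    r1 = hT + dt * a_h
    r2 = d + dt * b_d
    det = a11 * a22 - a12 * a21
    hT_new = (r1 * a22 - a12 * r2) / det
    d_new = (a11 * r2 - a21 * r1) / det
    return (min(1.0, max(0.0, hT_new)), min(1.0, max(0.0, d_new)))


# ---------------------------------------------------------------------------
# Calcium
# ---------------------------------------------------------------------------

def nernst_vca(Ca_i: float,
               constants: MembraneConstants = DEFAULT_CONSTANTS) -> float:
    """Dynamic Ca reversal potential (mV) from the Nernst relation (z = 2)."""
    if Ca_i <= 0:
        raise ValueError("Ca_i must be positive")
    rt_2f = constants.R_gas * constants.T_kelvin / (2.0 * constants.F)
    return 1e3 * rt_2f * math.log(constants.Ca_e / Ca_i)


_CA_FLOOR = 1e-12  # M; keeps the shell concentration positive


def advance_calcium(Ca_i: float, I_Ca: float, dt: float,
                    constants: MembraneConstants = DEFAULT_CONSTANTS) -> float:
    """Advance the sub-membrane calcium shell one step at frozen I_Ca.

    dCa/dt = -3 I_Ca / (2 F r) - (Ca - Ca_res)/tau_Ca with I_Ca in mA/cm^2
    (inward negative, so inward current raises Ca).  The linear ODE is solved
    exactly over the step; the result is floored at a tiny positive value so
    the Nernst potential stays defined.
    """
    if dt <= 0 or Ca_i <= 0:
        raise ValueError("dt and Ca_i must be positive")
    r_cm = constants.r_shell * 1e-4
    source = -3.0 * (I_Ca * 1e-3) / (2.0 * constants.F * r_cm)  # M/ms
    ca_inf = constants.Ca_res + constants.tau_Ca * source
    ca = ca_inf + (Ca_i - ca_inf) * math.exp(-dt / constants.tau_Ca)
    return max(ca, _CA_FLOOR)


def kca_conductance(Ca_i: float, g_KCa_max: float,
                    constants: MembraneConstants = DEFAULT_CONSTANTS) -> float:
    """Ca-activated K conductance: Hill(2) of the shell concentration."""
    if Ca_i < 0:
        raise ValueError("Ca_i must be non-negative")
    x = (Ca_i / constants.Ca_diss) ** 2
    return g_KCa_max * x / (1.0 + x)


@dataclass
class CalciumState:
    """Shell concentration and the matching Nernst reversal potential."""
    Ca_i: float = 1e-7
    V_Ca: float = field(default=math.nan)

    def __post_init__(self):
        if math.isnan(self.V_Ca):
            self.V_Ca = nernst_vca(self.Ca_i)


# ---------------------------------------------------------------------------
# Regional channel distribution
# ---------------------------------------------------------------------------

REGION_ORDER = ("soma", "dendrite", "initial_segment", "narrow_segment",
                "socb", "distal_axon")

CHANNELS = ("g_Na", "g_Ca", "g_K", "g_KA", "g_KCa_max", "g_L", "g_h",
            "g_NaP", "g_T")


@dataclass(frozen=True)
class ChannelDensities:
    """Per-channel maximal conductance densities (S/cm^2) of one compartment."""
    g_Na: float
    g_Ca: float
    g_K: float
    g_KA: float
    g_KCa_max: float
    g_L: float
    g_h: float
    g_NaP: float
    g_T: float


@dataclass(frozen=True)
class DistributionTable:
    """Regional channel densities and free-triple multipliers.

    Fixed densities (S/cm^2) per region in the order soma, dendrite, initial
    segment, narrow segment, SOCB overlay, distal axon.  The free triple
    (g_NaP, g_T, g_h) enters through per-region multipliers: the SOCB carries
    5x the somatic NaP density, the distal axon 1/20 of it (ensuring
    orthodromic propagation), dendrites carry 5x the somatic T density, and
    g_h is uniform in every region.  Absent entries contribute zero current.
    The distal-axon K(Ca) ceiling of 0.07 S/cm^2 is reproduced as printed but
    exposed as an override because it is suspiciously large.
    """
    g_Na: tuple = (0.08, 0.025, 0.15, 0.2, 5 * 0.08, 0.07)
    g_Ca: tuple = (0.0015, 0.002, 0.0015, 0.0, 0.0, 0.0)
    g_K: tuple = (0.018, 0.012, 0.018, 0.018, 0.0, 0.018)
    g_KA: tuple = (0.054, 0.036, 0.054, 0.0, 0.0, 0.0)
    g_KCa_max: tuple = (6.5e-5, 1e-6, 6.5e-5, 6.5e-5, 0.0, 0.07)
    leak_multiplier: tuple = (15.0, 15.0, 15.0, 15.0, 15.0, 25.0)
    h_multiplier: tuple = (1.0, 1.0, 1.0, 1.0, 1.0, 1.0)
    nap_multiplier: tuple = (1.0, 1.0, 0.05, 0.05, 5.0, 0.05)
    t_multiplier: tuple = (1.0, 5.0, 1.0, 1.0, 1.0, 1.0)
    gL0: float = 8e-6

    def with_overrides(self, **kwargs) -> "DistributionTable":
        for key, value in kwargs.items():
            logger.info("channel distribution override: %s = %r", key, value)
        return replace(self, **kwargs)


DEFAULT_DISTRIBUTION = DistributionTable()


def compartment_conductances(table: DistributionTable, region: str,
                             in_socb: bool,
                             free_triple: tuple[float, float, float]
                             ) -> ChannelDensities:
    """Resolve the nine channel densities of one compartment.

    ``region`` is a region name (or :class:`~rgcsim.morphology.Region`);
    SOCB-flagged compartments take the SOCB overlay column regardless of
    whether they sit in the initial or the narrow segment.
    """
    g_nap, g_t, g_h = free_triple
    if min(free_triple) < 0:
        raise ValueError("free triple components must be non-negative")
    name = getattr(region, "value", region)
    if name == "socb":
        name = "initial_segment"
        in_socb = True
    if name not in REGION_ORDER:
        raise ValueError(f"unknown region {name!r}")
    idx = REGION_ORDER.index("socb") if in_socb else REGION_ORDER.index(name)
    return ChannelDensities(
        g_Na=table.g_Na[idx],
        g_Ca=table.g_Ca[idx],
        g_K=table.g_K[idx],
        g_KA=table.g_KA[idx],
        g_KCa_max=table.g_KCa_max[idx],
        g_L=table.leak_multiplier[idx] * table.gL0,
        g_h=table.h_multiplier[idx] * g_h,
        g_NaP=table.nap_multiplier[idx] * g_nap,
        g_T=table.t_multiplier[idx] * g_t,
    )


# ---------------------------------------------------------------------------
# Current balance
# ---------------------------------------------------------------------------

def total_ionic_current(V: float, gates: GatingState, ca: CalciumState,
                        densities: ChannelDensities,
                        constants: MembraneConstants = DEFAULT_CONSTANTS
                        ) -> tuple[float, dict]:
    """Total membrane current density (mA/cm^2, positive outward).

    Gating exponents: Na m^3 h, HVA Ca c^3, delayed rectifier n^4, A-type
    a^3 h_A, h-current l, T-type m_T^3 h_T, NaP p; K(Ca) and leak carry no
    voltage gate.  The HVA Ca term uses the dynamic Nernst reversal and is
    the only current feeding the calcium shell; the T current uses the fixed
    reversal V_T.  Returns (total, per-channel breakdown).
    """
    g = gates
    k = constants
    d = densities
    currents = {
        "L": d.g_L * (V - k.V_L),
        "Na": d.g_Na * g.m ** 3 * g.h * (V - k.V_Na),
        "Ca": d.g_Ca * g.c ** 3 * (V - ca.V_Ca),
        "K": d.g_K * g.n ** 4 * (V - k.V_K),
        "KA": d.g_KA * g.a ** 3 * g.h_A * (V - k.V_K),
        "KCa": kca_conductance(ca.Ca_i, d.g_KCa_max, k) * (V - k.V_K),
        "h": d.g_h * g.l * (V - k.V_h),
        "T": d.g_T * g.m_T ** 3 * g.h_T * (V - k.V_T),
        "NaP": d.g_NaP * g.p * (V - k.V_Na),
    }
    return sum(currents.values()), currents
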