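"""Cable solver: passive analytics, determinism, protocols, kernel fidelity."""

import math
from dataclasses import replace

import numpy as np
import pytest

from rgcsim.membrane import (DEFAULT_CONSTANTS, DistributionTable,
                             GatingState, MembraneConstants, advance_calcium,
                             advance_gates, nernst_vca)
from rgcsim.morphology import Compartment, Morphology, Region
from rgcsim.simulator import (SimulationConfig, StimStep, StimulusProtocol,
                              build_cell, make_protocol, simulate)


def passive_soma_cell(config, g_leak_mult=15.0):
    soma = Morphology([Compartment(1, None, Region.SOMA, 20.0, 20.0)])
    table = DistributionTable(
        g_Na=(0.0,) * 6, g_Ca=(0.0,) * 6, g_K=(0.0,) * 6, g_KA=(0.0,) * 6,
        g_KCa_max=(0.0,) * 6, leak_multiplier=(g_leak_mult,) * 6)
    return build_cell(soma, table, (0.0, 0.0, 0.0), config)


class TestPassiveAnalytics:
    def test_rc_steady_state_and_tau(self, soma_config):
        """Leak-only compartment matches the RC closed form within 1%."""
        cfg = replace(soma_config, settle_time=200.0, initial_V=-60.0)
        cell = passive_soma_cell(cfg)
        prot = StimulusProtocol(steps=(StimStep(50.0, 200.0, -0.2),),
                                duration=300.0)
        rec = simulate(cell, prot, cfg)
        g_l = 1.2e-4  # S/cm^2
        dv = -0.2 / (g_l * cell.area[0] * 1e6)  # nA / uS = mV
        v = rec["soma"]
        assert v[int(round(240.0 / cfg.dt))] == pytest.approx(-60.0 + dv,
                                                              rel=0.01)
        tau = 1.0 / g_l * 1e-3  # C_m / g_L = 8.33 ms
        elapsed = 8.325
        v_at_tau = v[int(round((50.0 + elapsed) / cfg.dt))]
        expected = -60.0 + dv * (1 - math.exp(-elapsed / tau))
        assert v_at_tau == pytest.approx(expected, rel=0.01)

    def test_crank_nicolson_matches_backward_euler_passive(self, soma_config):
        cfg = replace(soma_config, settle_time=100.0, initial_V=-60.0)
        prot = StimulusProtocol(steps=(StimStep(20.0, 100.0, -0.1),),
                                duration=150.0)
        recs = {}
        for solver in ("backward_euler", "crank_nicolson"):
            c = replace(cfg, solver=solver)
            recs[solver] = simulate(passive_soma_cell(c), prot, c)["soma"]
        assert np.max(np.abs(recs["backward_euler"]
                             - recs["crank_nicolson"])) < 0.05

    def test_charge_conservation(self, soma_config):
        """With every reversal at the initial potential and no stimulus the
        membrane stays put to machine precision."""
        k = MembraneConstants(V_K=-65.0, V_L=-65.0, V_h=-65.0, V_T=-65.0,
                              V_Na=-65.0)
        soma = Morphology([Compartment(1, None, Region.SOMA, 20.0, 20.0),
                           Compartment(2, 1, Region.DENDRITE, 100.0, 2.0)])
        table = DistributionTable(g_Ca=(0.0,) * 6, g_KCa_max=(0.0,) * 6)
        cfg = replace(soma_config, settle_time=0.0, initial_V=-65.0)
        cell = build_cell(soma, table, (1e-5, 3e-4, 1e-9), cfg, constants=k)
        rec = simulate(cell, make_protocol("spontaneous", duration=100.0),
                       cfg)
        assert np.max(np.abs(rec["soma"] + 65.0)) < 1e-9


class TestBuildCell:
    def test_axial_conductance_closed_form(self, soma_config):
        comps = [Compartment(1, None, Region.SOMA, 10.0, 1.0),
                 Compartment(2, 1, Region.DENDRITE, 10.0, 1.0)]
        cell = build_cell(Morphology(comps), config=replace(
            soma_config, max_segment_length=50.0))
        # two identical cylinders: g = pi d^2 / (4 R_i L), in uS
        d_cm, l_cm, ri = 1e-4, 10e-4, 110.0
        expected = math.pi * d_cm ** 2 / (4 * ri * l_cm) * 1e6
        assert cell.gax[1] == pytest.approx(expected, rel=1e-12)

    def test_zero_triple_matches_fixed_model(self, fixture_cell,
                                             soma_config):
        cell = build_cell(fixture_cell, triple=(0.0, 0.0, 0.0),
                          config=soma_config)
        assert np.all(cell.conductances["g_NaP"] == 0.0)
        assert np.all(cell.conductances["g_T"] == 0.0)
        assert np.all(cell.conductances["g_h"] == 0.0)
        assert cell.conductances["g_Na"].max() > 0.0

    def test_socb_density(self, fixture_cell, soma_config):
        cell = build_cell(fixture_cell, triple=(1e-5, 3e-4, 1e-9),
                          config=soma_config)
        i = cell.sites["socb"]
        assert cell.densities["g_Na"][i] == pytest.approx(0.4)

    def test_missing_socb_site_rejected(self, soma_only):
        cfg = SimulationConfig(record_sites=("soma", "socb"))
        cell = build_cell(soma_only, config=cfg)
        with pytest.raises(ValueError, match="socb"):
            simulate(cell, make_protocol("spontaneous", duration=10.0), cfg)


class TestProtocols:
    def test_hyp_step(self):
        p = make_protocol("hyp_step_200pA")
        (step,) = p.steps
        assert step.amplitude == -0.2
        assert step.duration == 500.0
        assert step.t_start >= 1000.0
        assert p.duration >= step.t_start + step.duration + 500.0

    def test_staircase(self):
        p = make_protocol("staircase_fig9")
        amps = [s.amplitude for s in p.steps]
        assert amps[:7] == pytest.approx(
            [-0.02 * (k + 1) for k in range(7)])
        assert amps[7] == -0.2
        assert [s.duration for s in p.steps[:7]] == [2000.0] * 7
        assert p.steps[7].duration == 500.0

    def test_cv_steps(self):
        p = make_protocol("cv_steps")
        amps = [s.amplitude for s in p.steps]
        assert min(amps) == -0.08
        assert np.allclose(np.diff(amps), -0.02)
        assert all(s.duration >= 10000.0 for s in p.steps)

    def test_unknown_protocol(self):
        with pytest.raises(ValueError):
            make_protocol("zap")

    def test_overlapping_steps_rejected(self):
        with pytest.raises(ValueError):
            StimulusProtocol(steps=(StimStep(0.0, 100.0, -0.1),
                                    StimStep(50.0, 100.0, -0.1)),
                             duration=200.0)


class TestDeterminismAndDynamics:
    def test_identical_replay(self, fixture_cell, soma_config):
        cell = build_cell(fixture_cell, triple=(2e-5, 3e-4, 1e-9),
                          config=soma_config)
        prot = make_protocol("spontaneous", duration=300.0)
        a = simulate(cell, prot, soma_config)["soma"]
        cell2 = build_cell(fixture_cell, triple=(2e-5, 3e-4, 1e-9),
                          config=soma_config)
        b = simulate(cell2, prot, soma_config)["soma"]
        assert np.array_equal(a, b)

    def test_socb_spike_leads_soma_then_distal(self, fixture_cell):
        """Action potentials initiate in the sodium-channel band and
        propagate orthodromically."""
        cfg = SimulationConfig(
            record_sites=("soma", "socb", "distal_axon"))
        cell = build_cell(fixture_cell, triple=(1e-5, 3e-4, 1e-9),
                          config=cfg)
        rec = simulate(cell, make_protocol("spontaneous", duration=800.0),
                       cfg)
        t = rec.time
        crossings = {}
        for site in ("soma", "socb", "distal_axon"):
            v = rec[site]
            up = np.flatnonzero((v[1:] >= 0.0) & (v[:-1] < 0.0))
            assert up.size > 0, f"no spike at {site}"
            crossings[site] = t[up + 1]
        # every somatic spike is preceded by a SOCB crossing within 1 ms
        for ts in crossings["soma"]:
            lead = crossings["socb"][crossings["socb"] <= ts]
            assert lead.size and ts - lead[-1] < 1.0
        assert crossings["socb"][0] < crossings["soma"][0]
        assert crossings["soma"][0] < crossings["distal_axon"][0]

    def test_dt_refinement_preserves_spike_times(self, fixture_cell):
        """Halving dt barely moves early spikes (and only slowly dephases
        later ones), starting from a quiescent initial state."""
        cfg = SimulationConfig(record_sites=("soma",), settle_time=0.0)
        times = {}
        for dt in (0.025, 0.0125):
            c = replace(cfg, dt=dt)
            cell = build_cell(fixture_cell, triple=(2e-5, 3e-4, 1e-9),
                              config=c)
            rec = simulate(cell, make_protocol("spontaneous",
                                               duration=1000.0), c)
            v = rec["soma"]
            up = np.flatnonzero((v[1:] >= 0.0) & (v[:-1] < 0.0))
            times[dt] = rec.time[up + 1]
        n = min(len(times[0.025]), len(times[0.0125]))
        assert n > 5
        diffs = np.abs(times[0.025][:n] - times[0.0125][:n])
        assert diffs[0] < 0.2       # first spike essentially unmoved
        assert diffs[:5].max() < 1.0
        # mean firing period agrees to better than 1%
        p1 = np.mean(np.diff(times[0.025][:n]))
        p2 = np.mean(np.diff(times[0.0125][:n]))
        assert p1 == pytest.approx(p2, rel=0.01)


class TestRecordingExport:
    def test_hdf5_round_trip(self, fixture_cell, soma_config, tmp_path):
        import h5py
        cfg = replace(soma_config, settle_time=50.0, record_currents=True)
        cell = build_cell(fixture_cell, triple=(1e-5, 3e-4, 1e-9),
                          config=cfg)
        rec = simulate(cell, make_protocol("spontaneous", duration=50.0),
                       cfg)
        path = tmp_path / "rec.h5"
        rec.to_hdf5(path)
        with h5py.File(path) as f:
            assert np.array_equal(f["voltage/soma"][...], rec["soma"])
            assert np.array_equal(f["time_ms"][...], rec.time)
            assert "T" in f["current"]


class TestKernelMatchesReference:
    def test_single_step_gates_and_calcium(self, soma_config):
        """One kernel step reproduces the scalar reference membrane update
        (exact exponential gates at frozen V, implicit (h_T,d), exact
        calcium) in every compartment."""
        from rgcsim.morphology import attach_standard_axon
        soma = Morphology([Compartment(1, None, Region.SOMA, 20.0, 20.0),
                           Compartment(2, 1, Region.DENDRITE, 80.0, 1.5)])
        morph = attach_standard_axon(soma)
        cfg = replace(soma_config, settle_time=0.0, initial_V=-58.0,
                      dt=0.1)
        cell = build_cell(morph, triple=(2e-5, 3e-4, 1e-7), config=cfg)
        rec = simulate(cell, make_protocol("spontaneous", duration=0.1), cfg)
        assert rec.time[-1] == pytest.approx(0.1)

        # reference: advance the scalar state one step at the frozen V
        ref = advance_gates(GatingState.steady_state(-58.0), -58.0, 0.1)
        # compare against a second simulation's internal state via a fresh
        # build (kernel state is not exposed; recompute one step by hand)
        from rgcsim import _kernel
        k = DEFAULT_CONSTANTS
        N = cell.n_compartments
        V = np.full(N, -58.0)
        g0 = GatingState.steady_state(-58.0)
        arrays = {name: np.full(N, getattr(g0, name))
                  for name in ("m", "h", "c", "n", "a", "h_A", "l", "m_T",
                               "h_T", "d", "p")}
        Ca = np.full(N, k.Ca_res)
        recV = np.zeros((1, 2))
        cur = np.zeros((9, 1))
        _kernel.integrate(
            V, arrays["m"], arrays["h"], arrays["c"], arrays["n"],
            arrays["a"], arrays["h_A"], arrays["l"], arrays["m_T"],
            arrays["h_T"], arrays["d"], arrays["p"], Ca,
            cell.parent, cell.gax, cell.cap,
            cell.conductances["g_Na"], cell.densities["g_Ca"],
            cell.conductances["g_K"], cell.conductances["g_KA"],
            cell.conductances["g_KCa_max"], cell.conductances["g_L"],
            cell.conductances["g_h"], cell.conductances["g_NaP"],
            cell.conductances["g_T"], cell.area, 0.1, 1, False,
            np.array([0], dtype=np.int64), np.zeros((1, 1)),
            np.array([0], dtype=np.int64), recV, False, cur,
            k.V_K, k.V_L, k.V_h, k.V_T, k.V_Na, k.Ca_e, k.Ca_diss,
            k.Ca_res, k.tau_Ca,
            3e-3 / (2 * k.F * k.r_shell * 1e-4),
            1e3 * k.R_gas * k.T_kelvin / (2 * k.F))
        soma_idx = 0
        for name in ("m", "h", "c", "n", "a", "h_A", "l", "m_T", "h_T",
                     "d", "p"):
            assert arrays[name][soma_idx] == pytest.approx(
                getattr(ref, name), rel=1e-12, abs=1e-14), name
        # calcium: exact update at the new c gate and frozen V
        from rgcsim.membrane import compartment_conductances, \
            DEFAULT_DISTRIBUTION
        dens = compartment_conductances(DEFAULT_DISTRIBUTION, "soma", False,
                                        (2e-5, 3e-4, 1e-7))
        i_ca = dens.g_Ca * ref.c ** 3 * (-58.0 - nernst_vca(k.Ca_res))
        assert Ca[soma_idx] == pytest.approx(
            advance_calcium(k.Ca_res, i_ca, 0.1), rel=1e-12)
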