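"""Constraint classification, grid search, valid sets, validation, reduction."""

from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rgcsim.analysis import SpikeTrain
from rgcsim.simulator import SimulationConfig
from rgcsim.tuning import (ConductanceGrid, ConstraintReport, GridSpec,
                           _regime, classify_point, evaluate_point,
                           extract_valid_sets, grid_search,
                           morphology_reduction_experiment, refine_spec,
                           validate_point)


def report(**kw):
    base = dict(c0_pass=True, rest_mV=-65.0, spont_Hz=0.0,
                spikes_during_hyp=0, rebound_rate_Hz=0.0)
    base.update(kw)
    return ConstraintReport(**base)


class TestClassify:
    def test_on_cell(self):
        assert classify_point(report()) == "ON"

    def test_off_transient(self):
        r = report(rest_mV=-55.0, spont_Hz=20.0, rebound_rate_Hz=60.0)
        assert classify_point(r) == "OFF_T"

    def test_off_sustained(self):
        r = report(rest_mV=-55.0, spont_Hz=44.0, rebound_rate_Hz=90.0)
        assert classify_point(r) == "OFF_S"

    def test_rate_between_bands_is_none(self):
        r = report(rest_mV=-55.0, spont_Hz=30.0, rebound_rate_Hz=90.0)
        assert classify_point(r) == "none"

    def test_c0_failure_forces_none(self):
        r = report(c0_pass=False)
        assert classify_point(r) == "none"

    def test_rebound_rule_is_relative(self):
        # 2x the spontaneous rate is required, not an absolute 60 Hz
        r = report(rest_mV=-55.0, spont_Hz=20.0, rebound_rate_Hz=30.0)
        assert classify_point(r) == "none"

    def test_spiking_during_step_disqualifies(self):
        r = report(rest_mV=-55.0, spont_Hz=20.0, spikes_during_hyp=3,
                   rebound_rate_Hz=60.0)
        assert classify_point(r) == "none"

    @settings(max_examples=200, deadline=None)
    @given(st.booleans(),
           st.floats(min_value=-90.0, max_value=-30.0),
           st.floats(min_value=0.0, max_value=80.0),
           st.integers(min_value=0, max_value=5),
           st.floats(min_value=0.0, max_value=150.0))
    def test_phenotypes_mutually_exclusive(self, c0, rest, spont, nstep,
                                           reb):
        r = ConstraintReport(c0, rest, spont, nstep, reb)
        assert int(r.on_pass) + int(r.offT_pass) + int(r.offS_pass) <= 1
        # pure function: classification is stable
        assert classify_point(r) == classify_point(r)


def flood_fill_oracle(labels, phenotype):
    """Brute-force 6-neighbor component extraction (independent of scipy)."""
    shape = labels.shape
    todo = {tuple(idx) for idx in np.argwhere(labels == phenotype)}
    comps = []
    while todo:
        seed = todo.pop()
        comp = {seed}
        frontier = [seed]
        while frontier:
            i, j, k = frontier.pop()
            for di, dj, dk in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                               (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                nb = (i + di, j + dj, k + dk)
                if nb in todo:
                    todo.remove(nb)
                    comp.add(nb)
                    frontier.append(nb)
        comps.append(frozenset(comp))
    return set(comps)


def grid_from_labels(labels):
    n = labels.shape
    spec = GridSpec(tuple(range(n[0])), tuple(range(n[1])),
                    tuple(range(n[2])))
    return ConductanceGrid(spec, labels, {})


class TestValidSets:
    def test_two_separated_blocks(self):
        labels = np.full((6, 4, 4), "none", dtype=object)
        labels[0:2, 0:2, 0:2] = "OFF_S"
        labels[4:6, 2:4, 2:4] = "OFF_S"
        sets = extract_valid_sets(grid_from_labels(labels))
        offs = [s for s in sets if s.phenotype == "OFF_S"]
        assert len(offs) == 2
        assert sorted(len(s.members) for s in offs) == [8, 8]
        assert not any(s.is_singleton for s in offs)

    def test_empty_labelling(self):
        labels = np.full((3, 3, 3), "none", dtype=object)
        assert extract_valid_sets(grid_from_labels(labels)) == []

    def test_full_plane_is_one_component(self):
        labels = np.full((5, 5, 5), "none", dtype=object)
        labels[:, :, 2] = "ON"
        sets = extract_valid_sets(grid_from_labels(labels))
        assert len(sets) == 1
        assert len(sets[0].members) == 25

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        labels = rng.choice(np.array(["none", "ON", "OFF_T", "OFF_S"],
                                     dtype=object),
                            size=(8, 8, 8), p=[0.55, 0.15, 0.15, 0.15])
        sets = extract_valid_sets(grid_from_labels(labels))
        for phen in ("ON", "OFF_T", "OFF_S"):
            got = {frozenset(s.members) for s in sets
                   if s.phenotype == phen}
            assert got == flood_fill_oracle(labels, phen)


class TestGridSearchLogic:
    def evaluate_stub(self, triple):
        gnap, gt, gh = triple
        if gnap > 1.0 and gt > 1.0:
            return report(rest_mV=-55.0, spont_Hz=20.0,
                          rebound_rate_Hz=60.0)
        return report(rest_mV=-75.0)

    def test_all_none_when_nothing_can_pass(self):
        spec = GridSpec((0.0, 0.5), (0.0, 0.5), (0.0, 0.5))
        grid = grid_search(None, spec, evaluate_fn=self.evaluate_stub)
        assert grid.label_counts() == {"none": 8}

    def test_labels_independent_of_evaluation_order(self):
        spec = GridSpec((0.0, 2.0), (0.0, 2.0), (0.0, 2.0))
        grid1 = grid_search(None, spec, evaluate_fn=self.evaluate_stub)

        class ReversedSpec(GridSpec):
            def points(self):
                yield from reversed(list(super().points()))

        spec2 = ReversedSpec((0.0, 2.0), (0.0, 2.0), (0.0, 2.0))
        grid2 = grid_search(None, spec2, evaluate_fn=self.evaluate_stub)
        assert np.array_equal(grid1.labels, grid2.labels)
        assert grid1.label_counts()["OFF_T"] == 2

    def test_cache_makes_search_resumable(self):
        calls = []

        def counting(triple):
            calls.append(triple)
            return self.evaluate_stub(triple)

        spec = GridSpec((0.0, 2.0), (0.0, 2.0), (0.0,))
        cache = {}
        grid_search(None, spec, evaluate_fn=counting, cache=cache)
        n_first = len(calls)
        grid_search(None, spec, evaluate_fn=counting, cache=cache)
        assert len(calls) == n_first  # second pass fully served by cache

    def test_refine_spec_covers_labelled_box(self):
        spec = GridSpec((0.0, 1.0, 2.0, 3.0), (0.0, 1.0, 2.0, 3.0),
                        (0.0, 1.0))
        grid = grid_search(None, spec, evaluate_fn=self.evaluate_stub)
        refined = refine_spec(grid, "OFF_T", n_linear=5)
        assert refined is not None
        assert min(refined.gnap_values) <= 2.0 <= max(refined.gnap_values)
        assert len(refined.gnap_values) == 5

    def test_logarithmic_default_axes(self):
        spec = GridSpec.logarithmic()
        assert spec.gnap_values[0] == pytest.approx(1e-15)
        assert spec.gnap_values[-1] == pytest.approx(1e-1)
        ratios = np.diff(np.log10(spec.gnap_values))
        assert np.allclose(ratios, 1.0)


class TestRegimes:
    def test_silent(self):
        assert _regime(SpikeTrain(np.array([])), 2000.0) == "silent"

    def test_regular(self):
        train = SpikeTrain(np.arange(0.0, 2000.0, 50.0))
        assert _regime(train, 2000.0) == "regular"

    def test_irregular(self):
        rng = np.random.default_rng(4)
        isis = rng.exponential(50.0, 40) + 2.0
        train = SpikeTrain(np.cumsum(isis))
        assert _regime(train, float(train.spike_times[-1])) == "irregular"

    def test_burst(self):
        # two tight clusters in a long window
        times = np.concatenate([np.arange(0, 50, 5.0),
                                np.arange(300, 350, 5.0)])
        assert _regime(SpikeTrain(times), 2000.0) == "burst"


@pytest.fixture(scope="module")
def fast_config():
    # coarse but converged enough for classification smoke tests
    return SimulationConfig(dt=0.05, record_sites=("soma",),
                            settle_time=300.0)


class TestSimulationBacked:
    def test_zero_triple_is_silent(self, fixture_cell, fast_config):
        rep = evaluate_point(fixture_cell, (0.0, 0.0, 0.0), fast_config,
                             spont_duration=1200.0)
        assert rep.spont_Hz == 0.0
        assert rep.rebound_rate_Hz == 0.0

    def test_nap_above_threshold_drives_firing(self, fixture_cell,
                                               fast_config):
        rep = evaluate_point(fixture_cell, (3e-5, 0.0, 0.0), fast_config,
                             spont_duration=1200.0)
        assert rep.spont_Hz > 0.0

    def test_validate_point_rejects_on_phenotype(self, fixture_cell,
                                                 fast_config):
        with pytest.raises(ValueError, match="OFF"):
            validate_point(fixture_cell, (1e-5, 1e-5, 1e-5), fast_config,
                           phenotype="ON")

    def test_off_staircase_ends_in_silence_or_burst(self, fixture_cell,
                                                    fast_config):
        """Increasing hyperpolarization drives the OFF cell out of regular
        firing, through irregular/burst regimes, toward silence."""
        rep = validate_point(fixture_cell, (3.33e-6, 5.36e-4, 1e-9),
                             fast_config, phenotype="OFF_S",
                             step_duration=1000.0, hold_duration=2000.0)
        assert rep.v2[0] in ("regular", "irregular")
        assert rep.v2[-1] in ("silent", "burst")
        assert len(rep.v2) >= 2
        assert len(rep.v3_table) == 4

    def test_label_insensitive_to_gh(self, fixture_cell, fast_config):
        """Classification does not depend on g_h across its explored range
        at fixed (g_NaP, g_T)."""
        labels = set()
        for gh in (1e-12, 1e-6):
            rep = evaluate_point(fixture_cell, (1e-5, 1e-5, gh),
                                 fast_config, spont_duration=1200.0)
            labels.add(classify_point(rep))
        assert len(labels) == 1

    def test_reduction_identity_row(self, fixture_cell, fast_config):
        df = morphology_reduction_experiment(
            fixture_cell, (3.33e-6, 5.36e-4, 1e-9), fast_config,
            factors=(1.0,), targets=("dendrite_diameter", "soma"),
            spont_duration=1200.0)
        a, b = df.iloc[0], df.iloc[1]
        for col in ("spont_rate_Hz", "rebound_rate_Hz", "spike_peak_mV",
                    "max_dvdt_mV_ms"):
            assert a[col] == b[col]
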