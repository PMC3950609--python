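"""Leak-conductance sweep: input resistance and hyperpolarized potential.

Reproduces the leak-adjustment argument on the reference cell: as the
uniform leak multiplier rises from the inherited 8e-6 S/cm^2 to the adopted
1.2e-4 S/cm^2 (15x), the input resistance falls steeply (here from ~770 to
~170 MOhm) and the potential reached during a -0.2 nA step rises toward
about -90 mV, the physiological hyperpolarization range.
"""

from pathlib import Path

import pandas as pd

from rgcsim.experiments import (hyperpolarizing_step_response,
                                input_resistance_vs_leak)
from rgcsim.membrane import DEFAULT_DISTRIBUTION
from rgcsim.simulator import SimulationConfig, build_cell, make_protocol, \
    simulate
from rgcsim.analysis import step_response_metrics
from rgcsim.synthetic import reference_fixture

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

TRIPLE = (1e-5, 3e-4, 1e-9)
MULTIPLIERS = (1.0, 5.0, 15.0, 25.0, 40.0)


def main():
    cell = reference_fixture()
    cfg = SimulationConfig(record_sites=("soma",))
    sweep = input_resistance_vs_leak(cell, TRIPLE, MULTIPLIERS, cfg)
    rows = []
    for (g_l, r_in), mult in zip(sweep, MULTIPLIERS):
        table = DEFAULT_DISTRIBUTION.with_overrides(
            leak_multiplier=(float(mult),) * 5 + (25.0,))
        cc = build_cell(cell, table, TRIPLE, cfg)
        rec = simulate(cc, make_protocol("hyp_step_200pA"), cfg)
        m = step_response_metrics(rec)
        rows.append({"g_L_S_cm2": g_l, "R_in_MOhm": r_in,
                     "V_rest_mV": m.V_rest, "V_hyp_mV": m.V_hyp})
        print(f"g_L = {g_l:.1e}: R_in = {r_in:7.1f} MOhm, "
              f"rest = {m.V_rest:6.1f} mV, V_hyp = {m.V_hyp:7.1f} mV")
    pd.DataFrame(rows).to_csv(OUT / "leak_sweep.csv", index=False)


if __name__ == "__main__":
    main()
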