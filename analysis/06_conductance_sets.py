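"""Desk-scale conductance-space search on the reference cell.

Evaluates a reduced lattice over the region where the phenotype boundaries
live (the full published search burned cluster-years; this driver keeps to a
few dozen points) and extracts connected valid sets per phenotype under
face adjacency.  On the reference cell the OFF bands sit at high g_T with
the spontaneous-rate windows selecting g_NaP, and labels are independent of
g_h across its range, as expected.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rgcsim.simulator import SimulationConfig
from rgcsim.synthetic import reference_fixture
from rgcsim.tuning import GridSpec, extract_valid_sets, grid_search

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)


def main():
    cell = reference_fixture()
    cfg = SimulationConfig(record_sites=("soma",))
    spec = GridSpec(
        gnap_values=(1e-15, 3e-6, 1e-5, 3e-5),
        gt_values=(1e-15, 1e-5, 1e-4, 4e-4),
        gh_values=(1e-12, 1e-6),
    )
    grid = grid_search(cell, spec, cfg)
    print("label counts:", grid.label_counts())

    rows = []
    for (i, j, k), triple in spec.points():
        rep = grid.reports.get((i, j, k))
        rows.append({
            "g_NaP": triple[0], "g_T": triple[1], "g_h": triple[2],
            "label": grid.labels[i, j, k],
            "rest_mV": getattr(rep, "rest_mV", np.nan),
            "spont_Hz": getattr(rep, "spont_Hz", np.nan),
            "rebound_Hz": getattr(rep, "rebound_rate_Hz", np.nan),
        })
    pd.DataFrame(rows).to_csv(OUT / "grid_labels.csv", index=False)

    for vs in extract_valid_sets(grid):
        print(f"{vs.phenotype}: {len(vs.members)} points, "
              f"bbox {vs.bounding_box}, singleton={vs.is_singleton}")


if __name__ == "__main__":
    main()
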