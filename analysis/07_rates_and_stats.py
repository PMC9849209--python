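#!/usr/bin/env python
"""Derived kinetic arithmetic and the figure-style statistical comparisons.

Computes the transfer rates implied by focus lifespans, the Ssb coverage
budget, the duplication-delay percent changes, and Mann-Whitney /
ANOVA-Dunnett comparisons on simulated lifespan samples. Writes
results/summary_stats.json.
"""

import json
from pathlib import Path

import numpy as np

from conjview import (
    compare_groups,
    conjugation_frequency,
    coverage_budget,
    percent_change,
    transfer_rate,
)
from conjview.population import draw_truncated_normal

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = {}
    out["transfer_rate_f_nt_s"] = transfer_rate(108_000, 2.9).rate_nt_s
    out["transfer_rate_chromosome_nt_s"] = transfer_rate(4_600_000, 100.0).rate_nt_s
    b = coverage_budget(1320, 8, 170, 650, 108_000)
    out["ssb_capacity_nt"] = b.capacity_nt
    out["ssb_pool_sufficient_for_plasmid"] = b.sufficient
    out["dup1_delay_increase_percent"] = percent_change(10.4, 16.4)
    out["dup2_delay_increase_percent"] = percent_change(10.1, 13.0)

    rng = np.random.default_rng(17)
    donors = [draw_truncated_normal(rng, 2.5, 1.1) for _ in range(197)]
    trans = [draw_truncated_normal(rng, 2.9, 1.1) for _ in range(294)]
    mw = compare_groups(donors, trans, test="mannwhitney")
    out["lifespan_mannwhitney_p"] = mw.p_value
    out["lifespan_mannwhitney_code"] = mw.code

    dup_wt = [draw_truncated_normal(rng, 10.4, 4.7) for _ in range(158)]
    dup_wt2 = [draw_truncated_normal(rng, 10.4, 4.7) for _ in range(150)]
    dup_dssb = [draw_truncated_normal(rng, 16.4, 9.5) for _ in range(120)]
    dn = compare_groups(
        None, None, test="anova_dunnett", groups=[dup_wt, dup_wt2, dup_dssb]
    )
    out["dup1_dunnett_p_vs_control"] = dn.details["dunnett_p"]

    t_cells, r_cells = 250, 20  # e.g. classified counts after 3 h of mating
    out["transconjugant_frequency_percent"] = 100 * conjugation_frequency(t_cells, r_cells)

    res = ROOT / "results"
    res.mkdir(exist_ok=True)
    with open(res / "summary_stats.json", "w") as fh:
        json.dump(out, fh, indent=2, default=float)
    for k, v in out.items():
        print(f"{k}: {v}")


if __name__ == "__main__":
    main()
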