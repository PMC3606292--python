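"""Convergence and goodness-of-fit diagnostics for the fitted scenarios.

Computes the Gelman-Rubin statistic for every hyper-parameter and a
posterior predictive check (Freeman-Tukey discrepancy on species x site
detection counts) for each prior scenario fitted by 02_fit_scenarios.py.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from msocc import dataio, diagnostics
from msocc.priors import SCENARIOS

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--outdir", type=Path, default=Path("results"))
args = parser.parse_args()

data = dataio.read_detection_data(args.outdir / "data.csv")
rows = []
for scenario in SCENARIOS:
    draws = dataio.load_draws(args.outdir / f"draws_{scenario}.npz")
    rng = np.random.default_rng([args.seed, SCENARIOS.index(scenario)])
    rep = diagnostics.diagnostic_report(data, draws, rng)
    rep["rhat"].to_csv(args.outdir / f"diagnostics_{scenario}.csv", index=False)
    rows.append({"scenario": scenario, "max_rhat": rep["max_rhat"],
                 "ppc_p_value": rep["ppc_p_value"]})
    print(f"{scenario}: max rhat {rep['max_rhat']:.3f}, "
          f"PPC Bayesian p-value {rep['ppc_p_value']:.3f}")

pd.DataFrame(rows).to_csv(args.outdir / "diagnostics_summary.csv", index=False)
print(f"wrote per-scenario rhat tables and {args.outdir / 'diagnostics_summary.csv'}")
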