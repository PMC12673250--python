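#!/usr/bin/env python
"""Climate-scenario population projection.

Runs the stochastic sex- and age-structured projection under six scenarios
(snow and summer temperature each at observed min / mean / max, the other
variable held at its mean), 2000 replicates of 30 years each, and reports
the per-variable change in mean population growth.  The survival schedule
is the shipped illustrative default, so the absolute growth rates are
illustrative; the snow-versus-temperature contrast is the result of
interest.  Writes scenario_summary.csv and sensitivity.json; replicate-
level draws go to scratch/ (large, regenerable).
"""

import json
from pathlib import Path

import pandas as pd

from oreamnos.coefficients import parturition_model
from oreamnos.projection import ProjectionSetup, climate_sensitivity

SEED = 20250925
ROOT = Path(__file__).resolve().parents[1]
OUT = ROOT / "results"
SCRATCH = ROOT / "scratch"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)
    setup = ProjectionSetup(parturition=parturition_model(), n_sims=2000)
    report = climate_sensitivity(setup, seed=SEED)

    summary = report.summary_frame()
    summary.to_csv(OUT / "scenario_summary.csv", index=False)
    (OUT / "sensitivity.json").write_text(
        json.dumps(
            {
                "delta_lambda_pct": report.delta_lambda_pct,
                "dominant_driver": report.dominant_driver,
                "n_sims": setup.n_sims,
                "horizon": setup.horizon,
                "seed": SEED,
            },
            indent=1,
        )
    )
    reps = pd.concat(
        [
            pd.DataFrame({"scenario": r.scenario.label, "lambda": r.lambdas})
            for r in report.results.values()
        ]
    )
    reps.to_csv(SCRATCH / "scenario_replicates.csv", index=False)

    print("scenario summary (2000 replicates each, 30-year horizon):")
    print(summary.round(4).to_string(index=False))
    print(
        f"\nchange in mean growth across observed range: "
        f"snow {report.delta_lambda_pct['snow']:.1f}% vs "
        f"temperature {report.delta_lambda_pct['temp']:.1f}% "
        f"-> dominant driver: {report.dominant_driver}"
    )


if __name__ == "__main__":
    main()
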