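#!/usr/bin/env python
"""Optional genome-scale pipeline (requires user-supplied downloads).

Runs the robust knockout screen on a genome-scale model (e.g. a BiGG
reconstruction in SBML or COBRA JSON) against an experimental essentiality
label TSV, and optionally the flux fit against a measurement TSV. None of
this is exercised by the test suite; it exists so the desk-scale pipeline can
be pointed at real reconstructions.

Example:
    python scripts/genome_scale.py --model iJO1366.xml --labels keio.tsv \
        --scenario-model model1 --out-dir results/
"""

from __future__ import annotations

import argparse
import json
from pathlib import Path

import numpy as np


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--model", required=True)
    parser.add_argument("--labels", default=None, help="TSV: gene_id, essential (0/1)")
    parser.add_argument("--measurements", default=None, help="TSV: reaction_id, flux[, sd]")
    parser.add_argument("--scenario-model", default="model1",
                        choices=["model1", "model2", "model3", "model4"])
    parser.add_argument("--rho", type=int, default=2)
    parser.add_argument("--sigma", type=float, default=0.2)
    parser.add_argument("--epsilon2", type=float, default=0.1)
    parser.add_argument("--theta", type=float, default=0.9)
    parser.add_argument("--out-dir", type=Path, default=Path("genome_scale_results"))
    args = parser.parse_args()

    import rampfba as rf
    from rampfba import fixtures, scenarios

    args.out_dir.mkdir(parents=True, exist_ok=True)
    net = rf.load_model(args.model)
    builders = {
        "model1": lambda: scenarios.build_model1(net),
        "model2": lambda: scenarios.build_model2(net, rho=args.rho),
        "model3": lambda: scenarios.build_model3(net, sigma=args.sigma),
        "model4": lambda: scenarios.build_model4(net, epsilon2=args.epsilon2),
    }
    scen = builders[args.scenario_model]()

    fba_screen = rf.screen_knockouts(net, "fba")
    ramp_screen = rf.screen_knockouts(net, "ramp", scenarios=scen)
    fba_screen.to_frame().to_csv(args.out_dir / "screen_fba.tsv", sep="\t", index=False)
    ramp_screen.to_frame().to_csv(args.out_dir / "screen_ramp.tsv", sep="\t", index=False)

    summary = {
        "fba_essential": len(fba_screen.essential_set),
        "ramp_essential": len(ramp_screen.essential_set),
        "sets_equal": fba_screen.essential_set == ramp_screen.essential_set,
    }
    if args.labels:
        labels = fixtures.read_labels(args.labels)
        for name, screen in (("fba", fba_screen), ("ramp", ramp_screen)):
            cm = rf.compare_to_experiment(screen, labels)
            summary[f"{name}_confusion"] = {"tp": cm.tp, "fp": cm.fp, "fn": cm.fn, "tn": cm.tn}
            summary[f"{name}_predictive_power_pct"] = 100 * rf.predictive_power(cm)
    if args.measurements:
        meas = rf.read_flux_measurements(args.measurements)
        summary["flux_fit"] = rf.fit_summary(net, scen, meas, theta=args.theta)

    (args.out_dir / "summary.json").write_text(json.dumps(summary, indent=1, default=str))
    print(json.dumps(summary, indent=1, default=str))


if __name__ == "__main__":
    main()
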