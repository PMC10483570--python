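#!/usr/bin/env python
"""The two-class spike-classification benchmark over all nine models.

Default configuration: 1,000 samples per class, benchmark-regime parameters,
unit-weight mapping (constant current = feature, 100 steps, class 1 iff at
least one spike), accuracies averaged over 10 dataset seeds.  Writes
results/metrics.csv, results/loss_matrix.csv and results/report.json and
prints the ranking.
"""

import json
from pathlib import Path

from spikebench import run_benchmark

OUT = Path(__file__).resolve().parent.parent / "results"


def main():
    OUT.mkdir(exist_ok=True)
    report, loss = run_benchmark(regime="table3", n_per_class=1000,
                                 seeds=range(10), mapping="unit",
                                 window_steps=100)
    report.to_frame().to_csv(OUT / "metrics.csv", index=False)
    loss.to_csv(OUT / "loss_matrix.csv")
    (OUT / "report.json").write_text(json.dumps(
        {"accuracy": report.accuracy, "error": report.error,
         "spike_totals": report.spike_totals, "seeds": list(report.seeds),
         "config": report.config_snapshot}, indent=2))
    print("mean accuracy over 10 seeds (2,000 samples each):")
    for name in report.ranking():
        print(f"  {name:12s} {report.accuracy[name]:6.2f}%   "
              f"error {report.error[name]:6.2f}%")
    print()
    print("reading: the LIF-family integrators (IFSFA, ThetaNeuron, LIF) have")
    print("effective input thresholds near 1, closest to the optimal 1.5, and")
    print("lead; AdEx's tau*I drive makes it fire on much weaker inputs; the")
    print("always-firing (Izhikevich, HH at its sub-rest detection threshold)")
    print("and never-firing (NLIF) units sit at chance on balanced classes;")
    print("SRM, whose membrane integrates the NEGATIVE of the input, spikes")
    print("only on strongly negative class-0 features and scores below chance.")
    print(f"wrote {OUT / 'metrics.csv'}, loss_matrix.csv, report.json")


if __name__ == "__main__":
    main()
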