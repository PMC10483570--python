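#!/usr/bin/env python
"""Arithmetic cost of each model's update rule.

Accumulates the itemized per-step operation counts over a 1,000-step run for
every model in the benchmark regime and writes results/operation_counts.csv.
The tallies are a hardware-independent proxy for relative update cost; their
ordering depends entirely on the counting convention, so they are reported,
not ranked against any external total.
"""

from pathlib import Path

import pandas as pd

from spikebench import MODEL_NAMES, PER_STEP_COSTS, count_run, make_model

OUT = Path(__file__).resolve().parent.parent / "results"
STEPS = 1000


def main():
    OUT.mkdir(exist_ok=True)
    rows = []
    for name in MODEL_NAMES:
        model = make_model(name, params_source="table3")
        count = count_run(model, STEPS)
        per_step = PER_STEP_COSTS[name]
        rows.append({"model": name, "per_step_total": per_step.total,
                     "additions": count.additions,
                     "subtractions": count.subtractions,
                     "multiplications": count.multiplications,
                     "divisions": count.divisions,
                     "comparisons": count.comparisons,
                     "total": count.total})
        print(f"{name:12s} {per_step.total:3d} ops/step  "
              f"{count.total:6d} ops over {STEPS} steps")
    frame = pd.DataFrame(rows).sort_values("per_step_total", ascending=False)
    frame.to_csv(OUT / "operation_counts.csv", index=False)
    print(f"wrote {OUT / 'operation_counts.csv'}")


if __name__ == "__main__":
    main()
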