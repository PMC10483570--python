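#!/usr/bin/env python
"""Pulse-response membrane traces for all nine models (trace regime).

Each model is driven by an input current pulse spanning 10%-60% of a
1,000-step run at its regime time step; per-model pulse amplitudes are chosen
so every model fires visibly.  Writes one trace CSV per model plus a combined
figure under results/traces/.
"""

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from spikebench import (MODEL_NAMES, SimulationGrid, StimulusProtocol,
                        make_model, run_trace)

OUT = Path(__file__).resolve().parent.parent / "results" / "traces"
N_STEPS = 1000

# pulse amplitude per model (regime units); each clears its threshold
AMPLITUDES = {
    "LIF": 2.0, "NLIF": 2.0, "AdEx": 2.0, "HH": 10.0, "QIF": 30.0,
    "ThetaNeuron": 35.0, "Izhikevich": 20.0, "SRM": 40.0, "IFSFA": 500.0,
}


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    fig, axes = plt.subplots(3, 3, figsize=(13, 8), sharex=False)
    for ax, name in zip(axes.ravel(), MODEL_NAMES):
        model = make_model(name, params_source="table2")
        grid = SimulationGrid(dt=model.dt, n_steps=N_STEPS)
        proto = StimulusProtocol.pulse_fractions(AMPLITUDES[name], grid)
        record = run_trace(model, proto)
        record.write_csv(OUT / f"trace_{name}.csv")
        frame = record.to_frame()
        ax.plot(frame["time"], frame["V"], lw=0.7)
        spikes = frame[frame["spiked"] == 1]
        ax.plot(spikes["time"], spikes["V"], "rx", ms=4)
        ax.axvspan(proto.onset_step * model.dt, proto.offset_step * model.dt,
                   color="0.92", zorder=0)
        ax.set_title(f"{name} ({len(record.spike_steps)} spikes)", fontsize=9)
        print(f"{name:12s} dt={model.dt:<4} pulse={AMPLITUDES[name]:<6} "
              f"spikes={len(record.spike_steps)}")
    fig.suptitle("Membrane response to an input current pulse (trace regime)")
    fig.supxlabel("time (ms)")
    fig.supylabel("membrane potential")
    fig.tight_layout()
    fig.savefig(OUT / "traces.png", dpi=120)
    print(f"wrote per-model CSVs and {OUT / 'traces.png'}")


if __name__ == "__main__":
    main()
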