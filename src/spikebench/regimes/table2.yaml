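# Trace regime (time in ms, potentials in mV), used for the pulse-response
# membrane-trace experiment.  Keys mirror the parameter-table row labels;
# cells marked "X" are omitted.
LIF:
  Time step: 0.1
  Time constant: 10.0
  Membrane resistance: 1.0
  Threshold value: 1.0
  Reset membrane potential: 0.0
  Initial potential: 0.5
  Leak conductance: 0.1
NLIF:
  Time step: 0.1
  Time constant: 10.0
  Membrane resistance: 1.0
  Threshold value: 1.0
  Reset membrane potential: 0.0
  Initial potential: 0.5
  Leak conductance: 0.1
AdEx:
  Time step: 0.1
  Time constant: 10.0
  Membrane resistance: 1.0
  Threshold value: 1.0
  Reset membrane potential: 0.0
  Initial potential: 0.5
  Leak conductance: 0.1
  Adaptation time constant: 30.0
  Adaptation conductance: 0.001
  Adaptation increment: 0.01
HH:
  Time step: 1.5
  Threshold value: -66.0
  Reset membrane potential: 0.0
  Initial potential: -65.0
  Leak conductance: 0.3
  Membrane capacitance: 1.0
  Sodium conductance: 120.0
  Potassium conductance: 36.0
  Sodium reversal: 50.0
  Potassium reversal: -82.0
  Leak reversal: -84.4
Izhikevich:
  Time step: 0.1
  Time constant: 20.0
  Membrane resistance: 10.0
  Threshold value: -60.0
  Reset membrane potential: -90.0
  Initial potential: -90.0
  Refractory period: 10.0
  Recovery variable: 0.02
  Sensitivity (RV/MP): 0.2
  After-spike reset: -95.0
  After-spike reset (RV/AV): 6.0
SRM:
  Time step: 0.5
  Time constant: 10.0
  Membrane resistance: 5.0
  Threshold value: -60.0
  Reset membrane potential: -90.0
  Initial potential: -90.0
  Refractory period: 1.0
  Leak conductance: 0.01
  Membrane capacitance: 5.0
  Input conductance: 1.5
  Synaptic time constant: 5.0
  Synaptic reversal potential: 0.01
  Synaptic weight: 0.09
IFSFA:
  Time step: 0.1
  Membrane resistance: 1.0
  Threshold value: 35.0
  Reset membrane potential: -60.0
  Initial potential: -90.0
  Adaptation time constant: 200.0
  Adaptation conductance: 0.01
  Adaptation increment: -0.1
  Membrane capacitance: 100.0
  Sensitivity (RV/MP): 0.7
  After-spike reset: -50.0
  After-spike reset (RV/AV): 100.0
QIF:
  Time step: 0.1
  Threshold value: 1.0
  Reset membrane potential: 0.0
  Initial potential: 0.5
  Refractory period: 2.0
  Membrane capacitance: 0.1
ThetaNeuron:
  Time step: 0.1
  Time constant: 20.0
  Threshold value: -50.0
  Reset membrane potential: -70.0
  Initial potential: -70.0
  Input conductance: 1.5
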