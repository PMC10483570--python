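# Benchmark regime (dimensionless units; thresholds near 1).
# Keys mirror the parameter-table row labels; cells marked "X" are omitted.
LIF:
  Time step: 0.1
  Tau: 4.0
  Reset potential: 0.0
  Threshold value: 1.0
  Initial potential: 0.1
  No. of neurons: 1000
NLIF:
  Time step: 0.1
  Tau: 4.0
  Reset potential: 0.0
  Threshold value: 1.0
  Initial potential: 0.5
  Alpha: 0.5
  Beta: 0.5
  No. of neurons: 1000
AdEx:
  Time step: 0.1
  Tau: 4.0
  Reset potential: 0.1
  Initial potential: 0.1
  Rheobase potential: 0.5
  Threshold potential: 1.0
  Slope factor: 1.0
  No. of neurons: 1000
HH:
  Time step: 0.1
  Tau: 4.0
  Reset potential: -65.0
  Initial potential: -65.0
  Activation variable for potassium: 0.3177
  Activation variable for sodium: 0.0529
  Inactivation variable for sodium: 0.5961
  Maximum conductances gNa: 120.0
  Maximum conductances gK: 36.0
  Maximum conductances gL: 0.3
  Sodium rev. pot.: 50.0
  Potassium rev. pot.: -77.0
  Leak conductance rev. pot.: -54.4
  No. of neurons: 1000
IFSFA:
  Time step: 0.1
  Tau: 4.0
  Reset potential: 0.0
  Threshold value: 1.0
  Initial potential: -0.1
  Slope factor: 2.0
  Adaptation time constant: 100.0
  Adaptation conductance: 0.1
  Adaptation control: 0.01
  No. of neurons: 1000
QIF:
  Time step: 0.1
  Tau: 4.0
  Reset potential: 0.0
  Threshold value: 1.0
  Initial potential: -0.1
  Beta: 0.5
  No. of neurons: 1000
ThetaNeuron:
  Time step: 0.1
  Tau: 4.0
  Reset potential: 0.0
  Threshold value: 1.0
  Initial potential: 0.0
  No. of neurons: 1000
SRM:
  Time step: 0.1
  Tau: 0.3
  Reset potential: 0.0
  Threshold value: 1.0
  Initial potential: 0.0
  Synaptic time constants: 10.0
  No. of neurons: 1000
Izhikevich:
  Time step: 0.1
  Threshold value: 0.8
  Initial potential: 0.01
  Recovery variable: 0.2
  Time scale RV: 0.02
  Sensitivity RV: 0.2
  After-spike reset MP: 0.1
  After-spike reset RV: 0.06
  No. of neurons: 1000
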