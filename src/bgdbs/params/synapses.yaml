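# Projection conductances (mS/cm^2), reversal potentials (mV) and fan-in
# (afferents per post-synaptic neuron) of the six inter-population
# projections.  Gating of each synapse follows first-order kinetics
#   s' = alpha * T(V_pre) * (1 - s) - beta * s,
#   T(V) = 1 / (1 + exp(-(V - theta) / k)),
# i.e. s rises toward alpha/(alpha+beta) while the presynaptic membrane
# is above threshold (during a spike) and decays exponentially otherwise.
# alpha/beta values are this package's choice within the Rubin-Terman
# family: fast AMPA-like excitation, slower GABA-A-like inhibition.

projections:
  GPi->TH:  {pre: GPi, post: TH, g_syn: 0.17, E_syn: -85.0, sign: inhibitory, fan_in: 1}
  GPe->STN: {pre: GPe, post: STN, g_syn: 0.5, E_syn: -85.0, sign: inhibitory, fan_in: 2}
  STN->GPe: {pre: STN, post: GPe, g_syn: 0.15, E_syn: 0.0, sign: excitatory, fan_in: 2}
  GPe->GPe: {pre: GPe, post: GPe, g_syn: 0.5, E_syn: -85.0, sign: inhibitory, fan_in: 2}
  STN->GPi: {pre: STN, post: GPi, g_syn: 0.15, E_syn: 0.0, sign: excitatory, fan_in: 2}
  GPe->GPi: {pre: GPe, post: GPi, g_syn: 0.5, E_syn: -85.0, sign: inhibitory, fan_in: 2}

kinetics:
  excitatory: {alpha: 5.0, beta: 1.0, theta: -20.0, k: 2.0}
  inhibitory: {alpha: 2.0, beta: 0.08, theta: -20.0, k: 2.0}
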