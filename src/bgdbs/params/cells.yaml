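# Membrane and channel parameters for the four modeled populations.
#
# Conductances (mS/cm^2), reversal potentials (mV) and bias currents
# (uA/cm^2) are the network model's reference values; gating steady-state curves
# and time constants are adopted from the Rubin-Terman / So-family
# single-compartment cell models that the network derives from.
#
# Gate forms:
#   inf  boltzmann:  x_inf(V) = 1 / (1 + exp(-(V - theta) / k))
#                    (k < 0 gives an inactivation curve)
#   tau  sigmoid:    tau(V) = tau0 + tau1 / (1 + exp(-(V - theta) / k))
#   tau  inv_rates:  tau(V) = 1 / (a + b),
#                    a = a0 * exp(-(V - a_theta) / a_k)
#                    b = b0 / (1 + exp(-(V - b_theta) / b_k))
#   tau  exp_decay:  tau(V) = tau0 + tau1 * exp(-(V - theta) / k)
#   tau  const:      tau(V) = tau0
# Dynamic gates integrate  x' = phi * (x_inf(V) - x) / tau(V).
# Derived gates are algebraic functions of another gate:
#   th_k:   n = 0.75 * (1 - h)          (K activation tied to Na inactivation)
#   stn_b:  b = 1/(1+exp((r-0.4)/-0.1)) - 1/(1+exp(4))

TH:
  C_m: 1.0
  I_bias: {healthy: 0.0, pd: 0.0}
  channels:
    L:  {g_max: 0.05, E_rev: -70.0, m_exp: 0, h_exp: 0}
    Na: {g_max: 3.0, E_rev: 50.0, m_exp: 3, h_exp: 1, activation: m, inactivation: h}
    K:  {g_max: 5.0, E_rev: -75.0, m_exp: 4, h_exp: 0, activation: k_from_h}
    T:  {g_max: 5.0, E_rev: 0.0, m_exp: 2, h_exp: 1, activation: p, inactivation: r}
  gates:
    m: {mode: instantaneous, inf: {form: boltzmann, theta: -37.0, k: 7.0}}
    h:
      mode: dynamic
      inf: {form: boltzmann, theta: -41.0, k: -4.0}
      tau: {form: inv_rates, a0: 0.128, a_theta: -46.0, a_k: 18.0,
            b0: 4.0, b_theta: -23.0, b_k: 5.0}
      phi: 1.0
    p: {mode: instantaneous, inf: {form: boltzmann, theta: -60.0, k: 6.2}}
    r:
      mode: dynamic
      inf: {form: boltzmann, theta: -84.0, k: -4.0}
      tau: {form: exp_decay, tau0: 28.0, tau1: 1.0, theta: -25.0, k: 10.5}
      phi: 1.0
  derived_gates:
    k_from_h: {form: th_k, source: h}

STN:
  C_m: 1.0
  I_bias: {healthy: 29.0, pd: 20.0}
  channels:
    L:  {g_max: 2.25, E_rev: -60.0, m_exp: 0, h_exp: 0}
    Na: {g_max: 37.0, E_rev: 55.0, m_exp: 3, h_exp: 1, activation: m, inactivation: h}
    K:  {g_max: 45.0, E_rev: -80.0, m_exp: 4, h_exp: 0, activation: n}
    Ca: {g_max: 2.0, E_rev: 140.0, m_exp: 2, h_exp: 0, activation: s}
    T:  {g_max: 0.5, E_rev: 0.0, m_exp: 3, h_exp: 2, activation: a, inactivation: b_from_r}
  gates:
    m: {mode: instantaneous, inf: {form: boltzmann, theta: -30.0, k: 15.0}}
    h:
      mode: dynamic
      inf: {form: boltzmann, theta: -39.0, k: -3.1}
      tau: {form: sigmoid, tau0: 1.0, tau1: 500.0, theta: -57.0, k: -3.0}
      phi: 0.75
    n:
      mode: dynamic
      inf: {form: boltzmann, theta: -32.0, k: 8.0}
      tau: {form: sigmoid, tau0: 1.0, tau1: 100.0, theta: -80.0, k: -26.0}
      phi: 0.75
    s: {mode: instantaneous, inf: {form: boltzmann, theta: -39.0, k: 8.0}}
    a: {mode: instantaneous, inf: {form: boltzmann, theta: -63.0, k: 7.8}}
    r:
      mode: dynamic
      inf: {form: boltzmann, theta: -67.0, k: -2.0}
      tau: {form: sigmoid, tau0: 7.1, tau1: 17.5, theta: -68.0, k: -2.2}
      phi: 0.2
  derived_gates:
    b_from_r: {form: stn_b, source: r}

GPe:
  C_m: 1.0
  I_bias: {healthy: 20.0, pd: 8.0}
  channels:
    L:  {g_max: 0.1, E_rev: -65.0, m_exp: 0, h_exp: 0}
    Na: {g_max: 120.0, E_rev: 55.0, m_exp: 3, h_exp: 1, activation: m, inactivation: h}
    K:  {g_max: 30.0, E_rev: -80.0, m_exp: 4, h_exp: 0, activation: n}
    Ca: {g_max: 0.15, E_rev: 120.0, m_exp: 2, h_exp: 0, activation: s}
    T:  {g_max: 0.5, E_rev: 0.0, m_exp: 3, h_exp: 1, activation: a, inactivation: r}
  gates:
    m: {mode: instantaneous, inf: {form: boltzmann, theta: -37.0, k: 10.0}}
    h:
      mode: dynamic
      inf: {form: boltzmann, theta: -58.0, k: -12.0}
      tau: {form: sigmoid, tau0: 0.05, tau1: 0.27, theta: -40.0, k: -12.0}
      phi: 0.05
    n:
      mode: dynamic
      inf: {form: boltzmann, theta: -50.0, k: 14.0}
      tau: {form: sigmoid, tau0: 0.05, tau1: 0.27, theta: -40.0, k: -12.0}
      phi: 0.05
    a: {mode: instantaneous, inf: {form: boltzmann, theta: -57.0, k: 2.0}}
    s: {mode: instantaneous, inf: {form: boltzmann, theta: -35.0, k: 2.0}}
    r:
      mode: dynamic
      inf: {form: boltzmann, theta: -70.0, k: -2.0}
      tau: {form: const, tau0: 30.0}
      phi: 1.0

GPi:
  C_m: 1.0
  I_bias: {healthy: 22.0, pd: 12.0}
  channels:
    L:  {g_max: 0.1, E_rev: -65.0, m_exp: 0, h_exp: 0}
    Na: {g_max: 120.0, E_rev: 55.0, m_exp: 3, h_exp: 1, activation: m, inactivation: h}
    K:  {g_max: 30.0, E_rev: -80.0, m_exp: 4, h_exp: 0, activation: n}
    Ca: {g_max: 0.15, E_rev: 120.0, m_exp: 2, h_exp: 0, activation: s}
    T:  {g_max: 0.5, E_rev: 0.0, m_exp: 3, h_exp: 1, activation: a, inactivation: r}
  gates:
    m: {mode: instantaneous, inf: {form: boltzmann, theta: -37.0, k: 10.0}}
    h:
      mode: dynamic
      inf: {form: boltzmann, theta: -58.0, k: -12.0}
      tau: {form: sigmoid, tau0: 0.05, tau1: 0.27, theta: -40.0, k: -12.0}
      phi: 0.05
    n:
      mode: dynamic
      inf: {form: boltzmann, theta: -50.0, k: 14.0}
      tau: {form: sigmoid, tau0: 0.05, tau1: 0.27, theta: -40.0, k: -12.0}
      phi: 0.05
    a: {mode: instantaneous, inf: {form: boltzmann, theta: -57.0, k: 2.0}}
    s: {mode: instantaneous, inf: {form: boltzmann, theta: -35.0, k: 2.0}}
    r:
      mode: dynamic
      inf: {form: boltzmann, theta: -70.0, k: -2.0}
      tau: {form: const, tau0: 30.0}
      phi: 1.0
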