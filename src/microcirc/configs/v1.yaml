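version: 1
populations: [E, P, S, V]
fi:
  E: {v_th: -50.0, v_r: -60.0, v: 1.0, tau_m_s: 0.028, g_l_nS: 6.25, v_l: -70.0}
  P: {v_th: -50.0, v_r: -60.0, v: 1.0, tau_m_s: 0.008, g_l_nS: 10.0, v_l: -70.0}
  S: {v_th: -50.0, v_r: -60.0, v: 1.0, tau_m_s: 0.016, g_l_nS: 5.0, v_l: -70.0}
  V: {v_th: -50.0, v_r: -60.0, v: 1.0, tau_m_s: 0.016, g_l_nS: 5.0, v_l: -70.0}
W_pAs:
  - [3.30, -3.48, -2.98, 0.0]
  - [1.73, -4.25, -1.07, 0.0]
  - [3.50, 0.0, 0.0, -4.51]
  - [0.53, 0.0, -0.13, 0.0]
tau_r_s: 0.002
baseline_rates_Hz: [1.0, 10.0, 3.0, 2.0]
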