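{
 "w": {
  "t": 2.3e-09,
  "e": 2.3e-09,
  "r": 4.2e-07,
  "q": 2.2e-06
 },
 "theta": {
  "t": 1e-05,
  "e": 1e-05,
  "r": 0.0003,
  "q": 1e-05
 },
 "d": {
  "t": 0.1,
  "e": 0.1,
  "r": 0.1,
  "q": 0.1
 },
 "n": {
  "t": 300,
  "e": 300,
  "r": 7459,
  "q": 300
 },
 "K_q": 0.0022,
 "h": 4.0,
 "k_b": 22000000.0,
 "k_u": 1.0,
 "gamma_max": 1260.0,
 "K_gamma": 3e-05,
 "v_t": 726.0,
 "v_m": 5800.0,
 "K_m": 0.0003,
 "n_s": 5.0,
 "s": 1.0,
 "O_c": 2e-09,
 "tau_CD": 60.0,
 "k_cm": 0.003,
 "X_cm": 0.0
}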