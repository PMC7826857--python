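{
  "parameters": {
    "n": 100.0,
    "s_ext": 10000.0,
    "w": {
      "R": 930.0,
      "ET": 4.14,
      "EM": 4.14,
      "Q": 948.9,
      "H": 4.14
    },
    "theta": {
      "R": 426.87,
      "ET": 4.38,
      "EM": 4.38,
      "Q": 4.38,
      "H": 4.38
    },
    "b": {
      "R": 0.0095,
      "ET": 0.0095,
      "EM": 0.0095,
      "Q": 0.0095,
      "H": 0.0095
    },
    "length": {
      "R": 750,
      "ET": 30,
      "EM": 30,
      "Q": 30,
      "H": 30
    },
    "K_q": 152219.0,
    "h_q": 4.0,
    "d_m": 0.1,
    "gamma_max": 126.0,
    "K_gamma": 7.0,
    "v_t": 726.0,
    "K_t": 1000.0,
    "v_m": 5800.0,
    "K_m": 1000.0,
    "M": 10000000.0,
    "mass_per_nt": 330.0,
    "mass_per_aa": 110.0
  },
  "construct": {
    "promH": 1.0,
    "RBSH": 1.0,
    "codon_profile": [
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0,
      1.0
    ]
  },
  "simulation": {
    "seed": 0,
    "t_initial": 60.0,
    "max_time": 1920.0,
    "sample_dt": 0.1,
    "ss_window_frac": 0.1,
    "ss_tol": 0.01,
    "init_on_occupied": true
  },
  "analysis": {
    "time_points_h": [
      0.0,
      4.0,
      8.0,
      24.0
    ],
    "turbidostat_N": 1000000000.0,
    "prom_values": [
      0.3333333333333333,
      1.0,
      3.0
    ],
    "rbs_values": [
      0.3333333333333333,
      1.0,
      3.0
    ],
    "n_replicates": 3,
    "t_zero_interval_h": 1e-12
  }
}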