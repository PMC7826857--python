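{
  "parameters": {
    "n": 100.0,
    "s_ext": 10000.0,
    "w": {
      "R": 1.2,
      "ET": 1.25,
      "EM": 1.25,
      "Q": 15.0,
      "H": 1.0
    },
    "theta": {
      "R": 427.0,
      "ET": 427.0,
      "EM": 427.0,
      "Q": 427.0,
      "H": 427.0
    },
    "b": {
      "R": 0.0095,
      "ET": 0.0095,
      "EM": 0.0095,
      "Q": 0.0095,
      "H": 0.0095
    },
    "length": {
      "R": 75,
      "ET": 30,
      "EM": 30,
      "Q": 30,
      "H": 30
    },
    "K_q": 4600.0,
    "h_q": 4.0,
    "d_m": 0.1,
    "gamma_max": 126.0,
    "K_gamma": 300.0,
    "v_t": 0.38,
    "K_t": 1000.0,
    "v_m": 0.3,
    "K_m": 100.0,
    "M": 250000.0,
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
    "t_initial": 720.0,
    "max_time": 1440.0,
    "sample_dt": 0.2,
    "ss_window_frac": 0.3333333333333333,
    "ss_tol": 0.75,
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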