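{
  "version": 1,
  "comment": "Steady-state/time-constant gate parameterization for the 11-current CA1 ensemble. Voltage gates: x_inf = 1/(1+exp((vh-V)/k)), tau = tau_min + tau_amp/(exp((V-v_tau)/k1)+exp(-(V-v_tau)/k2)). Calcium gates: x_inf = 1/(1+(kd/Ca)^hill). Units mV, ms, mM. Temperature (Q10) effects are folded into the stored tau values.",
  "reversals": {
    "na": 50.0,
    "k": -90.0,
    "ca": 120.0,
    "nonspecific": -30.0
  },
  "calcium": {
    "rest_mM": 5e-05,
    "tau_ms": 100.0,
    "shell_depth_um": 0.1
  },
  "channels": {
    "Na": {
      "ion": "na",
      "gates": [
        {
          "name": "m",
          "exponent": 3,
          "kind": "volt",
          "vh": -40.0,
          "k": 5.0,
          "tau_min": 0.05,
          "tau_amp": 0.5,
          "v_tau": -40.0,
          "k1": 18.0,
          "k2": 18.0
        },
        {
          "name": "h",
          "exponent": 1,
          "kind": "volt",
          "vh": -55.0,
          "k": -7.0,
          "tau_min": 0.8,
          "tau_amp": 10.0,
          "v_tau": -55.0,
          "k1": 12.0,
          "k2": 12.0
        }
      ]
    },
    "K_DR": {
      "ion": "k",
      "gates": [
        {
          "name": "n",
          "exponent": 2,
          "kind": "volt",
          "vh": -35.0,
          "k": 8.0,
          "tau_min": 0.8,
          "tau_amp": 4.0,
          "v_tau": -35.0,
          "k1": 20.0,
          "k2": 20.0
        }
      ]
    },
    "K_A": {
      "ion": "k",
      "gates": [
        {
          "name": "a",
          "exponent": 1,
          "kind": "volt",
          "vh": -30.0,
          "k": 13.0,
          "tau_min": 0.3,
          "tau_amp": 2.0,
          "v_tau": -30.0,
          "k1": 25.0,
          "k2": 25.0
        },
        {
          "name": "b",
          "exponent": 1,
          "kind": "volt",
          "vh": -72.0,
          "k": -7.0,
          "tau_min": 4.0,
          "tau_amp": 20.0,
          "v_tau": -60.0,
          "k1": 15.0,
          "k2": 15.0
        }
      ]
    },
    "K_M": {
      "ion": "k",
      "gates": [
        {
          "name": "m",
          "exponent": 1,
          "kind": "volt",
          "vh": -35.0,
          "k": 9.0,
          "tau_min": 10.0,
          "tau_amp": 60.0,
          "v_tau": -35.0,
          "k1": 20.0,
          "k2": 20.0
        }
      ]
    },
    "K_D": {
      "ion": "k",
      "gates": [
        {
          "name": "a",
          "exponent": 1,
          "kind": "volt",
          "vh": -55.0,
          "k": 8.0,
          "tau_min": 1.0,
          "tau_amp": 4.0,
          "v_tau": -55.0,
          "k1": 20.0,
          "k2": 20.0
        },
        {
          "name": "b",
          "exponent": 1,
          "kind": "volt",
          "vh": -75.0,
          "k": -8.0,
          "tau_min": 50.0,
          "tau_amp": 300.0,
          "v_tau": -75.0,
          "k1": 20.0,
          "k2": 20.0
        }
      ]
    },
    "CaN": {
      "ion": "ca",
      "gates": [
        {
          "name": "m",
          "exponent": 2,
          "kind": "volt",
          "vh": -20.0,
          "k": 7.0,
          "tau_min": 0.5,
          "tau_amp": 2.0,
          "v_tau": -20.0,
          "k1": 18.0,
          "k2": 18.0
        },
        {
          "name": "h",
          "exponent": 1,
          "kind": "volt",
          "vh": -45.0,
          "k": -10.0,
          "tau_min": 20.0,
          "tau_amp": 50.0,
          "v_tau": -45.0,
          "k1": 20.0,
          "k2": 20.0
        }
      ]
    },
    "CaL": {
      "ion": "ca",
      "gates": [
        {
          "name": "m",
          "exponent": 2,
          "kind": "volt",
          "vh": -15.0,
          "k": 6.0,
          "tau_min": 0.8,
          "tau_amp": 1.5,
          "v_tau": -15.0,
          "k1": 15.0,
          "k2": 15.0
        }
      ]
    },
    "CaT": {
      "ion": "ca",
      "gates": [
        {
          "name": "m",
          "exponent": 2,
          "kind": "volt",
          "vh": -42.0,
          "k": 5.0,
          "tau_min": 1.5,
          "tau_amp": 6.0,
          "v_tau": -42.0,
          "k1": 15.0,
          "k2": 15.0
        },
        {
          "name": "h",
          "exponent": 1,
          "kind": "volt",
          "vh": -67.0,
          "k": -5.0,
          "tau_min": 10.0,
          "tau_amp": 30.0,
          "v_tau": -67.0,
          "k1": 15.0,
          "k2": 15.0
        }
      ]
    },
    "Ih": {
      "ion": "nonspecific",
      "gates": [
        {
          "name": "q",
          "exponent": 1,
          "kind": "volt",
          "vh": -82.0,
          "k": -8.0,
          "tau_min": 20.0,
          "tau_amp": 60.0,
          "v_tau": -80.0,
          "k1": 18.0,
          "k2": 18.0
        }
      ]
    },
    "K_Ca": {
      "ion": "k",
      "gates": [
        {
          "name": "c",
          "exponent": 1,
          "kind": "ca",
          "kd": 0.0005,
          "hill": 2.0,
          "tau0": 120.0
        }
      ]
    },
    "Cagk": {
      "ion": "k",
      "gates": [
        {
          "name": "o",
          "exponent": 1,
          "kind": "cavolt",
          "kd": 0.001,
          "hill": 2.0,
          "vh": -25.0,
          "k": 9.0,
          "tau0": 3.0
        }
      ]
    }
  }
}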