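{
  "PLS": {
    "ALG": {"preprocessing": ["MC"], "compression": null,
            "params": {"max_lv": 10, "alpha": 0.25}},
    "PIO": {"preprocessing": ["MC"], "compression": null,
            "params": {"max_lv": 10, "alpha": 0.25}},
    "GLM": {"preprocessing": ["MC"], "compression": null,
            "params": {"max_lv": 10, "alpha": 0.25}}
  },
  "ANN": {
    "ALG": {"preprocessing": ["MC"], "compression": {"method": "PCA", "k": 4},
            "params": {"hidden": 5, "learning_rate": 0.125,
                        "max_epochs": 2000, "patience": 20}},
    "PIO": {"preprocessing": ["MC"], "compression": {"method": "PLS", "k": 3},
            "params": {"hidden": 5, "learning_rate": 0.125,
                        "max_epochs": 2000, "patience": 20}},
    "GLM": {"preprocessing": ["MC"], "compression": {"method": "PCA", "k": 4},
            "params": {"hidden": 5, "learning_rate": 0.125,
                        "max_epochs": 2000, "patience": 20}}
  },
  "SVR": {
    "ALG": {"preprocessing": ["MC", "OSC"], "compression": {"method": "PCA", "k": 4},
            "params": {"C": 100.0, "nu": 0.5, "gamma": 0.1}},
    "PIO": {"preprocessing": ["MC", "OSC"], "compression": {"method": "PCA", "k": 4},
            "params": {"C": 100.0, "nu": 0.5, "gamma": 0.1}},
    "GLM": {"preprocessing": ["MC"], "compression": {"method": "PCA", "k": 4},
            "params": {"C": 31.623, "nu": 0.5, "gamma": 3.162}}
  },
  "XGB": {
    "ALG": {"preprocessing": ["MC", "OSC"], "compression": {"method": "PLS", "k": 3},
            "params": {"eta": 0.5, "max_depth": 6, "num_round": 300}},
    "PIO": {"preprocessing": ["MC", "OSC"], "compression": {"method": "PLS", "k": 3},
            "params": {"eta": 0.1, "max_depth": 1, "num_round": 300}},
    "GLM": {"preprocessing": ["MC"], "compression": {"method": "PLS", "k": 3},
            "params": {"eta": 0.3, "max_depth": 4, "num_round": 300}}
  }
}
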