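{
  "description": "Literature-derived ranges of the nondimensional model parameters (rho, eps, alpha, kappa, beta) for published channel-rheotaxis experiments. 'point' entries are order-of-magnitude estimates; 'interval' entries are ranges; null means not estimable from the study. Starred alpha entries were estimated from the intact-lateral-line swimming speed.",
  "presets": [
    {
      "label": "study-1",
      "rho": {"kind": "point", "value": 0.05},
      "eps": {"kind": "interval", "lo": 0.01, "hi": 0.1},
      "alpha": {"kind": "interval", "lo": 0.0, "hi": 0.17},
      "kappa": null,
      "beta": null,
      "note": ""
    },
    {
      "label": "study-2",
      "rho": {"kind": "point", "value": 0.04},
      "eps": {"kind": "interval", "lo": 0.01, "hi": 0.1},
      "alpha": {"kind": "interval", "lo": 0.0, "hi": 0.16},
      "kappa": {"kind": "point", "value": 0.0},
      "beta": {"kind": "interval", "lo": 0.0, "hi": 100.0},
      "note": "alpha estimated from intact-lateral-line swimming speed ~5 cm/s in still water"
    },
    {
      "label": "study-3",
      "rho": {"kind": "point", "value": 0.1},
      "eps": {"kind": "interval", "lo": 0.01, "hi": 0.1},
      "alpha": {"kind": "interval", "lo": 0.0, "hi": 0.32},
      "kappa": {"kind": "interval", "lo": 2.0, "hi": 7.0},
      "beta": {"kind": "interval", "lo": 0.0, "hi": 256.0},
      "note": "alpha estimated from intact-lateral-line swimming speed; kappa from the threshold-speed ratio after lateral-line ablation"
    },
    {
      "label": "mexican-tetra",
      "rho": {"kind": "point", "value": 0.066},
      "eps": {"kind": "interval", "lo": 0.01, "hi": 0.1},
      "alpha": {"kind": "interval", "lo": 0.0, "hi": 0.24},
      "kappa": {"kind": "point", "value": 0.0},
      "beta": {"kind": "interval", "lo": 0.0, "hi": 55.0},
      "note": "body length 8.3 cm in a 25 cm channel; alpha estimated from intact-lateral-line swimming speed"
    },
    {
      "label": "study-5",
      "rho": {"kind": "point", "value": 0.04},
      "eps": {"kind": "point", "value": 1.0},
      "alpha": {"kind": "point", "value": 1.3},
      "kappa": null,
      "beta": null,
      "note": "eps ~1 near the center of a jet"
    },
    {
      "label": "zebrafish-larvae",
      "rho": {"kind": "interval", "lo": 0.018, "hi": 0.066},
      "eps": {"kind": "interval", "lo": 0.2, "hi": 0.82},
      "alpha": null,
      "kappa": null,
      "beta": null,
      "note": "body length ~4.2 mm in 1.27-4.76 cm tubes; low-Reynolds laminar profiles"
    },
    {
      "label": "study-7",
      "rho": {"kind": "point", "value": 0.044},
      "eps": {"kind": "point", "value": 1.0},
      "alpha": null,
      "kappa": null,
      "beta": null,
      "note": ""
    },
    {
      "label": "study-8",
      "rho": {"kind": "point", "value": 0.018},
      "eps": {"kind": "interval", "lo": 0.1, "hi": 1.0},
      "alpha": null,
      "kappa": null,
      "beta": null,
      "note": ""
    },
    {
      "label": "study-9",
      "rho": {"kind": "interval", "lo": 0.055, "hi": 0.127},
      "eps": {"kind": "interval", "lo": 0.01, "hi": 0.1},
      "alpha": {"kind": "interval", "lo": 0.0, "hi": 0.32},
      "kappa": {"kind": "point", "value": 0.0},
      "beta": {"kind": "interval", "lo": 0.0, "hi": 106.0},
      "note": "alpha estimated from intact-lateral-line swimming speed"
    }
  ]
}
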