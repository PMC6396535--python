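{
  "source": "ECSC/ERS 1993 summary reference equations for total lung capacity, adults; TLC [L] = slope * height [m] + intercept",
  "units": {"height": "m", "tlc": "L"},
  "male": {"height_slope": 7.99, "intercept": -7.08},
  "female": {"height_slope": 6.60, "intercept": -5.79}
}
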