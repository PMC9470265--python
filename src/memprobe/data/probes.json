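{
  "pro12a": {
    "lambda_lo": 423.0,
    "lambda_ld": 494.0,
    "excitation_nm": 405.0,
    "channels": {"start_nm": 423.0, "stop_nm": 601.0, "n": 20}
  },
  "nr12s": {
    "lambda_lo": 557.0,
    "lambda_ld": 664.0,
    "excitation_nm": 488.0,
    "channels": {"start_nm": 503.0, "stop_nm": 700.0, "n": 22}
  },
  "nr12a": {
    "lambda_lo": 583.0,
    "lambda_ld": 673.0,
    "excitation_nm": 488.0,
    "channels": {"start_nm": 503.0, "stop_nm": 700.0, "n": 22}
  }
}
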