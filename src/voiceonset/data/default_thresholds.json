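{
  "amp_mod": 0.49363672286305577,
  "amplitude": 0.5700525058542337,
  "freq_mod": 0.660815023257982,
  "harmonic_pitch": 0.5347145712870028,
  "spectral_change": 0.3851265216601541,
  "wiener_entropy": 0.5204328500263609
}
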