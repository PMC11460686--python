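{
 "duration_ms": 600000.0,
 "state": {
  "V": -73.1970841762385,
  "Ca_SR": 0.4902844777875077,
  "Cai": 3.51418926203445e-05,
  "Nai": 8.15955977159483,
  "Ki": 103.57456774581932,
  "m": 0.039845298644961405,
  "h": 0.6738736642239179,
  "j": 0.6416099062796424,
  "d": 0.0005566229376487986,
  "f": 0.8819743791090471,
  "fCa": 1.0072237701567566,
  "Xr1": 0.0006326474864391703,
  "Xr2": 0.4241625350957015,
  "Xs": 0.0669596972310634,
  "Xf": 0.050258991656416716,
  "r": 0.0003313979649254421,
  "s": 0.9771012275857756,
  "dCaT": 0.00040267544671373004,
  "fCaT": 0.8902361820169353,
  "RyR_R": 0.9356326926471857,
  "RyR_O": 5.979709872427614e-06,
  "RyR_I": 4.112982234228092e-07
 }
}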