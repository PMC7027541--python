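metadata:
  calibration: one-parameter timescale fit (Brent) of the nominal rate set to the
    human baseline time-to-peak of 34 s
  fitted_on: human baseline copy numbers only; mouse held out
  optimizer: scipy.optimize.brentq, xtol 1e-6 (deterministic; seed 0 recorded for
    provenance)
  seed: 0
rates:
  k_act: 8981.883627576468
  k_auto: 157182.96348258818
  k_cbl: 44909.41813788234
  k_down: 13472.825441364703
  k_int: 0.004490941813788234
  k_off: 0.022454709068941172
  k_on: 314365.92696517636
  k_tula: 1347282.5441364702
schema_version: 1
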