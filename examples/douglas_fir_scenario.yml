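# Douglas-fir stand under a mid-range warming scenario.
# Anything omitted falls back to the package defaults
# (summer-dry montane synthetic climate, published soil/canopy tables).

species: douglas_fir
seed: 7

site:
  latitude: 50.93
  elevation: 1162

reference:
  years: 30            # calibration period for NGRI/NDRI

run:
  years: 80
  established: false   # true: 60 reference years precede the change

co2:
  c_a0: 380.0          # reference concentration (2005-pinned)

# monthly temperature offsets (degC) and precipitation ratios per
# anchor period, interpolated linearly between anchors; CO2 trajectory
# in ppm
scenario:
  anchors:
    2005:
      t_offsets: [0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
      p_ratios:  [1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]
    2025:
      t_offsets: [1.4, 1.3, 1.2, 1.1, 1.0, 1.1, 1.3, 1.4, 1.2, 1.1, 1.2, 1.4]
      p_ratios:  [1.02, 1.02, 1.01, 1.0, 0.99, 0.97, 0.95, 0.95, 0.98, 1.0, 1.02, 1.03]
    2055:
      t_offsets: [2.8, 2.6, 2.4, 2.2, 2.1, 2.3, 2.7, 2.9, 2.5, 2.2, 2.4, 2.8]
      p_ratios:  [1.04, 1.03, 1.02, 1.0, 0.98, 0.95, 0.92, 0.92, 0.96, 1.0, 1.03, 1.05]
    2085:
      t_offsets: [3.8, 3.6, 3.3, 3.0, 2.9, 3.1, 3.6, 3.9, 3.4, 3.0, 3.3, 3.8]
      p_ratios:  [1.05, 1.04, 1.02, 1.0, 0.97, 0.94, 0.90, 0.90, 0.95, 1.0, 1.04, 1.06]
  co2:
    2005: 380
    2025: 431
    2055: 487
    2085: 532
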