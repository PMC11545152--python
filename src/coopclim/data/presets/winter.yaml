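# Winter preset: pads closed, minimum-ventilation season. The floor offset
# places the manure-pit temperature near the indoor range (the pit sits
# inside the heated house) rather than at outdoor temperature.
season: winter
setpoint_c: 25.5
gains: {kp: 13.0, ki: 12.0, kd: 4.0}
pad_open: false
ventilation: {min_m3_per_min: 1858.0, max_m3_per_min: 7435.0}
profile:
  t_min: -10.5
  t_max: 1.4
  rh_mean: 46.9
  irradiance_peak: 400.0
  sunrise_h: 7.5
  sunset_h: 17.0
  t_mean: -5.7
  floor_offset: 27.5
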