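# Autumn preset: pads closed.
season: autumn
setpoint_c: 27.0
gains: {kp: 17.0, ki: 13.0, kd: 8.0}
pad_open: false
ventilation: {min_m3_per_min: 1858.0, max_m3_per_min: 7435.0}
profile:
  t_min: 13.2
  t_max: 27.4
  rh_mean: 45.3
  irradiance_peak: 600.0
  sunrise_h: 6.5
  sunset_h: 17.5
  t_mean: 19.4
  floor_offset: 4.0
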