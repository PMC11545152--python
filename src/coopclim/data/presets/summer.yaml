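# Summer preset: evaporative pads open, hottest validation day as the
# synthetic profile anchor.
season: summer
setpoint_c: 27.5
gains: {kp: 23.0, ki: 15.0, kd: 3.0}
pad_open: true
ventilation: {min_m3_per_min: 1858.0, max_m3_per_min: 7435.0}
profile:
  t_min: 19.3
  t_max: 35.0
  rh_mean: 45.4
  irradiance_peak: 850.0
  sunrise_h: 5.0
  sunset_h: 19.5
  t_mean: 26.9
  floor_offset: -2.0
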