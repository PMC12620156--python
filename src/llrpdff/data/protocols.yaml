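# Packaged acquisition protocol presets: two low-field (0.55 T) multi-echo
# GRE protocols at minimum-TE spacing and two 1.5 T product protocols.
protocol1_055T:
  field_strength_t: 0.55
  te_ms: [1.8, 3.4, 5.1, 6.8, 8.5, 10.2]
  tr_ms: 12.5
  acceleration: 4
  acquired_matrix: [109, 160, 48]
  flip_angle_deg: 4.0
protocol2_055T:
  field_strength_t: 0.55
  te_ms: [1.6, 3.3, 4.9, 6.5, 8.2, 9.8]
  tr_ms: 11.8
  acceleration: 3
  acquired_matrix: [89, 128, 48]
  flip_angle_deg: 4.0
protocol1_15T:
  field_strength_t: 1.5
  te_ms: [1.3, 2.6, 3.9, 5.2, 6.5, 7.8]
  tr_ms: 9.2
  acceleration: 3
  acquired_matrix: [111, 160, 48]
  flip_angle_deg: 4.0
protocol2_15T:
  field_strength_t: 1.5
  te_ms: [2.4, 4.8, 7.1, 9.5, 11.9, 14.3]
  tr_ms: 15.6
  acceleration: 4
  acquired_matrix: [109, 160, 44]
  flip_angle_deg: 4.0
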