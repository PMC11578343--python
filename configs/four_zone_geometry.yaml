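# Four-zone device: 6 mm zones, period lengths 500/250/167/125 µm,
# contraction width 11.25 + 2.75 cos(2*pi*x/L_p) µm, 21 µm nodes,
# 1 mm sizing pore with a 25 µm effective diameter.
pore:
  L_pore: 1000.0
  D_eff: 25.0
zones:
  - {L_zone: 6000.0, L_p: 500.0, w0: 11.25, a: 2.75, w_node: 21.0}
  - {L_zone: 6000.0, L_p: 250.0, w0: 11.25, a: 2.75, w_node: 21.0}
  - {L_zone: 6000.0, L_p: 167.0, w0: 11.25, a: 2.75, w_node: 21.0}
  - {L_zone: 6000.0, L_p: 125.0, w0: 11.25, a: 2.75, w_node: 21.0}
zone_D_eff: [25.0, 25.0, 25.0, 25.0]
sample_rate: 10000.0
applied_pressure: 13800.0
node_length: 500.0
mu_f: 0.1
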