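# Reference device: one chamber unit of the millifluidic flow cell.
geometry:
  chamber_diameter: 8 mm
  connector_width: 5 mm
  connector_length: 5 mm
  disc_diameter: 3 mm
  channel_width: 400 um
  channel_angle: 30 deg

mesh:
  # test-scale resolution; the reference twin uses 20 um / 1 mm
  h_boundary: 40 um
  h_max: 1 mm

simulation:
  bulk_velocity: 115 um/s
  t_end: 24 h
  dt: 12 s

# physics defaults live in macropore.growth.GrowthParams; override here, e.g.
# physics:
#   B_max: 1.0e24

sweep:
  angles: [0, 15, 30, 45, 60, 75, 90]
  widths_um: [200, 300, 400, 500, 600]
  velocities_um_s: [11.5, 115, 1150]
  include_solid_controls: true
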