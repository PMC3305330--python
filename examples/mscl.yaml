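# Worked example: MscL gating in a half-protein membrane.
# Channel opens from 2.4 to 3.5 nm radius among uniform 1 nm crowders
# occupying half the membrane area.
channel:
  closed_radius: 2.4   # nm
  open_radius: 3.5     # nm
crowders:
  radius: 1.0          # nm, uniform crowders (delta2 = 0)
  area_fraction: 0.5
applied_tension: 0.0   # kBT/nm^2
gating_tension: 0.9    # kBT/nm^2, bare (non-crowding) gating tension
tension_grid:
  min: 0.0
  max: 2.0
  n: 201
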