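# Demo pipeline: Brownian pore simulation -> permeation counting -> occupancy.
# All randomness flows from this seed; rerunning reproduces summary.json exactly.
seed: 1

simulate:
  n_frames: 20000      # recorded frames
  dt: 1.0e-3           # ns per integration step
  substeps: 5          # integration steps per recorded frame (100 ns total)
  model:
    voltage: 0.6                 # V, transmembrane
    ion_charge: 2.0              # e (divalent)
    n_ions: 3
    diffusion_coeff: 30.0        # Å²/ns (confined-ion estimate)
    well_positions: [-7.0, -2.0, 3.0, 8.0]   # binding sites along the pore (Å)
    well_depths: [3.0, 4.0, 3.0, 2.0]        # k_BT
    well_width: 1.5
    coupling_strength: 25.0      # k_BT·Å screened ion-ion repulsion
    screening_length: 3.0        # Å
    box: [30.0, 30.0, 70.0]      # Å
    temperature: 303.0           # K

permeation:
  span: [-10.0, 10.0]    # channel span the ion must fully traverse (Å)
  counting: net          # net = outward - inward

occupancy:
  bins: [-35.0, 35.0, 70]
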