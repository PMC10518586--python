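# Demonstration configuration: generates a synthetic dataset with every
# planted feature (thinned patch, hydrogen-bonded DDA aggregate, spanning
# water wire, flavonoids) and runs all analysis stages on it.
#
#   membrane-probe run --config examples/demo.yaml --outdir runs/demo
seed: 42
outdir: runs/demo
simulate:
  lipids_per_leaflet: 64
  lateral_box: [10.0, 10.0]
  head_plane_offset: 1.85
  n_frames: 5
  patch:
    center_xy: [5.0, 5.0]
    radius: 1.5
    head_plane_offset_inside: 1.35
  aggregate:
    n_dda: 8
    center_xy: [5.0, 5.0]
    lateral_sigma: 0.8
    carboxyl_pairing: 1.0
  water:
    count: 200
    slab_bounds: [2.2, 3.0]
    wire:
      n_waters: 9
      spacing: 0.28
      endpoints_z: [-1.12, 1.12]
  flavonoid_count: 13
saxs_fit:
  q_min: 0.05
  q_max: 6.0
afm:
  n_regions: 4
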