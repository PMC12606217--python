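# Visual characterization phase -> adaptive photostimulation targeting.
actors:
  source:
    impl: neuroloop.demos.actors.CharacterizationSource
    params: {n_rois: 20, repetitions: 2}
  tuning:
    impl: neuroloop.demos.actors.TuningActor
    params: {threshold: 0.9}
  photostim:
    impl: neuroloop.demos.actors.PhotostimActor
    params: {n_targets: 3, repetitions: 5}
connections:
  - source.out -> tuning.in
  - tuning.out -> photostim.in
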