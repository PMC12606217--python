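# Trajectory stream -> Bubblewrap mixture-HMM prediction.
actors:
  source:
    impl: neuroloop.demos.actors.LimitCycleSource
    params: {n_frames: 3000, dims: 6, noise_sd: 0.05}
  bubblewrap:
    impl: neuroloop.demos.actors.BubblewrapActor
    params: {n_tiles: 50, n_init: 20, horizons: [1, 2, 3, 4, 5], eval_stride: 5}
connections:
  - source.out -> bubblewrap.in
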