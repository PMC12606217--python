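# Behavior video -> streaming proSVD -> streaming ridge regression.
actors:
  source:
    impl: neuroloop.demos.actors.BehaviorSource
    params: {height: 24, width: 32, rank: 3, n_neurons: 10, n_frames: 600}
  prosvd:
    impl: neuroloop.demos.actors.ProSVDActor
    params: {k: 6, init_frames: 10}
  ridge:
    impl: neuroloop.demos.actors.RidgeActor
    params: {lam: 1.0e-5}
connections:
  - source.out -> prosvd.in
  - prosvd.out -> ridge.in
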