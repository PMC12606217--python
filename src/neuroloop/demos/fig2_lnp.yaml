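# Streaming LNP model fitting on a simulated spiking population.
actors:
  source:
    impl: neuroloop.demos.actors.LNPPopulationSource
    params: {n_neurons: 12, n_frames: 800}
  lnp:
    impl: neuroloop.demos.actors.LNPActor
    params: {window: 100}
connections:
  - source.out -> lnp.in
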