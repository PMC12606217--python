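# Closed-loop Bayesian optimization of visual stimuli (cyclic pipeline).
actors:
  presenter:
    impl: neuroloop.demos.actors.StimulusPresenter
    params: {n_neurons: 30, noise_sd: 0.2}
  bo:
    impl: neuroloop.demos.actors.BOActor
    params: {n_neurons: 30, n_max: 30}
connections:
  - presenter.out -> bo.in
  - bo.out -> presenter.in
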