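# Published-scale joint-moment CNN (dense head widths)
net:
  family: cnn
  layer_widths: [2000, 4000]
  learning_rate: 0.0001
  dropout: 0.4
  activation: relu
  epochs: 40
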