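# Published-scale joint-angle CNN (dense head widths)
net:
  family: cnn
  layer_widths: [3000, 6000]
  learning_rate: 0.00003
  dropout: 0.4
  activation: relu
  epochs: 40
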