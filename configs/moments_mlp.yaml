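# Published-scale joint-moment MLP
net:
  family: mlp
  layer_widths: [3000, 1000]
  learning_rate: 0.0003
  dropout: 0.5
  activation: relu
  epochs: 40
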