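# Published-scale joint-angle LSTM
net:
  family: lstm
  layer_widths: [32, 32]
  learning_rate: 0.0003
  dropout: 0.7
  activation: tanh
  epochs: 40
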