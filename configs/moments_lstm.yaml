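# Published-scale joint-moment LSTM
net:
  family: lstm
  layer_widths: [128, 1024]
  learning_rate: 0.0003
  dropout: 0.4
  activation: tanh
  epochs: 40
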