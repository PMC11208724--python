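# Example configuration for `olbac train`.
train.lambda1: 0.6          # weight of the prediction-stability loss
train.lambda2: 0.3          # weight of reconstruction + validity losses
train.epochs: 100
train.batch_size: 32
train.base_lr: 3.0e-3       # linear warm-up then linear decay
train.warmup_fraction: 0.1
train.eta: 1.0              # training-time perturbation size
train.epsilon: 0.01         # probe radius
train.p0: 0.5               # confidence threshold for selections
train.task: regression

model.hidden_dim: 64        # embedding width D
model.encoder_layers: 2     # message-passing rounds L (decoder matches)
model.decoder_T: 1          # molecule-to-atom refinement rounds
model.dropout: 0.1
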