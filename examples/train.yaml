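# Desk-scale training configuration: completes stage 1 in minutes on one
# CPU.  Remove the `generator` block to train the full-size model
# (14 backbone conv layers, 64 channels).
stage: mse
lr_init: 3.0e-4
lr_decay_factor: 3.0
max_decay_cycles: 3
plateau_patience: 3
batch_size: 16
max_epochs: 30
generator:
  n_residual_layers: 4
  channels: 8
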