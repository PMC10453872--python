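# A desk-scale learning-rate grid over a synthetic archive.
output_dir: runs/lr-grid
seed: 7
synthetic:
  n_images: 400
  class_balance: 0.5
  image_side: 64
  hair_probability: 0.3
  seed: 7
train_fraction: 0.7
unlabeled_fraction: 0.3
preprocess:
  target_size: [64, 64]
learning_rates: [0.01, 0.001, 0.0002]
batch_sizes: [16]
epochs: 3
momentum: 0.5
generator_loss_form: saturating
n_generate: 8
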