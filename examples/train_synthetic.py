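"""Train the revised model end-to-end on synthetic fundus data.

Generates a small balanced dataset (healthy vs red-lesion images), trains
the width-0.25 revised ResNet-50 with multiplication fusion on 64x64 inputs
for a few epochs, and evaluates on held-out images. Takes about half a
minute on one CPU.
"""

import numpy as np

import fundusdr as f
from fundusdr.preprocess import resize

seed = 0
spec = f.SyntheticSpec(seed=seed)
rng = np.random.default_rng(seed)
train_s = f.generate_samples(spec, 100, 100, rng=rng)
val_s = f.generate_samples(spec, 30, 30, rng=rng)


def arrays(samples):
    x = f.images_to_batch([resize(s.image, 64, 64) for s in samples])
    return x, np.array([s.label for s in samples], dtype=np.float32)


model = f.build_revised_model(
    f.ModelConfig(input_side=64, width_multiplier=0.25, init_seed=seed),
    f.FusionSpec(merge_op="multiplication"),
)
history = f.train(
    model, arrays(train_s), arrays(val_s),
    f.TrainConfig(epochs=10, batch_size=32, seed=seed),
)

print("epoch  train_acc  train_loss  val_acc  val_loss  lr")
for h in history:
    print(f"{h['epoch']:>5}  {h['train_acc']:>9.3f}  {h['train_loss']:>10.3f}"
          f"  {h['val_acc']:>7.3f}  {h['val_loss']:>8.3f}  {h['lr']:.4f}")

best = max(h["val_acc"] for h in history)
print(f"\nbest validation accuracy {best:.3f}: the model separates lesioned "
      "from healthy retinas from 200 training images in 10 epochs.")
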