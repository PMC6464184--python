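"""Train a hypercomplex ELM on the standard synthetic benchmark.

Generates 20 synthetic identities x 10 acquisitions x 4 registered
channels (32 x 32 ridge textures), splits them half/half per class, trains
a HELM with 500 hidden nodes and prints the test recognition accuracy —
the fraction of held-out acquisitions assigned to the right identity.
"""

import numpy as np

from hyperelm import (
    SynthConfig,
    generate_images,
    helm_predict,
    helm_train,
    images_to_dataset,
    recognition_accuracy,
)
from hyperelm.preprocessing import stratified_split_indices

cfg = SynthConfig(seed=0)
images, labels = generate_images(cfg)
train_idx, test_idx = stratified_split_indices(labels, train_fraction=0.5, seed=0)
train = images_to_dataset(images[train_idx], labels[train_idx])
test = images_to_dataset(images[test_idx], labels[test_idx])

model = helm_train(train, n_hidden=500, activation="sigmoid", seed=0)
pred = helm_predict(model, test)
acc = recognition_accuracy(pred, test.labels)
print(f"classes: {train.n_classes}, channels: {train.n_channels}, "
      f"train/test: {train.n_samples}/{test.n_samples}")
print(f"test recognition accuracy: {acc:.2f}%")
errors = np.flatnonzero(pred != test.labels)
print(f"misrecognized samples: {len(errors)} of {test.n_samples}")
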