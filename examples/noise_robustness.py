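"""Recognition under test-time image corruptions.

Trains a HELM on clean synthetic images and evaluates the held-out set
clean and under the three standard corruptions: additive Gaussian noise
(std 36 on the 8-bit scale), salt & pepper (10% of pixels) and
multiplicative speckle (variance 0.05).  Accuracy should degrade gently —
the min-max sum fusion averages information over channels.
"""

from hyperelm import (
    SynthConfig,
    apply_noise,
    generate_images,
    helm_predict,
    helm_train,
    images_to_dataset,
    recognition_accuracy,
)
from hyperelm.preprocessing import stratified_split_indices

cfg = SynthConfig(seed=1)
images, labels = generate_images(cfg)
tr, te = stratified_split_indices(labels, train_fraction=0.5, seed=1)
model = helm_train(images_to_dataset(images[tr], labels[tr]), n_hidden=500, seed=1)

for kind in ("none", "gaussian", "saltpepper", "speckle"):
    noisy = apply_noise(images[te], kind, seed=2)
    ds = images_to_dataset(noisy, labels[te])
    acc = recognition_accuracy(helm_predict(model, ds), ds.labels)
    print(f"{kind:<12} test accuracy: {acc:6.2f}%")
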