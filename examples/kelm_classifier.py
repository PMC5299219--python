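"""Train a kernel extreme learning machine and score held-out samples.

Builds a small two-class table with 5 informative features, fits the
closed-form KELM (C=32, gamma=0.5) on the first 80 samples and reports
accuracy on the remaining 20.  The accuracy printed is the fraction of
held-out samples whose decision-value sign matches their class.
"""

import numpy as np

from wolfsel import Dataset, KELMConfig, SyntheticSpec, generate_synthetic, predict, train
from wolfsel.datasets import normalize_minmax

data = normalize_minmax(generate_synthetic(SyntheticSpec(
    n_samples=100, n_informative=5, n_noise=5, class_separation=2.0, seed=42)))

train_set = Dataset(data.features[:80], data.labels[:80], data.feature_names)
model = train(train_set, KELMConfig(C=32.0, gamma=0.5))

held_out = predict(model, data.features[80:], encoded=True)
accuracy = np.mean(held_out == data.labels[80:])
print(f"held-out accuracy: {accuracy:.2%} on 20 samples")
print("first five decision signs:", held_out[:5])
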