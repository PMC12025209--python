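"""Build the labeled dataset, rank features with ReliefF, keep the two
best per channel, and train the backpropagation classifier.

This is the full recognition-model construction at desk scale: one
3.15 s recording per movement yields exactly 60 analysis windows per
class (420 windows x 40 features).
"""

import wristemg as w

config = w.GeneratorConfig(duration=3.15, seed=11)
recordings = w.generate_dataset(1, config=config)
features = w.extract_dataset(recordings)
print(f"dataset: {features.n_windows} windows x {len(features.feature_names)} features")

weights = w.relieff_weights(features, k_neighbors=10)
selected = w.select_top_per_channel(weights, per_channel=2)
print(f"\nReliefF kept {len(selected)} of {len(features.feature_names)} features:")
print(" ", ", ".join(selected))
# Amplitude features (MAV/RMS) dominate because the generator encodes
# movements purely in per-channel amplitude.

fm16 = w.project_features(features, selected)
model, report = w.train(fm16, w.TrainConfig(
    learning_rate=0.001, iterations=5000, seed=7))
print(f"\nnetwork layers: {model.layer_sizes}")  # 16 -> 15 -> 15 -> 7
print(f"initial mean loss {report.loss_curve[0]:.3f} (ln 7 = 1.946), "
      f"final {report.final_loss:.4f}")
print(f"train accuracy {report.train_accuracy:.1%}, "
      f"held-out accuracy {report.test_accuracy:.1%}")
# On this separable synthetic set the held-out accuracy reaches 100%;
# the pipeline is designed around a >= 97.4% floor.
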