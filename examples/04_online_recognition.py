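"""Deploy a trained model online: windowed classification, voting, and
command triggering over a recording that goes rest -> flexion -> rest.
"""

import numpy as np

import wristemg as w

# train at desk scale (see 02_select_and_train.py)
config = w.GeneratorConfig(duration=3.15, seed=11)
features = w.extract_dataset(w.generate_dataset(1, config=config))
selected = w.select_top_per_channel(w.relieff_weights(features), 2)
model, _ = w.train(w.project_features(features, selected),
                   w.TrainConfig(iterations=5000, seed=7))

# a 6 s session: 2 s relaxation, 2 s large flexion, 2 s relaxation
seg = lambda m, s: w.generate_recording(m, 0.0, w.GeneratorConfig(duration=2.0, seed=s))
session = w.EMGRecording(
    samples=np.hstack([seg("RELAX", 80).samples,
                       seg("F-L", 81).samples,
                       seg("RELAX", 82).samples]),
    sampling_rate=1000.0,
)

trace = w.recognize_online(model, session, selected=selected)
commands = w.commands_from_trace(trace)
print(f"{len(trace)} windows processed, commands emitted: {commands}")
for t in trace:
    if t.command:
        print(f"  window {t.window_index} "
          f"(~{t.window_index * 0.05 + 0.1:.2f} s): command {t.command!r}")
# Exactly one F-L command fires shortly after the flexion starts —
# the voted stream needs five consecutive identical results — and the
# return to rest emits nothing.
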