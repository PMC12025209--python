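"""Majority-of-5 voting and the consecutive-result command trigger.

The voting decision suppresses isolated classification errors; the
intensified trigger emits a robot command only after five consecutive
identical voted results, once per run, and never for relaxation.
"""

import wristemg as w
from wristemg.decision import DecisionState

# iid error null: a stream that is right 90.7% of the time, frame by frame
n = 100_000
truth = ["U"] * n
stream = w.generate_label_stream(truth, frame_accuracy=0.907, seed=5)
smoothed = w.smooth_stream(stream)
raw_acc, voted_acc, gain = w.compare_accuracy(stream, smoothed, truth)
print(f"raw accuracy {raw_acc:.1%} -> voted accuracy {voted_acc:.2%} "
      f"(+{gain:.1%})")
# Majority-of-5 needs 3+ coordinated errors in a window to fail, so
# ~90.7% per-frame accuracy becomes >99% after voting.

# the trigger on a short voted stream with a hesitation
voted = ["RELAX"] * 6 + ["U"] * 4 + ["RELAX"] + ["U"] * 7
state = DecisionState()
for i, label in enumerate(voted):
    state, command = w.trigger_step(state, label)
    if command:
        print(f"step {i}: command {command!r} emitted")
# The first run of U breaks at 4, so nothing fires; the second run
# reaches 5 and emits exactly one U command. RELAX never triggers.
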