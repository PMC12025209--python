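"""Decision smoothing for the per-window classifier output stream.

Two post-processing stages stabilise raw window-by-window
classifications before they reach the rehabilitation robot:

* the *voting decision* — a sliding majority filter over the five most
  recent classifications, which suppresses isolated errors; and
* the *intensified trigger* — a movement command is emitted only after
  five consecutive identical voted results, and only once per run, so a
  held posture issues a single command and relaxation never triggers.

Tie-breaking in the vote keeps the previous output when it is among the
tied labels (minimising command chatter), otherwise the tied label that
occurs earliest in the window wins.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

from .classifier import MLPModel, predict_batch
from .features import FeatureConfig, extract_features
from .selection import project_features
from .synthetic import RELAX, EMGRecording

VOTE_WINDOW = 5
TRIGGER_RUN = 5


def majority_vote(window: list[str], previous_output: str | None = None) -> str:
    """Modal label of a window of up to five recent classifications.

    On a tie, ``previous_output`` wins if it is among the tied labels;
    otherwise the tied label occurring earliest in the window.
    """
    if not window:
        raise ValueError("vote window must be nonempty")
    counts = Counter(window)
    top = max(counts.values())
    tied = [label for label, c in counts.items() if c == top]
    if len(tied) == 1:
        return tied[0]
    if previous_output in tied:
        return previous_output
    for label in window:
        if label in tied:
            return label
    raise AssertionError("unreachable")


def smooth_stream(stream: list[str]) -> list[str]:
    """Apply the sliding majority-of-5 vote to a whole label stream.

    The first four frames vote over the partial window available so
    far, so the output has the same length as the input.
    """
    if not stream:
        raise ValueError("stream must be nonempty")
    out: list[str] = []
    for i in range(len(stream)):
        window = stream[max(0, i - VOTE_WINDOW + 1) : i + 1]
        previous = out[-1] if out else None
        out.append(majority_vote(window, previous))
    return out


@dataclass(frozen=True)
class DecisionState:
    """State threaded through the online decision pipeline: the vote
    buffer of recent raw labels, the current run of identical voted
    results, and whether the trigger is armed for this run."""

    vote_buffer: tuple[str, ...] = ()
    last_voted: str | None = None
    consecutive_count: int = 0
    last_emitted: str | None = None
    armed: bool = True


def trigger_step(
    state: DecisionState, label: str
) -> tuple[DecisionState, str | None]:
    """Advance the consecutive-result trigger by one voted label.

    Emits ``label`` as a command exactly once when a run of five
    identical non-RELAX results completes; the run must break before
    the trigger can fire again.
    """
    if label == state.last_voted and state.consecutive_count > 0:
        count = state.consecutive_count + 1
        armed = state.armed
    else:
        count = 1
        armed = True
    command = None
    if count >= TRIGGER_RUN and armed and label != RELAX:
        command = label
        armed = False
    new_state = replace(
        state,
        last_voted=label,
        consecutive_count=count,
        armed=armed,
        last_emitted=command if command is not None else state.last_emitted,
    )
    return new_state, command


def decision_step(
    state: DecisionState, raw_label: str
) -> tuple[DecisionState, str, str | None]:
    """One online step: push a raw classification into the vote buffer,
    vote, then advance the trigger on the voted result."""
    buffer = (state.vote_buffer + (raw_label,))[-VOTE_WINDOW:]
    voted = majority_vote(list(buffer), state.last_voted)
    state = replace(state, vote_buffer=buffer)
    state, command = trigger_step(state, voted)
    return state, voted, command


@dataclass
class RecognitionTrace:
    """Per-window record of the online pipeline."""

    window_index: int
    raw_label: str
    voted_label: str
    command: str | None


def recognize_online(
    model: MLPModel,
    recording: EMGRecording,
    feature_config: FeatureConfig | None = None,
    selected: list[str] | None = None,
) -> list[RecognitionTrace]:
    """Run the full deployed pipeline over a recording: windowed
    features, feature projection, classification, voting, and the
    consecutive-result trigger.  Returns one trace row per window."""
    features = extract_features(recording, feature_config)
    if selected is not None:
        features = project_features(features, selected)
    raw = predict_batch(model, features)
    state = DecisionState()
    trace = []
    for i, raw_label in enumerate(raw):
        state, voted, command = decision_step(state, raw_label)
        trace.append(RecognitionTrace(i, raw_label, voted, command))
    return trace


def commands_from_trace(trace: list[RecognitionTrace]) -> list[str]:
    """The movement commands a trace emitted, in order."""
    return [t.command for t in trace if t.command is not None]
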