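"""Trial/frame synchronization and experimental-state labelling.

Photostimulation trials are defined by hardware trigger timestamps (onset)
plus the protocol duration (offset).  These are cross-referenced to the
imaging frame clock to (a) map trials onto frame indices and (b) build the
mask of frames contaminated by the photostimulation artifact.  Every trial is
then labelled with its experimental state relative to the convulsant
injection and the LFP-marked seizure intervals:

``baseline``
    before the convulsant (4-AP) injection;
``ictal``
    trial onset inside a seizure interval;
``excluded``
    trial onset within a guard band (default 0.5 s) of a seizure onset or
    offset, where the state is ambiguous;
``interictal``
    everything else after the injection, with ``preictal`` (within 30 s
    before a seizure onset) and ``postictal`` (within 30 s after a seizure
    offset) exposed as sub-labels of interictal, not separate states.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SeizureSet",
    "map_trials_to_frames",
    "classify_trial_state",
    "classify_trials",
]

STATES = ("baseline", "interictal", "ictal", "excluded")


@dataclass
class SeizureSet:
    """Seizure intervals plus per-trial wavefront annotations.

    ``table`` has columns ``seizure_id, onset, offset``; an onset of NaN marks
    a seizure already ongoing at recording start (no onset was defined).
    ``fronts`` maps trial_id -> :class:`~penumbra.wavefront.FrontLine` for the
    ictal trials whose wavefront was annotated.
    """

    table: pd.DataFrame
    fronts: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        for col in ("seizure_id", "onset", "offset"):
            if col not in t.columns:
                raise ValueError(f"seizure table missing column {col!r}")
        onset = t["onset"].to_numpy(float)
        offset = t["offset"].to_numpy(float)
        if np.any(onset[np.isfinite(onset)] >= offset[np.isfinite(onset)]):
            raise ValueError("seizure onset must precede offset")
        # non-overlap (treat undefined onsets as starting at -inf)
        start = np.where(np.isfinite(onset), onset, -np.inf)
        order = np.argsort(start)
        if np.any(start[order][1:] < offset[order][:-1]):
            raise ValueError("seizure intervals overlap")

    @property
    def onsets(self) -> np.ndarray:
        return self.table["onset"].to_numpy(float)

    @property
    def offsets(self) -> np.ndarray:
        return self.table["offset"].to_numpy(float)

    def __len__(self) -> int:
        return len(self.table)


def map_trials_to_frames(trials: pd.DataFrame, frame_clock) -> tuple[pd.DataFrame, np.ndarray]:
    """Map trial onset/offset times onto imaging frame indices.

    ``frame_clock`` is the strictly increasing array of frame timestamps
    (exposure start, seconds).  Returns a copy of the trial table with
    ``onset_frame``/``offset_frame`` columns plus the boolean mask of excluded
    frames: every frame whose timestamp lies in [onset, offset] of any trial
    (the photostimulation artifact window) is flagged.
    """
    t = np.asarray(frame_clock, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise ValueError("frame clock must be a strictly increasing 1-d array")
    out = trials.copy()
    excluded = np.zeros(t.size, dtype=bool)
    onset_frames = np.empty(len(out), dtype=int)
    offset_frames = np.empty(len(out), dtype=int)
    for i, (onset, offset) in enumerate(zip(out["onset"], out["offset"])):
        if not onset < offset:
            raise ValueError("trial onset must precede offset")
        if offset < t[0] or onset > t[-1]:
            raise ValueError(f"trial [{onset}, {offset}] lies outside the recording span")
        lo = int(np.searchsorted(t, onset, side="left"))
        hi = int(np.searchsorted(t, offset, side="right"))  # frames with time <= offset
        excluded[lo:hi] = True
        onset_frames[i] = min(lo, t.size - 1)
        offset_frames[i] = max(hi - 1, lo)
    out["onset_frame"] = onset_frames
    out["offset_frame"] = offset_frames
    return out, excluded


def classify_trial_state(
    trial_onset: float,
    seizures: SeizureSet,
    pre_window: float = 30.0,
    post_window: float = 30.0,
    guard: float = 0.5,
    session_phase: str = "post_drug",
) -> tuple[str, bool, bool]:
    """State of a single trial: ``(state, preictal, postictal)``.

    ``preictal``/``postictal`` are sub-labels of ``interictal`` and are False
    for any other primary state.  Guard-band exclusion takes precedence over
    every other post-injection label.
    """
    if session_phase not in ("pre_drug", "post_drug"):
        raise ValueError("session_phase must be 'pre_drug' or 'post_drug'")
    if session_phase == "pre_drug":
        return "baseline", False, False
    t = float(trial_onset)
    onsets, offsets = seizures.onsets, seizures.offsets
    boundaries = np.concatenate([onsets[np.isfinite(onsets)], offsets])
    if boundaries.size and np.min(np.abs(boundaries - t)) <= guard:
        return "excluded", False, False
    start = np.where(np.isfinite(onsets), onsets, -np.inf)
    if np.any((t >= start) & (t <= offsets)):
        return "ictal", False, False
    pre = bool(np.any((onsets - t > 0) & (onsets - t <= pre_window)))
    post = bool(np.any((t - offsets > 0) & (t - offsets <= post_window)))
    return "interictal", pre, post


def classify_trials(
    trials: pd.DataFrame,
    seizures: SeizureSet,
    injection_time: float | None = None,
    pre_window: float = 30.0,
    post_window: float = 30.0,
    guard: float = 0.5,
) -> pd.DataFrame:
    """Label every trial in a table; see :func:`classify_trial_state`.

    Trials with onset before ``injection_time`` (if given) are ``baseline``.
    Adds ``state``, ``preictal`` and ``postictal`` columns.
    """
    out = trials.copy()
    states, pres, posts = [], [], []
    for onset in out["onset"]:
        phase = "pre_drug" if injection_time is not None and onset < injection_time else "post_drug"
        s, a, b = classify_trial_state(
            onset, seizures, pre_window=pre_window, post_window=post_window,
            guard=guard, session_phase=phase,
        )
        states.append(s)
        pres.append(a)
        posts.append(b)
    out["state"] = states
    out["preictal"] = pres
    out["postictal"] = posts
    return out
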