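"""Photostimulation response quantification.

Response magnitude is the mean post-stimulation dF/F (from photostimulation
offset to +500 ms) minus the mean pre-stimulation dF/F (from -500 ms to
photostimulation onset).  Responses are z-scored target-wise against each
neuron's distribution of baseline-state responses; trial-to-trial
variability is summarized by the coefficient of variation.  The module also
extracts target traces from rendered frame stacks (10 um diameter disks on
each holographic target coordinate), selects non-target ROIs outside a 20 um
exclusion zone around every target, and quantifies widefield responses
around the detector-shutter window.

Conventions: the sample (n-1) standard deviation is used everywhere a SD
appears; undefined quantities propagate as NaN sentinels.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .traces import RoiTable, TraceSet

__all__ = [
    "extract_target_traces",
    "response_magnitude",
    "decay_constant",
    "zscore_to_baseline",
    "response_cv",
    "select_nontargets",
    "prestim_level",
    "widefield_response",
    "response_matrix",
]


def extract_target_traces(
    frame_stack,
    target_coords,
    px_size: float,
    frame_rate: float,
    diameter: float = 10.0,
) -> TraceSet:
    """Average fluorescence inside a disk on each holographic target.

    ``target_coords`` is (n, 2) in um; each trace is the per-frame mean over
    pixels whose centres fall within ``diameter``/2 of the coordinate.
    """
    stack = np.asarray(frame_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("frame_stack must be (frames, h, w)")
    coords = np.atleast_2d(np.asarray(target_coords, dtype=float))
    _, h, w = stack.shape
    xs = (np.arange(w) + 0.5) * px_size
    ys = (np.arange(h) + 0.5) * px_size
    out = np.empty((coords.shape[0], stack.shape[0]))
    for i, (cx, cy) in enumerate(coords):
        mask = np.hypot(xs[None, :] - cx, ys[:, None] - cy) <= diameter / 2.0
        if not mask.any():
            raise ValueError(f"target disk at ({cx:.1f}, {cy:.1f}) um covers no pixels")
        out[i] = stack[:, mask].mean(axis=1)
    return TraceSet(out, frame_rate=frame_rate)


def _window_mean(trace, times, lo, hi, excluded=None, closed_right=False):
    f = np.asarray(trace, dtype=float)
    t = np.asarray(times, dtype=float)
    sel = (t > lo) & (t <= hi) if closed_right else (t >= lo) & (t < hi)
    if excluded is not None:
        sel &= ~np.asarray(excluded, dtype=bool)
    if not sel.any():
        return float("nan")
    return float(f[sel].mean())


def response_magnitude(
    dff_trace,
    times,
    trial_onset: float,
    trial_offset: float,
    pre: float = 0.5,
    post: float = 0.5,
    excluded=None,
) -> float:
    """Post-stimulation minus pre-stimulation mean dF/F.

    Pre window: [onset - pre, onset); post window: (offset, offset + post].
    Frames flagged in ``excluded`` (e.g. inside any other trial) are dropped
    from the means; an empty window yields NaN.
    """
    pre_m = _window_mean(dff_trace, times, trial_onset - pre, trial_onset, excluded)
    post_m = _window_mean(dff_trace, times, trial_offset, trial_offset + post, excluded, closed_right=True)
    return post_m - pre_m


def decay_constant(
    mean_fov_trace,
    times,
    stim_end: float,
    frac: float = 0.63,
    horizon: float | None = None,
) -> float:
    """Time (s) after stimulation for the trace to fall below ``frac`` of its
    post-stimulation maximum.

    Measured on the mean-FOV fluorescence trace from ``stim_end`` onward
    (bounded by ``horizon`` seconds if given).  Trials whose trace never
    crosses (e.g. stimulation-triggered ictal events) return NaN and are
    excluded from aggregation downstream.
    """
    f = np.asarray(mean_fov_trace, dtype=float)
    t = np.asarray(times, dtype=float)
    sel = t >= stim_end
    if horizon is not None:
        sel &= t <= stim_end + horizon
    if not sel.any():
        raise ValueError("empty post-stimulation segment")
    fw, tw = f[sel], t[sel]
    peak = int(np.argmax(fw))
    thr = frac * fw[peak]
    # the signal must *decrease* below threshold, so search after the maximum
    idx = np.flatnonzero(fw[peak:] < thr)
    if idx.size == 0:
        return float("nan")
    return float(tw[peak + idx[0]] - stim_end)


def zscore_to_baseline(response, baseline_responses):
    """Z-score one or more responses against a neuron's baseline distribution.

    Uses the sample (n-1) SD of the neuron's baseline-state responses;
    requires at least two finite baseline responses with positive SD (NaN
    otherwise).
    """
    base = np.asarray(baseline_responses, dtype=float)
    base = base[np.isfinite(base)]
    r = np.asarray(response, dtype=float)
    if base.size < 2:
        return np.full_like(r, np.nan, dtype=float) if r.ndim else float("nan")
    sd = base.std(ddof=1)
    if sd == 0:
        return np.full_like(r, np.nan, dtype=float) if r.ndim else float("nan")
    z = (r - base.mean()) / sd
    return z if r.ndim else float(z)


def response_cv(responses) -> float:
    """Coefficient of variation (sample SD / mean) of response magnitudes."""
    r = np.asarray(responses, dtype=float)
    r = r[np.isfinite(r)]
    if r.size < 2 or r.mean() == 0:
        return float("nan")
    return float(r.std(ddof=1) / r.mean())


def select_nontargets(rois: RoiTable, target_coords, exclusion_radius: float = 20.0) -> pd.DataFrame:
    """Non-target ROIs outside the exclusion zone of every target.

    A circular exclusion zone of ``exclusion_radius`` um around each target
    coordinate removes ROIs that may have received off-target activation; the
    boundary is excluded (distance <= radius drops the ROI).
    """
    t = rois.table
    nt = t.loc[~t["is_target"]].copy()
    if nt.empty:
        return nt
    coords = np.atleast_2d(np.asarray(target_coords, dtype=float))
    p = nt[["x", "y"]].to_numpy(float)
    d = np.hypot(p[:, None, 0] - coords[None, :, 0], p[:, None, 1] - coords[None, :, 1])
    keep = d.min(axis=1) > exclusion_radius
    return nt.loc[keep].reset_index(drop=True)


def prestim_level(
    dff_trace,
    times,
    trial_onset: float,
    window: float = 0.5,
    window_start: float | None = None,
    excluded=None,
) -> float:
    """Mean dF/F in a window before trial onset.

    Default: the 500 ms period before each photostimulation trial.  The
    neuropil variant (0 to 250 ms before stimulation) is obtained with
    ``window=0.25``.  ``window_start`` optionally shifts the window further
    from the trial (e.g. ``window_start=-0.5, window=0.25`` for -500 to
    -250 ms).  NaN when the window is fully excluded.
    """
    start = trial_onset - window if window_start is None else trial_onset + window_start
    return _window_mean(dff_trace, times, start, start + window, excluded)


def widefield_response(
    mean_fov_trace,
    times,
    shutter_deploy: float,
    shutter_release: float,
    pre: float = 0.5,
    post: float = 0.5,
    excluded=None,
) -> float:
    """Widefield photostimulation response around the shutter window.

    Mean post-stimulation signal (0 to +``post`` s after high-speed shutter
    release) minus mean pre-stimulation signal (-``pre`` to 0 s before
    shutter deployment); frames during shutter closure carry no usable data
    and are ignored by construction of the windows.
    """
    if not shutter_deploy < shutter_release:
        raise ValueError("shutter deploy must precede release")
    pre_m = _window_mean(mean_fov_trace, times, shutter_deploy - pre, shutter_deploy, excluded)
    post_m = _window_mean(mean_fov_trace, times, shutter_release, shutter_release + post, excluded, closed_right=True)
    return post_m - pre_m


def response_matrix(
    dff,
    times,
    trials: pd.DataFrame,
    pre: float = 0.5,
    post: float = 0.5,
    excluded=None,
) -> np.ndarray:
    """(trials, neurons) matrix of response magnitudes for a dF/F matrix."""
    f = np.atleast_2d(np.asarray(dff, dtype=float))
    t = np.asarray(times, dtype=float)
    ok = None if excluded is None else ~np.asarray(excluded, dtype=bool)
    out = np.full((len(trials), f.shape[0]), np.nan)
    for i, (onset, offset) in enumerate(zip(trials["onset"], trials["offset"])):
        pre_sel = (t >= onset - pre) & (t < onset)
        post_sel = (t > offset) & (t <= offset + post)
        if ok is not None:
            pre_sel &= ok
            post_sel &= ok
        if pre_sel.any() and post_sel.any():
            out[i] = f[:, post_sel].mean(axis=1) - f[:, pre_sel].mean(axis=1)
    return out
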