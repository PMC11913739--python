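"""Trace-level quantities for ROI calcium fluorescence.

Houses the in-memory containers for ROI geometry and trace matrices plus the
per-trace operations: whole-trace dF/F normalization, annulus neuropil
extraction, deconvolved activity rate, seizure-aligned normalization,
recruitment delay (time to a stated fraction of the within-seizure maximum),
cross-correlation lag between neuron pairs, nearest-excitatory lookup and the
pixel-overlap ROI filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RoiTable",
    "TraceSet",
    "dff_normalize",
    "annulus_neuropil",
    "activity_rate",
    "align_to_seizure",
    "recruitment_delay",
    "xcorr_lag",
    "nearest_excitatory",
    "overlap_filter",
]


@dataclass
class RoiTable:
    """Per-neuron geometry and class flags.

    ``table`` columns: ``roi_id, x, y, is_target, is_inhibitory`` with
    centroids in um.  ``masks`` maps roi_id -> (rows, cols) integer pixel
    index arrays on the rendered pixel grid (may be empty when no rendered
    stack exists); ``px_size`` is the um size of one rendered pixel.
    """

    table: pd.DataFrame
    masks: dict = field(default_factory=dict)
    px_size: float = 1.0
    fov_size: tuple[float, float] = (512.0, 512.0)

    def __post_init__(self) -> None:
        required = {"roi_id", "x", "y", "is_target", "is_inhibitory"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"ROI table missing columns {sorted(missing)}")
        x = self.table["x"].to_numpy(float)
        y = self.table["y"].to_numpy(float)
        if np.any((x < 0) | (x > self.fov_size[0]) | (y < 0) | (y > self.fov_size[1])):
            raise ValueError("ROI centroid outside the field of view")
        for rid, (rr, cc) in self.masks.items():
            if len(rr) == 0:
                raise ValueError(f"ROI {rid} has an empty pixel mask")

    @property
    def centroids(self) -> np.ndarray:
        return self.table[["x", "y"]].to_numpy(float)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class TraceSet:
    """Fluorescence (and optional deconvolved) matrices with a timebase.

    ``fluorescence`` is (neurons, frames) in arbitrary units; ``deconvolved``
    (optional, same shape) is the event-like deconvolved activity signal;
    ``excluded_frames`` marks frames contaminated by the photostimulation
    artifact (and, in downstream dF/F normalization, ictal frames).
    """

    fluorescence: np.ndarray
    frame_rate: float
    deconvolved: np.ndarray | None = None
    excluded_frames: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, dtype=float)
        if self.fluorescence.ndim != 2:
            raise ValueError("fluorescence must be (neurons, frames)")
        if not self.frame_rate > 0:
            raise ValueError("frame_rate must be positive")
        if self.deconvolved is not None:
            self.deconvolved = np.asarray(self.deconvolved, dtype=float)
            if self.deconvolved.shape != self.fluorescence.shape:
                raise ValueError("deconvolved shape mismatch")
        if self.excluded_frames is None:
            self.excluded_frames = np.zeros(self.fluorescence.shape[1], dtype=bool)
        else:
            self.excluded_frames = np.asarray(self.excluded_frames, dtype=bool)
            if self.excluded_frames.shape != (self.fluorescence.shape[1],):
                raise ValueError("excluded_frames shape mismatch")

    @property
    def n_neurons(self) -> int:
        return self.fluorescence.shape[0]

    @property
    def n_frames(self) -> int:
        return self.fluorescence.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        """Frame timestamps (exposure start), seconds."""
        return np.arange(self.n_frames) / self.frame_rate


def dff_normalize(trace, excluded_frames=None):
    """Whole-trace dF/F: (F - m) / m with m the mean over non-excluded frames.

    The mean is computed with photostimulation-artifact and ictal frames
    removed (the caller supplies the union as ``excluded_frames``); the
    excluded frames themselves are still transformed.  Works on a single
    trace or a (neurons, frames) matrix (per-row mean).  Raises ``ValueError``
    when the included-frame mean of any trace is non-positive.
    """
    f = np.asarray(trace, dtype=float)
    one_d = f.ndim == 1
    f2 = np.atleast_2d(f)
    if excluded_frames is None:
        included = np.ones(f2.shape[1], dtype=bool)
    else:
        included = ~np.asarray(excluded_frames, dtype=bool)
        if included.shape != (f2.shape[1],):
            raise ValueError("excluded_frames shape mismatch")
        if not included.any():
            raise ValueError("all frames excluded from the dF/F mean")
    m = f2[:, included].mean(axis=1)
    bad = np.flatnonzero(m <= 0)
    if bad.size:
        raise ValueError(f"non-positive included-frame mean for trace rows {bad.tolist()}")
    out = (f2 - m[:, None]) / m[:, None]
    return out[0] if one_d else out


def annulus_neuropil(
    frame_stack,
    center,
    px_size: float,
    r_in: float = 20.0,
    r_out: float = 100.0,
    exclusion_masks=(),
) -> np.ndarray:
    """Per-frame mean intensity over an annulus around ``center``.

    The annulus (inner radius ``r_in``, outer radius ``r_out``, um) collects
    the local neuropil signal around a neuron; pixels belonging to other
    labelled somata are removed via ``exclusion_masks`` (an iterable of
    ``(rows, cols)`` index pairs or boolean images).  A pixel belongs to the
    annulus iff its centre lies in [r_in, r_out).
    """
    stack = np.asarray(frame_stack, dtype=float)
    if stack.ndim != 3:
        raise ValueError("frame_stack must be (frames, h, w)")
    _, h, w = stack.shape
    cx, cy = float(center[0]), float(center[1])
    xs = (np.arange(w) + 0.5) * px_size
    ys = (np.arange(h) + 0.5) * px_size
    rr = np.hypot(xs[None, :] - cx, ys[:, None] - cy)
    mask = (rr >= r_in) & (rr < r_out)
    for ex in exclusion_masks:
        if isinstance(ex, np.ndarray) and ex.dtype == bool:
            mask &= ~ex
        else:
            rows, cols = ex
            drop = np.zeros((h, w), dtype=bool)
            drop[rows, cols] = True
            mask &= ~drop
    if not mask.any():
        raise ValueError("annulus contains no pixels after exclusions")
    return stack[:, mask].mean(axis=1)


def activity_rate(deconvolved_trace, frame_rate: float) -> float:
    """Area under the deconvolved signal divided by the recording length.

    Rectangle-rule integral (sum x frame period) over total duration, i.e.
    the mean deconvolved amplitude per second of recording scaled by the
    sample spacing; units are a.u. of the deconvolved signal per second.
    """
    v = np.asarray(deconvolved_trace, dtype=float)
    if v.size == 0:
        raise ValueError("empty trace")
    if not np.all(np.isfinite(v)) or np.any(v < 0):
        raise ValueError("deconvolved trace must be finite and non-negative")
    dt = 1.0 / frame_rate
    return float(v.sum() * dt / (v.size * dt))


def align_to_seizure(
    dff,
    times,
    seizure_onset: float,
    base_window: tuple[float, float] = (-1.5, -0.5),
    excluded_frames=None,
):
    """Subtract the pre-onset baseline from a dF/F trace.

    The baseline is the mean over ``base_window`` (seconds relative to
    seizure onset, default the 1.5-0.5 s period before onset).  Works on one
    trace or a (neurons, frames) matrix.
    """
    f = np.asarray(dff, dtype=float)
    t = np.asarray(times, dtype=float)
    one_d = f.ndim == 1
    f2 = np.atleast_2d(f)
    rel = t - seizure_onset
    sel = (rel >= base_window[0]) & (rel < base_window[1])
    if excluded_frames is not None:
        sel &= ~np.asarray(excluded_frames, dtype=bool)
    if not sel.any():
        raise ValueError("baseline window contains no usable frames")
    out = f2 - f2[:, sel].mean(axis=1)[:, None]
    return out[0] if one_d else out


def recruitment_delay(
    aligned_trace,
    times,
    seizure_onset: float,
    seizure_offset: float,
    frac: float,
) -> float:
    """Delay (s) after seizure onset to reach ``frac`` of the seizure maximum.

    ``frac`` is a required parameter (0.65 was used for the interneuron
    recruitment analysis, 0.85 for the recruitment-ordering display); the
    first frame at-or-above threshold defines the crossing (frame-resolution
    output, no sub-frame interpolation).  Returns NaN when the trace never
    crosses or has no positive excursion.
    """
    f = np.asarray(aligned_trace, dtype=float)
    t = np.asarray(times, dtype=float)
    sel = (t >= seizure_onset) & (t <= seizure_offset)
    if not sel.any():
        raise ValueError("seizure window contains no frames")
    fw, tw = f[sel], t[sel]
    mx = fw.max()
    if not np.isfinite(mx) or mx <= 0:
        return float("nan")
    idx = np.flatnonzero(fw >= frac * mx)
    if idx.size == 0:
        return float("nan")
    return float(tw[idx[0]] - seizure_onset)


def xcorr_lag(
    trace_a,
    trace_b,
    frame_rate: float,
    max_lag: float = 2.0,
) -> float:
    """Signed lag (s) maximizing the Pearson cross-correlation of two traces.

    Positive lag means ``trace_b`` lags ``trace_a``.  Correlations are
    Pearson-normalized on the overlapping segment at each integer-frame lag;
    ties break toward the smaller absolute lag.  Returns NaN when either
    windowed trace has zero variance.
    """
    a = np.asarray(trace_a, dtype=float)
    b = np.asarray(trace_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be 1-d and equally long")
    kmax = int(round(max_lag * frame_rate))
    if a.size <= 2 * kmax:
        raise ValueError("window must be longer than twice the maximum lag")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    lags = np.arange(-kmax, kmax + 1)
    best_r, best_k = -np.inf, 0
    for k in lags[np.argsort(np.abs(lags), kind="stable")]:
        if k >= 0:
            x, y = a[: a.size - k], b[k:]
        else:
            x, y = a[-k:], b[: b.size + k]
        if x.std() == 0 or y.std() == 0:
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r > best_r + 1e-12:
            best_r, best_k = r, int(k)
    if not np.isfinite(best_r):
        return float("nan")
    return best_k / frame_rate


def nearest_excitatory(inh_roi_id, rois: RoiTable, radius: float = 100.0):
    """Nearest putatively-excitatory ROI within ``radius`` um, or ``None``."""
    t = rois.table
    row = t.loc[t["roi_id"] == inh_roi_id]
    if row.empty:
        raise KeyError(f"no ROI with id {inh_roi_id!r}")
    p = row[["x", "y"]].to_numpy(float)[0]
    cand = t.loc[~t["is_inhibitory"] & (t["roi_id"] != inh_roi_id)]
    if cand.empty:
        return None
    d = np.hypot(cand["x"].to_numpy(float) - p[0], cand["y"].to_numpy(float) - p[1])
    i = int(np.argmin(d))
    if d[i] > radius:
        return None
    return cand["roi_id"].iloc[i]


def overlap_filter(rois: RoiTable, threshold: float = 0.05) -> RoiTable:
    """Drop putatively-excitatory ROIs overlapping inhibitory somata.

    An excitatory ROI is excluded when more than ``threshold`` (default 5%)
    of its pixels are shared with any inhibitory ROI mask; inhibitory ROIs
    are always retained.  Requires pixel masks.
    """
    t = rois.table
    if not rois.masks:
        raise ValueError("overlap_filter requires pixel masks")
    inh_ids = t.loc[t["is_inhibitory"], "roi_id"]
    inh_pixels = set()
    for rid in inh_ids:
        rr, cc = rois.masks[rid]
        inh_pixels.update(zip(rr.tolist(), cc.tolist()))
    keep = []
    for _, row in t.iterrows():
        rid = row["roi_id"]
        if row["is_inhibitory"]:
            keep.append(True)
            continue
        rr, cc = rois.masks[rid]
        pix = set(zip(rr.tolist(), cc.tolist()))
        frac = len(pix & inh_pixels) / len(pix)
        keep.append(frac <= threshold)
    keep = np.asarray(keep, dtype=bool)
    new_table = t.loc[keep].reset_index(drop=True)
    new_masks = {rid: rois.masks[rid] for rid in new_table["roi_id"]}
    return RoiTable(new_table, new_masks, rois.px_size, rois.fov_size)
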