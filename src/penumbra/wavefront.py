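"""Seizure-wavefront geometry and distance-resolved excitability profiles.

The propagating boundary between the recruited seizure core and the
not-yet-recruited penumbra is approximated by a straight line drawn across
the field of view (two annotated coordinates at least 100 um apart).  This
module computes signed shortest distances of neurons to that line, classifies
neurons as proximal / distal to the front, builds rolling distance-binned
profiles of any per-measurement quantity, and estimates the per-neuron
seizure-invasion time from the raw fluorescence trace.

Sign convention: distances are positive on the penumbral (not-yet-recruited)
side of the front, negative inside the seizure core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "FrontLine",
    "distance_to_front",
    "classify_proximal_distal",
    "rolling_profile",
    "trial_frame_average",
    "invasion_time",
]

#: minimum separation of the two annotated coordinates (um)
MIN_POINT_SEPARATION = 100.0


@dataclass(frozen=True)
class FrontLine:
    """A linear approximation of the seizure wavefront.

    Parameters
    ----------
    p1, p2:
        Two points (x, y) in um on the front, at least 100 um apart.
    penumbra_side:
        A reference point (x, y) in um on the not-yet-recruited side of the
        line; distances to points on the same side as this reference are
        reported positive.
    """

    p1: tuple[float, float]
    p2: tuple[float, float]
    penumbra_side: tuple[float, float]

    def __post_init__(self) -> None:
        p1 = np.asarray(self.p1, dtype=float)
        p2 = np.asarray(self.p2, dtype=float)
        ref = np.asarray(self.penumbra_side, dtype=float)
        sep = float(np.hypot(*(p2 - p1)))
        if sep == 0.0:
            raise ValueError("degenerate front line: p1 == p2")
        if sep < MIN_POINT_SEPARATION:
            raise ValueError(
                f"front-line points are {sep:.1f} um apart; "
                f"at least {MIN_POINT_SEPARATION:.0f} um required"
            )
        # the reference must determine a side unambiguously
        if abs(_signed_offset(ref, p1, p2)) <= 1e-9:
            raise ValueError("penumbra_side reference point lies on the front line")

    @property
    def unit_normal(self) -> np.ndarray:
        """Unit normal pointing toward the penumbral side."""
        p1 = np.asarray(self.p1, float)
        p2 = np.asarray(self.p2, float)
        d = p2 - p1
        n = np.array([-d[1], d[0]]) / np.hypot(*d)
        ref = np.asarray(self.penumbra_side, float)
        if np.dot(ref - p1, n) < 0:
            n = -n
        return n


def _signed_offset(point: np.ndarray, p1: np.ndarray, p2: np.ndarray) -> float:
    d = p2 - p1
    n = np.array([-d[1], d[0]]) / np.hypot(*d)
    return float(np.dot(np.asarray(point, float) - p1, n))


def distance_to_front(point, front: FrontLine):
    """Signed perpendicular distance (um) from ``point`` to the front line.

    ``point`` may be a single (x, y) pair or an (n, 2) array.  Distances are
    measured to the infinite line through the two annotated coordinates (the
    annotation is drawn across the whole image), positive on the penumbral
    side.
    """
    pts = np.atleast_2d(np.asarray(point, dtype=float))
    if pts.shape[-1] != 2:
        raise ValueError("points must be (x, y) pairs")
    p1 = np.asarray(front.p1, float)
    n = front.unit_normal
    d = (pts - p1) @ n
    return float(d[0]) if np.ndim(point) == 1 else d


def classify_proximal_distal(distance) -> np.ndarray | str:
    """Classify signed distances into ``proximal`` / ``intermediate`` / ``distal``.

    Proximal: 0 <= d < 100 um ahead of the front; distal: d > 200 um; anything
    else (including points inside the core, d < 0) is intermediate.
    """
    d = np.asarray(distance, dtype=float)
    out = np.where(d > 200.0, "distal", np.where((d >= 0.0) & (d < 100.0), "proximal", "intermediate"))
    return str(out) if np.ndim(distance) == 0 else out


def rolling_profile(
    values,
    distances,
    bin_width: float = 40.0,
    step: float = 5.0,
    n_min: int = 5,
    ci: float = 0.95,
    centers=None,
) -> pd.DataFrame:
    """Sliding-window distance profile of ``values``.

    Each output row is a bin of width ``bin_width`` centred on a grid of
    spacing ``step`` spanning the data; a row reports the mean, a t-based
    confidence interval and the number of measurements in the window.  Bins
    with fewer than ``n_min`` measurements are suppressed.

    Returns a DataFrame with columns ``center, mean, ci_low, ci_high, n``.
    """
    v = np.asarray(values, dtype=float)
    d = np.asarray(distances, dtype=float)
    if v.shape != d.shape:
        raise ValueError("values and distances must be aligned")
    ok = np.isfinite(v) & np.isfinite(d)
    v, d = v[ok], d[ok]
    cols = ["center", "mean", "ci_low", "ci_high", "n"]
    if v.size == 0:
        return pd.DataFrame(columns=cols)
    if centers is None:
        lo = step * np.floor(d.min() / step)
        hi = step * np.ceil(d.max() / step)
        centers = np.arange(lo, hi + step / 2, step)
    rows = []
    half = bin_width / 2.0
    for c in np.asarray(centers, dtype=float):
        sel = (d >= c - half) & (d < c + half)
        n = int(sel.sum())
        if n < n_min:
            continue
        m = float(v[sel].mean())
        if n > 1 and v[sel].std(ddof=1) > 0:
            sem = v[sel].std(ddof=1) / np.sqrt(n)
            tcrit = stats.t.ppf(0.5 + ci / 2.0, df=n - 1)
            lo_ci, hi_ci = m - tcrit * sem, m + tcrit * sem
        else:
            lo_ci = hi_ci = m
        rows.append((float(c), m, lo_ci, hi_ci, n))
    return pd.DataFrame(rows, columns=cols)


def trial_frame_average(frame_stack, center_frame: int, n_frames: int = 100) -> np.ndarray:
    """Pixel-wise mean of ``n_frames`` centred on ``center_frame``.

    Windows extending beyond the recording are clipped with a warning.  The
    averaged image is the low-noise view used to annotate the wavefront.
    """
    stack = np.asarray(frame_stack)
    if stack.ndim != 3:
        raise ValueError("frame_stack must be (frames, h, w)")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    lo = center_frame - n_frames // 2
    hi = lo + n_frames
    if lo < 0 or hi > stack.shape[0]:
        warnings.warn("trial frame-average window clipped at recording edge", stacklevel=2)
        lo, hi = max(lo, 0), min(hi, stack.shape[0])
    if hi <= lo:
        raise ValueError("window does not intersect the recording")
    return stack[lo:hi].mean(axis=0)


def invasion_time(
    raw_trace,
    times,
    seizure_onset: float,
    seizure_offset: float,
    smooth_window: int = 3,
) -> float:
    """Time of seizure invasion of one neuron, in seconds.

    Marks the initiation of the greatest upward deflection of the raw
    fluorescence trace that leads to the within-seizure maximum,
    operationalised as the last local minimum (after light boxcar smoothing)
    preceding the argmax of the trace inside [onset, offset].  Returns NaN for
    a flat trace.
    """
    f = np.asarray(raw_trace, dtype=float)
    t = np.asarray(times, dtype=float)
    sel = (t >= seizure_onset) & (t <= seizure_offset)
    if not sel.any():
        raise ValueError("seizure window contains no frames")
    fw, tw = f[sel], t[sel]
    if np.ptp(fw) == 0.0:
        return float("nan")
    if smooth_window > 1:
        k = np.ones(smooth_window) / smooth_window
        fw = np.convolve(fw, k, mode="same")
    imax = int(np.argmax(fw))
    if imax == 0:
        return float(tw[0])
    seg = fw[: imax + 1]
    # last index i with seg[i-1] >= seg[i] <= seg[i+1] (start of the final rise)
    rising = np.diff(seg) > 0
    # walk back from the peak while strictly rising
    i = imax
    while i > 0 and rising[i - 1]:
        i -= 1
    return float(tw[i])
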