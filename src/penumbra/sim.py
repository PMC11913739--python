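"""Synthetic all-optical seizure-propagation experiments with ground truth.

The simulator generates a complete experiment — ROI table, fluorescence
traces, photostimulation trial table, seizure intervals with per-trial
wavefront annotations, and an LFP proxy — whose statistical structure
matches what the analysis assumes:

* GCaMP-like spontaneous transients (Poisson events convolved with an
  exponential decay kernel) on a per-neuron baseline fluorescence;
* seizures that sweep the field of view as a straight wavefront of constant
  speed: each neuron is recruited when the front reaches it (a fast
  sigmoidal rise to a large plateau that decays slowly, with spontaneous
  transients suppressed while recruited — indicator saturation);
* periodic photostimulation trials whose evoked amplitude on targeted
  neurons is the interictal gain multiplied by a piecewise function of the
  signed distance to the wavefront (suppressed just ahead of the front,
  enhanced far into the penumbra, near-zero in the core);
* distance-dependent coupling from targets onto non-targets (excitatory
  within 25 um, weakly inhibitory out to 200 um);
* a shared multiplicative per-trial fluctuation of all evoked amplitudes
  (correlated trial-to-trial excitability);
* post-ictal suppression of the fluorescence signal;
* optionally, stimulation-triggered seizures (a trial ignites a seizure with
  probability ``trigger_prob`` shortly after stimulus offset).

Every random draw comes from one seeded generator, so a fixed seed gives
bit-identical output.  The ground truth (recruitment times, applied gains,
coupling matrix, triggered trials) is returned for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve
from scipy.special import expit

from .timebase import SeizureSet
from .traces import RoiTable, TraceSet
from .wavefront import FrontLine

__all__ = [
    "SimConfig",
    "SeizureEvent",
    "GroundTruth",
    "default_front_gain",
    "default_coupling_kernel",
    "simulate",
    "front_line_at",
    "render_frames",
]


def default_front_gain(d):
    """Gain multiplier vs signed distance to the wavefront (um).

    Suppressed just ahead of the front (0 <= d < 100: x0.3), unchanged at
    intermediate penumbral distance (100 <= d <= 200: x1.0), enhanced far
    into the penumbra (d > 200: x1.5), nearly abolished in the core
    (d < 0: x0.1).
    """
    d = np.asarray(d, dtype=float)
    out = np.where(d < 0, 0.1, np.where(d < 100, 0.3, np.where(d <= 200, 1.0, 1.5)))
    return float(out) if out.ndim == 0 else out


def default_coupling_kernel(r):
    """Signed target->non-target coupling weight vs pair distance (um).

    Strong excitation within 25 um (+0.60) and weak, spatially distributed
    suppression out to 200 um (-0.03), zero beyond: local excitation with a
    broad inhibitory surround.  The magnitudes are asymmetric because dozens
    of targets are stimulated at once: each non-target sums the weights of
    ~20 targets in its 25-200 um surround but rarely more than one inside
    25 um, so equal magnitudes would produce unphysically large net
    suppression; the strong local weight keeps the excitatory component
    detectable through the 20 um target-exclusion zone applied in analysis
    (only the 20-25 um shell of positive pairs survives it).
    """
    r = np.asarray(r, dtype=float)
    out = np.where(r < 25, 0.60, np.where(r <= 200, -0.03, 0.0))
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic experiment (um, s, Hz, dF/F units)."""

    fov_size: tuple[float, float] = (512.0, 512.0)
    n_neurons: int = 100
    frac_targets: float = 0.4
    frac_inhibitory: float = 0.1
    frame_rate: float = 10.0
    duration: float = 600.0
    injection_time: float = 150.0
    # spontaneous transients
    transient_rate: float = 0.08
    transient_amp: float = 0.5
    transient_tau: float = 1.0
    noise_sd: float = 0.05
    baseline_fluorescence: tuple[float, float] = (80.0, 120.0)
    # seizures
    seizure_times: tuple[float, ...] = (200.0, 320.0, 440.0)
    seizure_duration: float = 30.0
    wavefront_speed: float = 25.0
    wavefront_direction: tuple[float, float] = (1.0, 0.0)
    seizure_plateau_amp: float = 3.0
    seizure_rise_tau: float = 0.1
    seizure_fall_tau: float = 2.0
    plateau_decay_tau: float = 20.0
    postictal_suppression: float = 0.6
    postictal_window: float = 30.0
    # photostimulation
    first_stim: float = 10.0
    stim_period: float | None = 10.0
    stim_duration: float = 0.25
    stim_gain_interictal: float = 0.21
    gain_vs_front_distance: callable = default_front_gain
    coupling_kernel: callable = default_coupling_kernel
    shared_fluctuation_sd: float = 0.2
    trigger_prob: float = 0.0
    trigger_jitter: float = 0.2
    # geometry / misc
    roi_radius: float = 5.0
    px_size: float = 4.0
    ictal_deconv_level: float = 1.0
    seed: int = 0

    def validate(self) -> None:
        if not (0 <= self.frac_targets <= 1 and 0 <= self.frac_inhibitory <= 1):
            raise ValueError("fractions must lie in [0, 1]")
        if self.frame_rate <= 0:
            raise ValueError("frame_rate must be positive")
        if self.wavefront_speed <= 0:
            raise ValueError("wavefront_speed must be positive")
        if not 0 < self.postictal_suppression <= 1:
            raise ValueError("postictal_suppression must be in (0, 1]")
        if np.hypot(*self.wavefront_direction) == 0:
            raise ValueError("wavefront_direction must be a non-zero vector")
        if not 0 <= self.trigger_prob <= 1:
            raise ValueError("trigger_prob must be a probability")
        ivals = sorted((t, t + self.seizure_duration) for t in self.seizure_times)
        for (a0, a1), (b0, _) in zip(ivals[:-1], ivals[1:]):
            if b0 < a1:
                raise ValueError("scheduled seizure intervals overlap")
        for t in self.seizure_times:
            if t < self.injection_time:
                raise ValueError("seizures cannot precede the convulsant injection")

    @property
    def direction(self) -> np.ndarray:
        u = np.asarray(self.wavefront_direction, dtype=float)
        return u / np.hypot(*u)


@dataclass(frozen=True)
class SeizureEvent:
    """One simulated seizure: interval plus onset-line anchor point (um)."""

    seizure_id: int
    onset: float
    offset: float
    anchor: tuple[float, float]


@dataclass
class GroundTruth:
    """The simulator's recovery targets."""

    seizures: list
    #: perpendicular distance of each neuron from the onset line (um)
    onset_distance: np.ndarray
    #: (seizures, neurons) recruitment times, onset + d / speed
    recruitment_time: np.ndarray
    #: (seizures, neurons) True where the front reached the neuron in time
    recruited: np.ndarray
    #: (trials, targets) gain multiplier applied on each trial
    gains: np.ndarray
    #: (trials, neurons) signed distance to the front at trial onset (NaN outside seizures)
    front_distance: np.ndarray
    #: (targets, nontargets) coupling weights
    coupling: np.ndarray
    target_ids: np.ndarray
    nontarget_ids: np.ndarray
    #: trial ids whose stimulation ignited a seizure
    triggered_trials: list
    #: per-trial shared excitability fluctuation epsilon_t
    shared_fluctuation: np.ndarray


def front_line_at(seizure: SeizureEvent, t: float, config: SimConfig, half_length: float = 200.0) -> FrontLine:
    """The wavefront line of ``seizure`` at time ``t``.

    The line is perpendicular to the propagation direction, displaced
    ``speed * (t - onset)`` from the onset line; the two returned points are
    2 * ``half_length`` apart (>= 100 um, mirroring the annotation rule) and
    the penumbral reference point lies ahead of the front.
    """
    if not seizure.onset <= t <= seizure.offset:
        raise ValueError("time outside the seizure interval")
    u = config.direction
    perp = np.array([-u[1], u[0]])
    q = np.asarray(seizure.anchor, dtype=float) + u * config.wavefront_speed * (t - seizure.onset)
    p1 = q + perp * half_length
    p2 = q - perp * half_length
    ref = q + u * 50.0
    return FrontLine(tuple(p1), tuple(p2), tuple(ref))


def _fov_anchor(config: SimConfig) -> np.ndarray:
    """FOV corner with the smallest projection on the propagation direction.

    The onset line passes through this corner, so every neuron starts on the
    penumbral (positive-distance) side.
    """
    u = config.direction
    w, h = config.fov_size
    corners = np.array([[0, 0], [w, 0], [0, h], [w, h]], dtype=float)
    return corners[np.argmin(corners @ u)]


def _disk_indices(cx, cy, radius, px_size, shape):
    r_px = max(int(np.ceil(radius / px_size)), 1)
    ci, cj = int(cy / px_size), int(cx / px_size)
    ii, jj = np.mgrid[ci - r_px : ci + r_px + 1, cj - r_px : cj + r_px + 1]
    xs = (jj + 0.5) * px_size
    ys = (ii + 0.5) * px_size
    keep = (np.hypot(xs - cx, ys - cy) <= radius) & (ii >= 0) & (jj >= 0) & (ii < shape[0]) & (jj < shape[1])
    return ii[keep].astype(np.intp), jj[keep].astype(np.intp)


def _build_trials(config: SimConfig) -> pd.DataFrame:
    rows = []
    if config.stim_period is not None:
        t = config.first_stim
        k = 0
        while t + config.stim_duration + 1.0 < config.duration:
            rows.append({"trial_id": k, "onset": t, "offset": t + config.stim_duration, "modality": "twophoton"})
            t += config.stim_period
            k += 1
    return pd.DataFrame(rows, columns=["trial_id", "onset", "offset", "modality"])


def simulate(config: SimConfig):
    """Generate one synthetic experiment.

    Returns ``(rois, traces, trials, seizures, lfp, ground_truth)``; see the
    module docstring for the generative model.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    fr = config.frame_rate
    n = config.n_neurons
    n_frames = int(round(config.duration * fr))
    times = np.arange(n_frames) / fr
    u = config.direction

    # --- ROI geometry -----------------------------------------------------
    margin = config.roi_radius + 2.0
    xy = np.column_stack(
        [
            rng.uniform(margin, config.fov_size[0] - margin, n),
            rng.uniform(margin, config.fov_size[1] - margin, n),
        ]
    )
    n_targets = int(round(config.frac_targets * n))
    n_inh = int(round(config.frac_inhibitory * n))
    order = rng.permutation(n)
    target_ids = np.sort(order[:n_targets])
    # inhibitory neurons are never photostimulation targets (the opsin is
    # expressed under an excitatory promoter)
    inh_ids = np.sort(order[n_targets : n_targets + n_inh])
    is_target = np.zeros(n, dtype=bool)
    is_target[target_ids] = True
    is_inh = np.zeros(n, dtype=bool)
    is_inh[inh_ids] = True
    shape = (
        int(np.ceil(config.fov_size[1] / config.px_size)),
        int(np.ceil(config.fov_size[0] / config.px_size)),
    )
    masks = {
        i: _disk_indices(xy[i, 0], xy[i, 1], config.roi_radius, config.px_size, shape)
        for i in range(n)
    }
    roi_table = pd.DataFrame(
        {
            "roi_id": np.arange(n),
            "x": xy[:, 0],
            "y": xy[:, 1],
            "is_target": is_target,
            "is_inhibitory": is_inh,
        }
    )
    rois = RoiTable(roi_table, masks, config.px_size, config.fov_size)
    f0 = rng.uniform(*config.baseline_fluorescence, n)

    # --- trials and seizures ---------------------------------------------
    trials = _build_trials(config)
    seizure_list = [(float(t), float(t) + config.seizure_duration) for t in config.seizure_times]
    triggered: list[int] = []
    if config.trigger_prob > 0 and len(trials):
        for _, tr in trials.iterrows():
            t_on = tr["onset"]
            if t_on < config.injection_time:
                continue
            inside = any(a <= t_on <= b for a, b in seizure_list)
            if inside:
                continue
            if rng.random() < config.trigger_prob:
                onset = float(tr["offset"] + rng.uniform(0.0, config.trigger_jitter))
                offset = onset + config.seizure_duration
                if offset > config.duration:
                    continue
                if any(onset < b and offset > a for a, b in seizure_list):
                    continue
                seizure_list.append((onset, offset))
                triggered.append(int(tr["trial_id"]))
        seizure_list.sort()
    anchor = _fov_anchor(config)
    seizures = [
        SeizureEvent(s, onset, offset, tuple(anchor)) for s, (onset, offset) in enumerate(seizure_list)
    ]
    sz_table = pd.DataFrame(
        {
            "seizure_id": [s.seizure_id for s in seizures],
            "onset": [s.onset for s in seizures],
            "offset": [s.offset for s in seizures],
        }
    )

    # --- recruitment geometry --------------------------------------------
    d_onset = (xy - anchor) @ u  # perpendicular distance from onset line, >= 0
    n_sz = len(seizures)
    rec_time = np.empty((n_sz, n))
    recruited = np.zeros((n_sz, n), dtype=bool)
    for s, ev in enumerate(seizures):
        rec_time[s] = ev.onset + d_onset / config.wavefront_speed
        recruited[s] = rec_time[s] <= ev.offset

    # --- spontaneous transient impulses ----------------------------------
    impulses = config.transient_amp * rng.poisson(config.transient_rate / fr, (n, n_frames)).astype(float)
    deconv = impulses.copy()
    for s, ev in enumerate(seizures):
        lo = int(np.searchsorted(times, ev.onset))
        hi = int(np.searchsorted(times, ev.offset, side="right"))
        slab = times[lo:hi][None, :] >= rec_time[s][:, None]
        slab &= recruited[s][:, None]
        impulses[:, lo:hi][slab] = 0.0  # indicator saturation while recruited
        deconv[:, lo:hi][slab] = config.ictal_deconv_level

    # --- photostimulation-evoked impulses ---------------------------------
    nontarget_ids = np.setdiff1d(np.arange(n), target_ids)
    pair_dist = np.hypot(
        xy[target_ids, None, 0] - xy[None, nontarget_ids, 0],
        xy[target_ids, None, 1] - xy[None, nontarget_ids, 1],
    )
    coupling = np.asarray(config.coupling_kernel(pair_dist), dtype=float)
    n_trials = len(trials)
    eps = rng.normal(0.0, config.shared_fluctuation_sd, n_trials) if n_trials else np.empty(0)
    gains = np.ones((n_trials, len(target_ids)))
    front_distance = np.full((n_trials, n), np.nan)
    stim_impulses = np.zeros((n, n_frames))
    for i, (_, tr) in enumerate(trials.iterrows()):
        t_on, t_off = float(tr["onset"]), float(tr["offset"])
        containing = next((ev for ev in seizures if ev.onset <= t_on <= ev.offset), None)
        if containing is not None:
            d_signed = d_onset - config.wavefront_speed * (t_on - containing.onset)
            front_distance[i] = d_signed
            gains[i] = np.asarray(config.gain_vs_front_distance(d_signed[target_ids]), dtype=float)
        amp_t = np.clip(config.stim_gain_interictal * gains[i] * (1.0 + eps[i]), 0.0, None)
        amp_nt = coupling.T @ amp_t
        frame = min(int(np.searchsorted(times, t_off)), n_frames - 1)
        stim_impulses[target_ids, frame] += amp_t
        stim_impulses[nontarget_ids, frame] += amp_nt
    deconv += np.clip(stim_impulses, 0.0, None)

    # --- convolution with the transient kernel ----------------------------
    k_len = int(np.ceil(5 * config.transient_tau * fr)) + 1
    kernel = np.exp(-np.arange(k_len) / (config.transient_tau * fr))
    signal = fftconvolve(impulses + stim_impulses, kernel[None, :], axes=1)[:, :n_frames]

    # --- seizure waveform --------------------------------------------------
    for s, ev in enumerate(seizures):
        lo = int(np.searchsorted(times, ev.onset - 1.0))
        hi = min(int(np.searchsorted(times, ev.offset + 6 * config.seizure_fall_tau)), n_frames)
        tt = times[lo:hi]
        rel = tt[None, :] - rec_time[s][:, None]
        comp = (
            config.seizure_plateau_amp
            * expit(rel / config.seizure_rise_tau)
            * np.exp(-np.clip(rel, 0.0, None) / config.plateau_decay_tau)
        )
        fall = np.where(tt > ev.offset, np.exp(-(tt - ev.offset) / config.seizure_fall_tau), 1.0)
        comp *= fall[None, :]
        comp[~recruited[s]] = 0.0
        signal[:, lo:hi] += comp

    # --- post-ictal suppression -------------------------------------------
    factor = np.ones(n_frames)
    for ev in seizures:
        sel = (times > ev.offset) & (times <= ev.offset + config.postictal_window)
        factor[sel] = config.postictal_suppression
    signal *= factor[None, :]

    fluorescence = f0[:, None] * (1.0 + signal + rng.normal(0.0, config.noise_sd, (n, n_frames)))

    # --- excluded frames, LFP proxy ---------------------------------------
    excluded = np.zeros(n_frames, dtype=bool)
    for _, tr in trials.iterrows():
        excluded |= (times >= tr["onset"]) & (times <= tr["offset"])
    traces = TraceSet(fluorescence, frame_rate=fr, deconvolved=deconv, excluded_frames=excluded)

    lfp = rng.normal(0.0, 0.02, n_frames)
    for ev in seizures:
        sel = (times >= ev.onset) & (times <= ev.offset)
        lfp[sel] += np.sin(2 * np.pi * 6.0 * (times[sel] - ev.onset))

    # --- wavefront annotations for ictal trials ----------------------------
    fronts = {}
    for _, tr in trials.iterrows():
        for ev in seizures:
            if ev.onset <= tr["onset"] <= ev.offset:
                fronts[int(tr["trial_id"])] = front_line_at(ev, float(tr["onset"]), config)
                break
    seizure_set = SeizureSet(sz_table, fronts)

    gt = GroundTruth(
        seizures=seizures,
        onset_distance=d_onset,
        recruitment_time=rec_time,
        recruited=recruited,
        gains=gains,
        front_distance=front_distance,
        coupling=coupling,
        target_ids=target_ids,
        nontarget_ids=nontarget_ids,
        triggered_trials=triggered,
        shared_fluctuation=eps,
    )
    return rois, traces, trials, seizure_set, lfp, gt


def render_frames(
    config: SimConfig,
    rois: RoiTable,
    traces: TraceSet,
    ground_truth: GroundTruth,
    frame_lo: int,
    frame_hi: int,
    background_amp: float = 1.0,
    background_level: float = 0.2,
    noise_sd: float = 0.01,
    seed: int = 0,
) -> np.ndarray:
    """Render an imaging frame stack for frames [frame_lo, frame_hi).

    The background (neuropil) of every pixel is recruited by the seizure
    front exactly like a neuron at that location (same waveform, amplitude
    ``background_amp`` on a resting level of ``background_level``); somata are
    painted on top with their own normalized fluorescence signal.  Intended
    for the annulus-neuropil and wavefront-image operations; returns a
    (frames, h, w) float32 stack in normalized fluorescence units.
    """
    rng = np.random.default_rng(seed)
    fr = config.frame_rate
    tt = np.arange(frame_lo, frame_hi) / fr
    h = int(np.ceil(config.fov_size[1] / config.px_size))
    w = int(np.ceil(config.fov_size[0] / config.px_size))
    xs = (np.arange(w) + 0.5) * config.px_size
    ys = (np.arange(h) + 0.5) * config.px_size
    u = config.direction
    proj = xs[None, :] * u[0] + ys[:, None] * u[1]
    anchor_proj = float(np.asarray(ground_truth.seizures[0].anchor) @ u) if ground_truth.seizures else 0.0
    d_px = proj - anchor_proj
    stack = np.full((tt.size, h, w), background_level, dtype=np.float32)
    for ev in ground_truth.seizures:
        rec_px = ev.onset + d_px / config.wavefront_speed
        for k, t in enumerate(tt):
            if t < ev.onset - 1.0 or t > ev.offset + 6 * config.seizure_fall_tau:
                continue
            rel = t - rec_px
            comp = (
                background_amp
                * expit(rel / config.seizure_rise_tau)
                * np.exp(-np.clip(rel, 0.0, None) / config.plateau_decay_tau)
            )
            if t > ev.offset:
                comp = comp * np.exp(-(t - ev.offset) / config.seizure_fall_tau)
            stack[k] += comp.astype(np.float32)
    # paint somata with their normalized signal (1 + dF/F-like excursion)
    row_mean = traces.fluorescence.mean(axis=1)
    for rid, (rr, cc) in rois.masks.items():
        sig = traces.fluorescence[rid, frame_lo:frame_hi] / row_mean[rid]
        stack[:, rr, cc] = sig[:, None].astype(np.float32)
    stack += rng.normal(0.0, noise_sd, stack.shape).astype(np.float32)
    return stack
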