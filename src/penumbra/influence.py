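"""Trial-wise influence of ensemble photostimulation on non-targeted neurons.

The influence metric quantifies the net excitatory (positive) or inhibitory
(negative) effect of photostimulation on each non-targeted neuron.  Because
every trial photostimulates the full target ensemble (no interleaved
no-stimulation trials exist), the predicted response of a non-target on a
trial is taken as the mean response of *all* non-targets on that trial; the
influence is the per-trial deviation from that prediction, normalized by the
across-trial sample SD of the deviation:

    d_jt = r_jt - p_t,      p_t = mean_j r_jt
    I_jt = d_jt / SD_t(d_j.)

The mean-prediction makes the metric invariant to per-trial additive offsets
shared by all non-targets (global state fluctuations), which is the property
that motivates the modification.  Under simultaneous ensemble stimulation,
single-target causal attribution is not possible; the distance profile
attributes each non-target's influence to every target within a maximum
radius, binned by pair distance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "InfluenceTable",
    "predicted_response",
    "influence_metric",
    "artificial_trials",
    "influence_vs_distance",
    "target_vs_nontarget_totals",
]


@dataclass
class InfluenceTable:
    """Per-(trial, non-target) influence values.

    ``difference`` and ``influence`` are (trials, non-targets) arrays;
    ``predicted`` is the per-trial mean non-target response.  ``influence``
    is NaN for neurons whose across-trial deviation SD is zero.
    """

    difference: np.ndarray
    influence: np.ndarray
    predicted: np.ndarray
    nontarget_ids: np.ndarray | None = None
    trial_ids: np.ndarray | None = None


def predicted_response(nontarget_responses) -> float:
    """Trial-wise predicted response: mean over non-targets (NaN if < 2)."""
    r = np.asarray(nontarget_responses, dtype=float)
    r = r[np.isfinite(r)]
    if r.size < 2:
        return float("nan")
    return float(r.mean())


def influence_metric(
    response_matrix,
    nontarget_ids=None,
    trial_ids=None,
) -> InfluenceTable:
    """Influence of photostimulation on every non-target, trial by trial.

    ``response_matrix`` is (trials, non-targets) of response magnitudes.
    Requires at least two trials (the sample SD needs two points); neurons
    with zero deviation SD get NaN influence.
    """
    r = np.asarray(response_matrix, dtype=float)
    if r.ndim != 2:
        raise ValueError("response matrix must be (trials, nontargets)")
    if r.shape[0] < 2:
        raise ValueError("influence metric requires at least two trials")
    p = np.array([predicted_response(row) for row in r])
    d = r - p[:, None]
    with np.errstate(invalid="ignore"):
        sd = np.nanstd(d, axis=0, ddof=1)
    influence = np.full_like(d, np.nan)
    ok = sd > 0
    influence[:, ok] = d[:, ok] / sd[ok]
    return InfluenceTable(
        difference=d,
        influence=influence,
        predicted=p,
        nontarget_ids=None if nontarget_ids is None else np.asarray(nontarget_ids),
        trial_ids=None if trial_ids is None else np.asarray(trial_ids),
    )


def artificial_trials(
    trials: pd.DataFrame,
    pre: float = 0.5,
    post: float = 0.5,
) -> pd.DataFrame:
    """Sham stimulation trials interleaved between real trials.

    One artificial trial is placed at the onset midpoint of each consecutive
    pair of real trials, with the same duration and ``modality='artificial'``.
    A gap too short to fit the sham trial plus its pre/post analysis windows
    clear of both real trials emits no sham.
    """
    real = trials.sort_values("onset").reset_index(drop=True)
    if len(real) < 2:
        return real.iloc[0:0].copy()
    rows = []
    for i in range(len(real) - 1):
        dur = real.loc[i, "offset"] - real.loc[i, "onset"]
        onset = (real.loc[i, "onset"] + real.loc[i + 1, "onset"]) / 2.0
        offset = onset + dur
        if onset - pre < real.loc[i, "offset"] or offset + post > real.loc[i + 1, "onset"]:
            continue
        rows.append({"trial_id": f"sham_{i}", "onset": onset, "offset": offset, "modality": "artificial"})
    return pd.DataFrame(rows, columns=["trial_id", "onset", "offset", "modality"])


def influence_vs_distance(
    table: InfluenceTable,
    nontarget_coords,
    target_coords,
    max_dist: float = 400.0,
    bin_width: float = 40.0,
) -> pd.DataFrame:
    """Distance-binned influence profile over (target, non-target) pairs.

    Every pair within ``max_dist`` um contributes the non-target's mean
    across-trial influence to the bin of the pair's centroid distance, so the
    bin mean is weighted by how many of a neuron's targets lie at that
    distance.  Because a pair's value depends only on its non-target, pairs
    sharing a neuron are duplicates; the SEM is therefore computed across the
    distinct non-targets contributing to the bin (pair- or trial-level SEMs
    would understate the error).

    Returns a DataFrame with ``center, mean, sem, n_pairs, n_nontargets``.
    """
    nt = np.atleast_2d(np.asarray(nontarget_coords, dtype=float))
    tg = np.atleast_2d(np.asarray(target_coords, dtype=float))
    infl = table.influence
    if infl.shape[1] != nt.shape[0]:
        raise ValueError("coordinate / influence column mismatch")
    d = np.hypot(nt[:, None, 0] - tg[None, :, 0], nt[:, None, 1] - tg[None, :, 1])
    with np.errstate(invalid="ignore"):
        pair_mean = np.nanmean(infl, axis=0)  # per non-target
        pair_count = np.sum(np.isfinite(infl), axis=0)
    edges = np.arange(0.0, max_dist + bin_width / 2, bin_width)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        jj, _ = np.nonzero((d >= lo) & (d < hi))
        keep = np.isfinite(pair_mean[jj]) & (pair_count[jj] > 0)
        jj = jj[keep]
        if jj.size == 0:
            continue
        uniq = np.unique(jj)
        vals = pair_mean[uniq]
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan
        rows.append(
            {
                "center": (lo + hi) / 2.0,
                "mean": float(pair_mean[jj].mean()),
                "sem": float(sem),
                "n_pairs": int(jj.size),
                "n_nontargets": int(uniq.size),
            }
        )
    return pd.DataFrame(rows, columns=["center", "mean", "sem", "n_pairs", "n_nontargets"])


def target_vs_nontarget_totals(
    target_responses,
    nontarget_responses,
):
    """Per-trial total target vs total non-target response, z-scored.

    Sums each group's response magnitudes per trial, z-scores the two total
    series within the replicate (sample SD), and returns
    ``(z_targets, z_nontargets, correlation)``; the correlation is NaN with
    fewer than three trials or a degenerate series.
    """
    rt = np.asarray(target_responses, dtype=float)
    rn = np.asarray(nontarget_responses, dtype=float)
    if rt.ndim != 2 or rn.ndim != 2 or rt.shape[0] != rn.shape[0]:
        raise ValueError("need (trials, neurons) matrices with matching trial counts")
    tot_t = np.nansum(rt, axis=1)
    tot_n = np.nansum(rn, axis=1)

    def _z(x):
        sd = x.std(ddof=1) if x.size > 1 else 0.0
        if sd == 0:
            return np.full_like(x, np.nan)
        return (x - x.mean()) / sd

    zt, zn = _z(tot_t), _z(tot_n)
    if tot_t.size < 3 or np.isnan(zt).all() or np.isnan(zn).all():
        r = float("nan")
    else:
        r = float(np.corrcoef(zt, zn)[0, 1])
    return zt, zn, r
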