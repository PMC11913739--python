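"""Reading and writing the on-disk dataset layout.

A dataset directory holds:

* ``rois.csv`` — roi_id, x, y, is_target, is_inhibitory
* ``roi_masks.h5`` — per-ROI pixel index arrays plus pixel size / FOV
* ``traces.h5`` — fluorescence, optional deconvolved, frame rate, excluded mask
* ``trials.csv`` — trial_id, onset, offset, modality (+ state columns if set)
* ``seizures.csv`` — seizure_id, onset, offset
* ``fronts.csv`` — trial_id, x1, y1, x2, y2, ref_x, ref_y (wavefront lines, um)
* ``lfp.csv`` — the LFP proxy channel
* ``ground_truth.h5`` / ``ground_truth.json`` — simulator recovery targets
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .timebase import SeizureSet
from .traces import RoiTable, TraceSet
from .wavefront import FrontLine

__all__ = ["save_dataset", "load_dataset", "save_ground_truth"]


def save_dataset(outdir, rois: RoiTable, traces: TraceSet, trials: pd.DataFrame,
                 seizures: SeizureSet, lfp=None, ground_truth=None) -> Path:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rois.table.to_csv(out / "rois.csv", index=False)
    with h5py.File(out / "roi_masks.h5", "w") as f:
        f.attrs["px_size"] = rois.px_size
        f.attrs["fov_size"] = rois.fov_size
        for rid, (rr, cc) in rois.masks.items():
            g = f.create_group(str(rid))
            g.create_dataset("rows", data=np.asarray(rr))
            g.create_dataset("cols", data=np.asarray(cc))
    with h5py.File(out / "traces.h5", "w") as f:
        f.create_dataset("fluorescence", data=traces.fluorescence)
        if traces.deconvolved is not None:
            f.create_dataset("deconvolved", data=traces.deconvolved)
        f.create_dataset("excluded_frames", data=traces.excluded_frames)
        f.attrs["frame_rate"] = traces.frame_rate
    trials.to_csv(out / "trials.csv", index=False)
    seizures.table.to_csv(out / "seizures.csv", index=False)
    rows = []
    for tid, fl in seizures.fronts.items():
        rows.append({
            "trial_id": tid,
            "x1": fl.p1[0], "y1": fl.p1[1], "x2": fl.p2[0], "y2": fl.p2[1],
            "ref_x": fl.penumbra_side[0], "ref_y": fl.penumbra_side[1],
        })
    pd.DataFrame(rows, columns=["trial_id", "x1", "y1", "x2", "y2", "ref_x", "ref_y"]).to_csv(
        out / "fronts.csv", index=False)
    if lfp is not None:
        pd.DataFrame({"lfp": np.asarray(lfp)}).to_csv(out / "lfp.csv", index=False)
    if ground_truth is not None:
        save_ground_truth(out, ground_truth)
    return out


def save_ground_truth(outdir, gt) -> None:
    out = Path(outdir)
    with h5py.File(out / "ground_truth.h5", "w") as f:
        f.create_dataset("onset_distance", data=gt.onset_distance)
        f.create_dataset("recruitment_time", data=gt.recruitment_time)
        f.create_dataset("recruited", data=gt.recruited)
        f.create_dataset("gains", data=gt.gains)
        f.create_dataset("front_distance", data=gt.front_distance)
        f.create_dataset("coupling", data=gt.coupling)
        f.create_dataset("target_ids", data=gt.target_ids)
        f.create_dataset("nontarget_ids", data=gt.nontarget_ids)
        f.create_dataset("shared_fluctuation", data=gt.shared_fluctuation)
    meta = {
        "seizures": [
            {"seizure_id": s.seizure_id, "onset": s.onset, "offset": s.offset, "anchor": list(s.anchor)}
            for s in gt.seizures
        ],
        "triggered_trials": list(map(int, gt.triggered_trials)),
    }
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_dataset(indir):
    """Load a dataset directory; returns (rois, traces, trials, seizures, lfp)."""
    d = Path(indir)
    table = pd.read_csv(d / "rois.csv")
    masks = {}
    px_size, fov = 1.0, (512.0, 512.0)
    if (d / "roi_masks.h5").exists():
        with h5py.File(d / "roi_masks.h5", "r") as f:
            px_size = float(f.attrs["px_size"])
            fov = tuple(np.asarray(f.attrs["fov_size"], dtype=float))
            for rid in f:
                masks[int(rid)] = (f[rid]["rows"][()], f[rid]["cols"][()])
    rois = RoiTable(table, masks, px_size, fov)
    with h5py.File(d / "traces.h5", "r") as f:
        traces = TraceSet(
            f["fluorescence"][()],
            frame_rate=float(f.attrs["frame_rate"]),
            deconvolved=f["deconvolved"][()] if "deconvolved" in f else None,
            excluded_frames=f["excluded_frames"][()].astype(bool),
        )
    trials = pd.read_csv(d / "trials.csv")
    sz_table = pd.read_csv(d / "seizures.csv")
    fronts = {}
    if (d / "fronts.csv").exists():
        fdf = pd.read_csv(d / "fronts.csv")
        for _, r in fdf.iterrows():
            fronts[int(r["trial_id"])] = FrontLine(
                (r["x1"], r["y1"]), (r["x2"], r["y2"]), (r["ref_x"], r["ref_y"]))
    seizures = SeizureSet(sz_table, fronts)
    lfp = None
    if (d / "lfp.csv").exists():
        lfp = pd.read_csv(d / "lfp.csv")["lfp"].to_numpy()
    return rois, traces, trials, seizures, lfp
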