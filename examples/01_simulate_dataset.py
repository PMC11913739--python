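"""Generate a synthetic all-optical experiment and save it as a dataset.

The default configuration is a 10-minute recording of 100 neurons (40 of
them photostimulation targets) with three seizures sweeping the field of
view as a straight wavefront, periodic 2-photon stimulation every 10 s, and
full ground truth (recruitment times, applied gains, coupling weights).
"""

from penumbra.io import save_dataset
from penumbra.sim import SimConfig, simulate

cfg = SimConfig(seed=42)
rois, traces, trials, seizures, lfp, gt = simulate(cfg)

out = save_dataset("example_dataset", rois, traces, trials, seizures, lfp=lfp, ground_truth=gt)

print(f"wrote dataset to {out}/")
print(f"  neurons:  {len(rois)} ({int(rois.table['is_target'].sum())} targets, "
      f"{int(rois.table['is_inhibitory'].sum())} inhibitory)")
print(f"  frames:   {traces.n_frames} at {traces.frame_rate:g} Hz")
print(f"  trials:   {len(trials)}")
print(f"  seizures: {len(seizures)} "
      f"(onsets {', '.join(f'{t:.0f} s' for t in seizures.onsets)})")
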