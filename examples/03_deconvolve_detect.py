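"""Timing-free event detection on a planted-event phantom.

Runs the full detection pipeline: trim the Random pads, deconvolve the
multi-echo data voxelwise (sparse L1 path + BIC penalty selection), clean
with the 3-point temporal max filter and 10-voxel cluster rule, build the
activation timeseries (ATS), threshold it against a volume-shuffled
surrogate run, and select ROI peaks — then compares the detected event
times with the planted truth.
"""

import numpy as np

from urgepfm import events, evaluation, synthgen

schedule = synthgen.make_block_schedule()
noise_sd = 0.5  # percent-signal units
amp = -evaluation.amplitude_for_cnr(cnr=3.0, noise_sd_pct=noise_sd)
truth = synthgen.make_ground_truth(
    grid=(8, 8, 4), n_rois=1, events_per_roi=6, amplitude=amp,
    noise_sd_pct=noise_sd, seed=1, roi_size=(3, 3, 2),
)
series = synthgen.simulate_multiecho_run(schedule, truth, seed=1)
roi = truth.roi_labels == 1

ev, decon, surrogate, keep = events.detect_events(series, schedule, roi, seed=1)

planted = truth.event_onsets[1] - keep[0]
print(f"planted events (trimmed TR index): {sorted(planted.tolist())}")
print(f"detected peaks:                    {sorted(ev.timepoints.tolist())}")
print(f"ROI surrogate threshold: {ev.metadata['threshold']:.1f} voxels")
hits = sum(any(abs(int(p) - int(o)) <= 1 for p in ev.timepoints) for o in planted)
print(f"recovered {hits}/6 planted events within one TR")
# The surrogate (volume-shuffled) run sets the null level of the ATS; with
# CNR-3 events the planted times stand clear of it while an event-free
# phantom would yield no peaks.

t = ev.timepoints[0]
print(f"\nfirst event map at TR {t}: "
      f"{(ev.maps[0] < 0).sum()} active voxels, "
      f"min dR2* {ev.maps[0].min():.2f} 1/s (planted {amp:.2f})")
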