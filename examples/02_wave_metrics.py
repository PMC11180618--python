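"""Waveform metrics from annotated waves, in physical units.

Uses the simulator's ground truth as a stand-in for manual ridge
annotations on a spatiotemporal map and converts each wave into
amplitude (um), period (s), frequency (Hz), velocity (um/s),
wavelength (um) and direction.
"""

import myowave as mw

params = mw.SimulationParams(duration_s=300.0, wave_speed_um_s=12.8,
                             wave_spacing_um=800.0, band_width_um=190.0)
truth = mw.ground_truth(params)
annotations = mw.truth_annotations(truth, n_waves=9, seed=1)

metrics = []
for ann in annotations:
    m = mw.compute_metrics(ann, params.calibration)
    m.segment = mw.assign_segment(ann, params.width)
    metrics.append(m)

summary = mw.summarize(metrics)
print(f"{summary['n_waves']} waves analysed")
for name, unit in [("velocity_um_s", "um/s"), ("frequency_hz", "Hz"),
                   ("amplitude_um", "um"), ("wavelength_um", "um")]:
    entry = summary[name]
    print(f"  median {name:15s} = {entry['median']:8.3f} {unit}  (n={entry['n']})")
print("simulated: 12.8 um/s, 0.016 Hz, 190 um amplitude, 800 um wavelength")
print("directions:", {m.direction for m in metrics})
print("segments  :", sorted(m.segment for m in metrics))
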