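"""Simulate one RF measurement and track the ringing surface.

One RAR measurement: 20 baseline pulses sample the surface at rest, a push
tone burst kicks it, and 500 detection pulses at 10 kHz record the damped
ring-down.  Cross-correlating each detection echo against the averaged
baseline recovers the displacement waveform to nanometre precision.
"""

import numpy as np

from mrar import AcquisitionConfig, CoagulationTrajectory, simulate_run, track_measurement

cfg = AcquisitionConfig(total_duration=0.0, n_channels=1, noise_snr_db=30.0, seed=1)
# a liquid-like sample ringing at 55 Hz with a 20 um, 20 ms ring-down
traj = CoagulationTrajectory(
    f_liquid=55.0, f_solid=55.1, t_start=1e9, t_end=2e9,
    amp_liquid=20e-6, amp_solid=20e-6, decay_liquid=20e-3, decay_solid=20e-3,
)
archive, truth = simulate_run(cfg, [traj])
record = archive.measurements(0)[0]
print(f"A-line matrix: {record.alines.shape[0]} pulses x {record.alines.shape[1]} samples")

trace = track_measurement(record, cfg)
err = trace.displacement - truth.channel(0).displacement_true[0]
print(f"peak programmed displacement: {np.abs(truth.channel(0).displacement_true[0]).max()*1e6:.2f} um")
print(f"peak recovered displacement:  {np.abs(trace.displacement).max()*1e6:.2f} um")
print(f"RMS tracking error at 30 dB SNR: {np.sqrt(np.mean(err**2))*1e6:.3f} um")
print(f"lowest correlation peak: {trace.correlation_peak.min():.3f} "
      f"({int(trace.low_confidence.sum())} low-confidence samples)")
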