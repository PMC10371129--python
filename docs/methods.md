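# Methods

## Physical model

A liquid or gel confined in a cylindrical well of radius *a* supports
resonant surface waves whose wavenumber is set by the geometry, *k = z/a*.
The default mode constant *z* = 3.8317 is the first nonzero root of J₁ —
the fundamental axisymmetric mode of a circular free surface with a
free-slip wall. The contact-line condition of a real well (pinned vs free)
is not settled by theory alone, so *z* is an explicit configuration
parameter; any other convention can be substituted without touching the
rest of the chain. Default density is 1000 kg/m³ (plasma ≈ water) and the
default radius 3.25 mm (96-well plate).

Dispersion laws: capillary waves f = (1/2π)√(σk³/ρ) in the liquid regime,
Rayleigh waves f = (1/2π)√(Gk²/ρ) in the solid regime. The inversions are
algebraic, σ = (2πf)²ρ/k³ and G = ρ(2πf/k)², and round-trip to ~1e-15
relative error. The intermediate visco-elasto-capillary crossover is out of
scope: regime selection is the caller's responsibility (liquid before
clotting starts, solid after it completes), and the module never
auto-classifies.

## Acquisition simulator

The simulator emulates one multichannel RAR run: per measurement (every
ΔT = 6 s), 20 baseline detection pulses at 10 kHz PRF, one 100-cycle push
tone burst (20 µs at 5 MHz), then 500 detection pulses at 10 kHz. All
channels share one observation-time grid (hardware-synchronized pulsing).
A note on pulse counts: the source acquisition scheme is described both as
0.1 s of detection at 10 kHz (1000 pulses) and as 500 detection pulses; the
default is 500 and the count is configurable.

Each A-line holds two static well-plate interface echoes (at 0.25 and 0.35
of the surface depth — kept well clear of the surface-echo correlation
gate) and one sample-surface echo: a Gaussian-windowed tone at the center
frequency with −6 dB fractional bandwidth 60 % (transducer impulse response
unspecified upstream; this is a conventional pulse model). The surface echo
round-trip delay is 2(z₀ + s)/c with sound speed c = 1480 m/s; positive
displacement moves the surface away from the transducer. White Gaussian
noise is added at `noise_snr_db` (echo peak amplitude over noise RMS), and
per-pulse transmit jitter (±5 % multiplicative, uniform) exercises the
baseline-averaging rationale. The digitizer rate defaults to 100 MHz
(20 samples per carrier cycle) for comfortable sub-sample interpolation;
the recorded trace is 5.12 µs (512 samples) with the surface at 2 mm
equivalent depth — a compact record that keeps full-resolution simulations
cheap without changing any acquisition timing.

Surface motion within a measurement is a damped harmonic oscillation
s(T, τ) = A(T)·exp(−τ/τ_d(T))·sin(2πf(T)τ). The coagulation trajectory
interpolates frequency, amplitude and ring-down time between liquid and
solid plateaus with either a rescaled logistic (midpoint (t_start+t_end)/2,
width (t_end−t_start)/8, clipped so the plateaus are reached exactly at
t_start/t_end) or a piecewise-linear ramp (analytically convenient).
Defaults: f_liquid ≈ 55 Hz (σ = 72 mN/m via the capillary law),
f_solid = 300 Hz (G ≈ 2.6 kPa via the Rayleigh law), amplitudes 20 → 2 µm,
ring-down 20 → 5 ms. The solid ring-down of 5 ms keeps the post-clot
quality factor Q = πfτ_d ≈ 4.7: a clot must still show an identifiable
(if visibly widened) resonance ridge in the spectrogram, which is the
empirically observed post-clot signature; much below Q ≈ 2 the spectral
peak of a single ring-down ceases to define a usable frequency at realistic
noise levels. Amplitude scales are order-of-magnitude choices — upstream
descriptions do not quantify them in µm.

What the simulator does *not* model: diffraction and beam profiles, bulk
speckle, nonlinear propagation, radiation-force magnitude, frequency
content of real transducers beyond the Gaussian pulse, or multi-mode
surface dynamics. Passing tests therefore demonstrate the correctness of
the signal-processing chain against its own physics, not robustness to
every artifact of real instruments.

## Displacement tracking

The equilibrium reference is the pointwise mean of the baseline A-lines,
gated to ±3 detection-pulse lengths (2 cycles at the center frequency)
around the surface echo, which is located as the strongest peak of the
analytic-signal envelope of the averaged baseline. Averaging cancels
pulse-to-pulse transmit-amplitude variation; normalized correlation makes
the estimator additionally scale-invariant per pulse.

Each detection echo is compared to that fixed equilibrium reference (no
motion accumulation across pulses). Normalized cross-correlation is
evaluated over an integer-lag window of ±0.5 µs (≈ ±370 µm, generous
against µm-scale motion) and refined by 3-point parabolic interpolation of
the correlation peak; displacement = c·delay/2. A peak correlation below
0.5 flags the sample low-confidence (the value is kept). On the reference
configuration the tracker achieves ≈ 0.01 µm RMS noise-free and ≈ 0.25 µm
RMS at 30 dB SNR — close to the delay-estimation noise bound for this
pulse bandwidth.

Missing or corrupted measurements become flagged NaN gap rows in
S(T_m, τ_n); nothing is interpolated.

## Spectral analysis

Each displacement trace is mean-subtracted, zero-padded to 4× its length
(peak-interpolation stability) and transformed; the magnitude-squared
spectrum is normalized to unit maximum per observation time, which
reproduces the familiar per-column contrast of coagulation spectrograms.
No taper is applied by default — the ring-down decays naturally.

The resonant frequency is the global spectral maximum in a search band
(floor 10 Hz to reject DC leakage, ceiling 0.8× the fast-time Nyquist).
The peak is refined with a least-squares parabola on log power fitted over
the contiguous half-power top of the peak (with a classic 3-point fallback
for narrow tops); fitting the whole top rather than 3 bins halves the
noise-driven wander of broad, heavily damped peaks without affecting sharp
ones. Exact power ties resolve deterministically to the lower frequency.
The −3 dB width is the half-power span with linearly interpolated edges.

Two physical caveats are inherent to peak reading and documented rather
than hidden: (i) the spectrum of a damped ring-down peaks at
√(f₀² − (γ/2π)²) with γ = 1/τ_d, slightly below the oscillation frequency —
a few percent at post-clot damping; (ii) the width mixes damping with
finite-record broadening. Both cancel to first order in the clotting
parameters, which compare frequencies measured by the same estimator.

## Clotting-parameter extraction

f_int is the mean peak frequency over the first 60 s of measurements
(closed window from the first sample), f_end over the final 300 s. T_int is
the earliest observation time with f ≥ 1.05·f_int whose next valid sample
also satisfies the threshold; T_end analogously with f ≥ 0.95·f_end. The
two-sample persistence check rejects single-sample noise spikes; NaN
samples are skipped and never count as crossings. A 3-point median
pre-filter (default on, configurable) further stabilizes the trace; the
analytic ground-truth oracle applies the identical threshold logic to the
noiseless trajectory without filtering. Traces whose plateau never rises
5 % above f_int are flagged `no_clot` (no degenerate near-zero durations);
runs shorter than the averaging windows are flagged `truncated` with
best-effort values. By construction T_int and T_end lie on the ΔT grid, so
±ΔT (6 s) is the natural recovery resolution.

## Validation sizing

The acceptance script and heavy tests use single-channel, 15-minute runs
(151 measurements, 512-sample A-lines) and 20-run ensembles; these sizes
give stable statistics (binomial resolution 1/40 on the recovery rate) at
about a minute of total runtime on one CPU. The acquisition timing itself —
PRF, pulse counts, ΔT, carrier — is never scaled.

## Known limitations

* Peak-reading biases at very heavy damping (Q ≲ 2) are not corrected;
  viscosity/damping quantification from peak width is explicitly out of
  scope.
* The tracker assumes a single dominant surface echo; overlapping echoes
  (very shallow samples) would require gating changes.
* The intermediate dispersion regime during the liquid–solid transition has
  no inversion; inverted moduli are meaningful only on the plateaus.
* Group-level statistics across samples (regression, significance testing)
  are left to standard tools downstream of the per-channel CSV output.
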