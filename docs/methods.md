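# Methods

This note records what the simulator models, the choices made where the
design was genuinely open, and what its tests do and do not demonstrate
about real hardware and real listeners.

## Signal path

One analysis frame per stimulation cycle: the frame hop is
`round(rate / pps)` samples, so at the default 500 pps and 16 kHz the
128-sample (8 ms) window slides by 32 samples per cycle and successive
windows overlap 75%. The final partial frame is zero-padded rather than
dropped so the stimulus duration — and with it the offset timing used in
binaural analysis — is preserved.

Envelopes are kept in the power domain, `Y(n) = Σ a(n,k) X²(k)`, exactly
as the filterbank defines them; no square root is taken. Whatever
amplitude-versus-power convention one prefers is absorbed by the acoustic
normalization that precedes compression (below).

**Channel allocation.** No allocation table is prescribed, so the default
22-channel table spans 188–7938 Hz with contiguous FFT-bin groups whose
widths follow a geometric progression subject to a minimum of one bin per
channel. This reproduces the conventional layout: channels 1–13 get one
125 Hz bin each, the basal channels widen to 8–10 bins. The Nyquist bin
participates in the top channel. The allocation, like the per-channel
gains (default 1), is replaceable through `ChannelWeights`.

**Electrode numbering.** Electrode 1 is the most basal (high-frequency)
contact, electrode 22 the most apical; analysis channel n (ascending
centre frequency) drives electrode 23 − n. Under the default table a
440 Hz tone lands on electrode 20, which is why that electrode is the
default ITD probe. Within a cycle, pulses fire base-to-apex (ascending
electrode number); the order is a convention, not a claim about hardware.

**Acoustic normalization.** The compression input must lie in [0, 1], but
no acoustic reference is prescribed. The envelope power of a full-scale
sinusoid at a channel centre under a 128-point Hann window is (L/4)² =
1024; that is the default saturation level. A 40 dB input dynamic range
below saturation maps to (0, 1]; quieter envelopes produce no stimulation
at all (magnitude 0 emits no pulse). Both parameters sit in
`StrategyConfig`. CIS applies the same loudness-growth function as
ACE/FACE by default (`compress_cis=False` disables it) so loudness growth
is uniform across strategies.

**Rate safety.** The validator enforces the 14 400 Hz aggregate ceiling,
the 650 pps per-channel cap when all 22 electrodes are active (the
conventional rounded-down 14400/22), the 125 pps safety floor, a warning
above the preferred 600 pps, and that one biphasic slot per active channel
fits in the cycle. Default pulse timing is 25 µs per phase with an 8 µs
interphase gap (typical clinical values, configurable); event times are
quantized to a 1 µs pulse clock.

**Default stimulation rate.** 500 pps per channel. A 1000 pps default is
impossible with all 22 channels active (22 000 Hz aggregate exceeds the
platform's own cap), and 500 pps is the rate at which the strategies were
actually evaluated.

## FACE formant track

The 28th-order autocorrelation-method LPC runs on the windowed
time-domain frame, not on the 22 channel envelopes: a 28-pole fit needs
the wideband signal to resolve three formants. A tiny ridge (10⁻⁶ on the
zero-lag autocorrelation) keeps the Toeplitz solve stable on
near-harmonic frames. Candidate poles are kept between 90 Hz and
Nyquist − 90 Hz with bandwidth under 400 Hz.

On voiced frames the poles lock onto individual harmonics, so one formant
surfaces as a pair of candidates straddling it one harmonic apart;
candidates closer than 175 Hz are therefore fused (inverse-bandwidth-
weighted mean). The continuity check accepts, for each of F1–F3, the
nearest candidate within the 150–200 Hz window (default ceiling 200 Hz)
and otherwise carries the previous formant forward one cycle; a cold
start accepts the three sharpest resonances outright. Formant channels
count **within** `n_maxima`, not in addition to it, and missing formant
slots fall back to maxima selection — so FACE degrades gracefully to ACE
on non-speech input.

## Bilateral synchronization

Processing latency is a *model* (`LatencyModel`), not a measurement:
wall-clock throughput is hardware-dependent and out of scope. The model
exists to exercise the stall contract: block i of each ear completes at
its 8 ms arrival time plus that ear's delay (plus optional non-negative
jitter drawn from the run seed), and the block is released at the later of
the two completion times, monotone non-decreasing. Stalling operates on
the release schedule only — the stimulation timelines are never shifted —
so an external interaural offset is preserved bit-exactly through any
latency mismatch, including an offline-scale 8 s ear against a real-time
ear. Stalls are at 8 ms block granularity, not per pulse.

Fractional-sample offsets (e.g. 740 µs = 11.84 samples) are injected with
an 81-tap Hann-windowed-sinc interpolator.

## Scene model

The loudspeaker ring is reduced to two azimuth-derived cues per component:
ITD = `itd_at_90`·sin θ and ILD = `ild_at_90`·sin θ, negative azimuths
leading and favouring the left ear. Defaults: 740 µs (the platform's
measured lateral lead) and 10 dB. The sine law replaces head-related
transfer functions; no room acoustics, no spectral pinna cues. Scenes are
padded with 50 ms of lead-in/lead-out silence, as in booth playback, so
onset and offset transients sit fully inside both ears' buffers even
after the interaural delay — for a steady tone those transients are the
only timing information the envelope coding retains, and truncating them
at the buffer edge would align them across ears and destroy the cue.

Speech-shaped noise is white noise through a fixed long-term-speech-
spectrum FIR (flat 300–500 Hz, falling ≈ 9 dB/octave above); babble is
eight amplitude-modulated narrowband streams (2–6 Hz syllabic envelopes);
the competing talker is a 4 Hz-modulated SSN carrier. These are
statistical surrogates: they share real interferers' spectra and
modulation depth but carry no phonetic content, so intelligibility-level
conclusions cannot be drawn from them. SNR is set on the mono signals
before spatialization. Tones carry 10 ms raised-cosine ramps. If a mix
exceeds full scale, both ears are rescaled together, preserving the
interaural cues.

## ITD/ILD measurement

ITD is measured where an oscilloscope would measure it — on the
electrodogram pulse trains of a probed electrode (default 20), not on the
audio. Each train becomes a per-cycle amplitude sequence; the estimator
then:

1. **normalizes levels through the MAP** of the probed electrode,
   `(level − T)/(C − T)`: the threshold offset T otherwise appears as a
   binary step at every event-train boundary and biases the correlation;
2. **first-differences** the sequences: plateau-dominated trains give a
   tent-shaped correlation apex on which sub-sample interpolation fails,
   while differencing turns the onset/offset edges into localized bumps;
3. **low-pass filters** the differences (31-tap FIR, cutoff 0.1 cycles
   per sample): a tone not centred on an FFT bin leaves an aliased
   carrier-beat ripple in the envelope near a quarter of the cycle rate
   whose apparent correlation lag is unrelated to the true delay; genuine
   envelope transients live well below the cutoff, and an identical
   linear-phase filter in both ears cannot shift the peak;
4. cross-correlates, upsamples the correlation ×64 by band-limited (FFT)
   interpolation, and refines the peak with a parabolic fit.

This recovers delays to a few microseconds — far below the 2 ms cycle —
because the two ears' sequences are samples of the *same* smoothed
envelope, shifted. The remaining error budget is level quantization
(integer clinical units) and envelope aliasing at the cycle rate.
Degenerate constant trains return ITD 0 with confidence 0. ILD is the RMS
ratio of the raw level sequences in dB (a stated definition, not a claim
about any particular hardware readout); confidence is the normalized
correlation peak.

`recover_azimuth` inverts the scene's sine law, θ = −arcsin(ITD/ITD₉₀),
clamping beyond ±90°. Without an explicit probe it pools the ITD over the
three strongest electrodes common to both ears: the analysis window
spreads any narrowband source across about three bins, so three
electrodes carry independently quantized copies of the same cue and
pooling averages the quantization error down — this matters near ±90°,
where arcsin amplifies microsecond-level ITD error into tens of degrees.
The RMS localization error wraps angle differences to (−180°, 180°].

## Problem sizes and determinism

Tests and the acceptance script use 3 s stimuli at 16 kHz (≈ 1500
stimulation cycles per run at 500 pps), 10⁴ random vectors for the
selection oracle, seven injected offsets (0.05–20 ms) across four strategy
pairings, and five azimuths for the closed loop. All randomness flows
from explicit seeds; identical inputs and seed give byte-identical
outputs.

## Known limitations

- Envelope coding destroys the carrier's fine-structure ITD; only
  envelope (onset/offset/modulation) ITD is represented or measured.
  A perfectly steady, never-ending tone would carry no measurable delay.
- The latency model does not measure real processing time; throughput
  numbers from it are inputs, not results.
- Human-subject localization performance cannot be inferred from the
  closed-loop recovery numbers: the simulator has no binaural neural
  model, and its scenes lack reverberation, head movement and HRTF cues.
- The babble/competing-talker surrogates carry no lexical content;
  speech-intelligibility outcomes are out of reach by construction.
- Inter-ear MAP asymmetries are supported in the chain but the ILD
  statistic compares raw current levels, which is only meaningful when
  the two ears' MAPs are comparable.
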