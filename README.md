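# bicisim — bilateral cochlear-implant sound-coding simulator

Bilateral cochlear-implant (BiCI) users localize sound through two cues:
the interaural time difference (ITD) and interaural level difference (ILD)
between their ears. Whether those cues survive the journey through two
independent sound processors depends on every stage of the coding chain —
filterbank, channel selection, compression, electric mapping, pulse
scheduling — and on how the two ears' outputs are synchronized.
`bicisim` is a desk-scale simulator of that chain for researchers and
audiologists who want to study cue preservation without bench hardware: it
turns binaural audio into synchronized left/right **electrodograms**
(time × electrode × current-level rasters) and measures the binaural cues
that remain in them.

## The coding chain

Audio is framed into 128-sample buffers at 16 kHz (8 ms per frame, one
frame per stimulation cycle). Each frame is Hann-windowed,

```
w(m) = 0.5 [1 − cos(2πm/(L−1))],   m = 0 … L−1,  L = 128,
```

transformed with a 128-point FFT, and reduced to the magnitude-squared
spectrum X²(k) of the 64 positive-frequency bins (125 Hz spacing). A
weight matrix a(n,k) groups bins into N = 22 contiguous channels with
per-channel gains G(n):

```
Y(n) = Σₖ a(n,k) X²(k),    Z(n) = G(n) Y(n).
```

Three strategies then pick which channels stimulate each cycle:

- **CIS** (continuous interleaved sampling) — all active channels;
- **ACE** (advanced combination encoder) — the N-of-M principle: only the
  `n_maxima` (default 8) spectrally strongest of the M active channels;
- **FACE** (formant-based ACE) — up to three channels are first reserved
  for the formants F1–F3, estimated per frame by 28th-order LPC with a
  cycle-to-cycle continuity check (150–200 Hz window); the remaining slots
  follow the ACE maxima rule.

Selected envelopes are normalized and compressed by the loudness-growth
function

```
c(x) = log(1 + b·x) / log(1 + b),   b = 415.995,
```

mapped into each electrode's clinical threshold/comfort range
(`level = T + (C − T)·c(x)`), and scheduled as interleaved biphasic pulses:
within each cycle of 1/pps seconds the electrodes fire sequentially from
base to apex, each pulse occupying 2·pulse_width + gap µs, so no two
pulses ever overlap. The platform caps the aggregate rate at 14 400 Hz
(650 pps per channel with all 22 electrodes active; 125 pps minimum).

Bilaterally, each ear runs its own chain — possibly different strategies —
and the output buffers release each 8 ms block only when **both** ears
have produced it: internal processing-time mismatch (ΔT) is absorbed by
stalling the faster ear, while external interaural offsets (Δλ, from the
direction of arrival) pass through untouched. A scene synthesizer emulates
a 24-loudspeaker ring (15° spacing) with a sine law for the cues
(ITD = 740 µs·sin θ, ILD = 10 dB·sin θ), plus speech-shaped noise, a
babble surrogate and competing-talker interferers at prescribed SNRs.

## Worked example

Play a 440 Hz tone from the −90° speaker (directly left), process both
ears with ACE, and read the cues off the electrodograms:

```bash
bicisim process --tone 440 --azimuth -90 --outdir run
```

```
wrote run/left.csv, right.csv, cues.csv (ITD +716.5 us on electrode 20)
```

The tone lands on electrode 20; its pulse train in the left ear leads the
right by ≈ 717 µs — the scene's 740 µs lateral delay recovered to well
within one 62.5 µs sample period. `run/cues.csv` holds the numbers
(`itd_us`, `ild_db`, `confidence`, throughput), and `run/left.csv` /
`right.csv` are the electrodograms (`time_s,electrode,current_level`).

Closed-loop localization across the speaker ring:

```bash
bicisim localize --azimuths "-90,-45,0,45,90" --outdir loc
```

```
 true_azimuth  est_azimuth  itd_us  ild_db  confidence
       -90.00       -90.00  747.86    1.89        0.99
       ...
RMS localization error: 0.09 degrees
```

Offset preservation (the synchronization contract):

```bash
bicisim sweep --offsets "0.05,1,5" --outdir sw
# 3 offsets swept; worst |error| 10.79 us
```

From Python, the same chain is three calls:

```python
from bicisim import *

scene = BinauralScene(source=SourceSpec(kind="tone", freq=440.0), azimuth=-90.0)
stereo = render_scene(scene, duration=3.0, seed=1)
cfg = StrategyConfig(strategy="ACE")          # 500 pps, 8-of-22
sync = process_bilateral(stereo.channel(0), stereo.channel(1), cfg, cfg, seed=1)
cue = estimate_itd(sync.left, sync.right, electrode=20)
print(f"{cue.itd * 1e6:+.1f} us")             # +716.5 us, left leads
```

## Layout

- `src/bicisim/audio_io.py` — WAV I/O, framing, electrodogram CSV
- `src/bicisim/filterbank.py` — window, FFT power spectrum, channel weights
- `src/bicisim/strategies.py` — CIS/ACE/FACE selection, compression, LPC formants
- `src/bicisim/mapping.py` — MAP validation, current mapping, pulse scheduling
- `src/bicisim/bilateral.py` — per-ear chains, synchronization, offset sweeps
- `src/bicisim/scene_synth.py` — binaural scenes, tones, SSN/babble
- `src/bicisim/analysis.py` — ITD/ILD estimation, localization statistics
- `src/bicisim/cli.py` — `bicisim synth | process | sweep | localize`
- `docs/methods.md` — model assumptions, estimator design, limitations
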