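# Methods

## Signal model and amplitude conventions

All audio is mono, carried as float64 in full-scale units: 16-bit PCM
codes divide by 2^15, so decoded samples lie in [−1, +1]. dBFS is
20·log10(RMS) with full scale 1.0. Writing clamps (never wraps) samples
outside full scale and logs the clip count; round-trip error through the
16-bit quantizer is at most 1 LSB = 2^−15 per sample.

A recorder is modeled as a linear, time-invariant coloration of the
sound field plus an additive DC offset: `y = h_dev * x + c`. The
equalizer estimates `|H_dev|` from paired white-noise recordings and
inverts it with a linear-phase FIR; the DC offset is removed separately
by mean subtraction, because a constant shows up as spurious power in
the first frequency bin and corrupts every index that has no
low-frequency cutoff (ADI, AEI, H, ZCR).

## Spectral estimation

PSDs are Welch averages: Hamming window, segment length equal to the
requested nfft, 50% overlap, density scaling, detrending disabled
(deliberately — a DC offset must remain visible in bin 0). The window
and overlap are conventional defaults; the protocol's output depends on
the *ratio* of two PSDs of the same stimulus estimated identically, so
it is insensitive to this choice. Zero-power bins are floored at
−200 dB so the RMSE metric stays finite on degenerate inputs.

The amplitude-RMSE metric operates on dB spectra (10·log10 PSD):
`sqrt(mean((Amp_ref − Amp_dev)^2))` over the bins of a band. It is
computed on the full grid by default; the validation battery restricts
it to 500 Hz – 15 kHz, where recorder sensitivity is meaningfully
restorable (below ~500 Hz the devices record too little signal for
equalization to recover fidelity, which is also why index analysis
starts at 500 Hz).

## Equalization-curve design

The target magnitude grid is `sqrt(PSD_ref / PSD_dev)` on the Welch grid
with nfft equal to the filter order. The square root converts the power
ratio into an amplitude response; the choice is validated empirically by
the closed-loop tests (a no-sqrt curve would double the correction in dB
and fail them). Practical guards:

* the denominator PSD is floored at 1e−20 (full-scale power) so dead
  bins cannot blow up the ratio;
* the magnitude is capped at +40 dB — a white-noise stimulus should
  never legitimately demand more correction;
* the DC and Nyquist grid points are copied from their interior
  neighbors, since one-sided Welch endpoints are the least reliable
  bins and DC is additionally contaminated by any offset.

Taps come from frequency sampling (scipy's `firwin2`): interpolation of
the magnitude grid onto a dense grid (next power of two above the tap
count), inverse FFT with a linear-phase term, Hamming window. The result
is a Type-I linear-phase FIR: `order + 1` real taps, symmetric about the
midpoint (enforced as a constructor invariant at 1e−9 relative
tolerance). Its group delay is frequency-independent and exactly
`order/2` samples, so delay correction is a deterministic trim: drop the
first `order/2` output samples and keep the output `order/2` samples
shorter than the input (no trailing padding — the take's final
milliseconds are lost). At 48 kHz this is 0.00533 s for order 512,
0.01067 s for 1024 and 0.17067 s for 16,384; a 60 s recording keeps
59.8293 s at the largest order.

The default reference gain is +18 dB: the reference meter records at
0 dB amplifier gain while deployed recorders typically use ~+18 dB, and
amplifying the reference (rather than attenuating the device) leaves
the device's field-optimized gain untouched. In the synthetic battery
the reference gain is set to each profile's own gain (0 dB for the
canonical profiles), i.e. exact compensation of the deployed setting.

Curves serialize to JSON sidecars (taps, design grid, provenance) with
bit-exact round trip, keeping curve computation and application
separable stages.

## Index front-end and parameterization

The spectrogram uses non-overlapping Hamming-windowed frames — zero
overlap is what makes the time resolution the exact reciprocal of the
frequency resolution (FR = fs/nfft = 46.875 Hz, TR = nfft/fs =
0.02133 s at the default nfft 1024, 48 kHz). dB values are relative to
the spectrogram maximum (0 dB), matching the reference R toolchain
behavior for thresholded indices.

Defaults: ACI and DSC on 500–12,000 Hz; ADI/AEI on 500–12,000 Hz with a
−50 dB threshold and a configured band width of 10 Hz — recorded
verbatim in the config, but realized on the FFT grid with an effective
width of at least one bin (46.875 Hz), since sub-bin bands are not
realizable at this resolution; BI on 1700–12,000 Hz; NDSI with
anthropophony 500–1700 Hz and biophony 1700–12,000 Hz (half-open bands,
so the shared 1700 Hz edge belongs to biophony only); H and ZCR on the
full signal. The temporal entropy of H uses the magnitude of the
analytic signal (Hilbert envelope), normalized to a probability mass
over samples; both entropies are divided by the log of their bin count
so H ∈ [0, 1]. Zeros count as positive in the ZCR sign convention.

When recordings equalized at different orders are compared, all series
are truncated to a common duration — the original length minus half the
largest order — so every status is scored on the same time window.

## Statistical gate

Paired index series (n ≥ 3; the battery uses one value per scene) are
compared by a paired Student t-test when Shapiro–Wilk passes on *each
series* and Bartlett passes across the two at α = 0.05, by the paired
Wilcoxon signed-rank test otherwise. Applying Shapiro to each series
rather than to the differences follows the protocol's stated procedure;
the textbook alternative (testing differences) is a known variation and
would only change which test runs, not the H0. All-zero differences are
reported as a degenerate retain-H0 outcome with p = 1 and a flag.
Constant series are treated as failing the normality gate. Monte-Carlo
calibration (1000 Gaussian H0 replicates, n = 9 pairs) puts the
realized type-I error at 0.05 within ±0.02; the Wilcoxon branch is
slightly conservative at n = 9 because of the discreteness of the
signed-rank distribution.

Summaries report, per device and status, the mean amplitude RMSE, the
median of each index's signed percentage error across recordings, and
the total percentage error as the mean of per-recording sums of
*absolute* index errors — signed errors of opposite sign would cancel
while both recordings are biased. No multiple-testing correction is
applied.

## Synthetic study conditions

The generator defines the conditions every test runs under:

* **Stimulus** — Gaussian white noise, 48 kHz, 20 s, −18.74 dBFS RMS
  (scaled exactly), seeded.
* **Device profiles** — parametric sensitivity curves: a sum in dB of an
  overall gain, Gaussian resonance bumps, a sinusoidal ripple and
  first-order low/high rolloffs (−3 dB at the corner), exponentiated and
  realized as an order-1024 linear-phase FIR; a DC offset is added after
  filtering. The three canonical profiles follow the qualitative shapes
  of common recorder families: "SMM-like" (+12 dB bump at 6.5 kHz,
  −9 dB dip at 12 kHz, low-frequency rolloff at 120 Hz, 0.02 DC offset),
  "SET-like" (near-flat, −3 dB at 6 kHz, no offset) and "AM-cased-like"
  (±5 dB ripple with 900 Hz period, rolloff at 150 Hz, 0.015 offset).
  Shapes are parametric stand-ins, not digitized device data; the
  SMM-like deviation was sized to be unambiguously non-flat (≈6.5 dB
  RMSE over 500 Hz–15 kHz before equalization).
* **Scenes** — 60 s by default: white noise low-passed at 1.5 kHz scaled
  to −30 dBFS RMS (anthropophony), 12 chirps/tones of 0.1–0.5 s at
  2–10 kHz with Hann envelopes and ~−28 dBFS peaks (biophony), plus a
  −80 dBFS broadband floor. The battery uses two scenes per run and
  three-scene runs for the paired-test table.

What the generator does *not* emulate: propagation and reverberation,
microphone directivity, wind/rain geophony, nonlinearity and clipping
in device front-ends, and non-stationary device response (temperature,
humidity). Passing tests therefore demonstrate that the pipeline
recovers a linear, time-invariant coloration in the presence of DC
offsets — the mechanism the protocol targets — not that any particular
hardware meets a given error bound in the field.

## Problem sizes and numerical choices

The test battery and acceptance script run on 20 s noise takes, 60 s
scenes, two scenes per profile, order 1024 (plus 512/16,384 where the
analytic values require them), and 1000 Monte-Carlo replicates for the
gate calibration — sizes chosen so a full run completes in tens of
seconds on one core while keeping Welch estimation error near 0.1 dB
per bin and the closed-loop RMSE resolvable to ~0.01 dB. All randomness
derives from explicit integer seeds (spawned via `SeedSequence` where a
run needs several streams); reruns are bit-identical.

Known limitations: equalization cannot restore frequency content the
device never captured (hence the 500 Hz analysis floor); very large
orders trade spectral accuracy against a 0.17 s loss of recording tail
and longer convolutions; the ADI/AEI band width silently widens to one
FFT bin when configured below the grid resolution; absolute SPL
calibration is out of scope — all comparisons are relative to the
reference instrument's recording.
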