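# ecoeq

Recorder frequency-response equalization for passive acoustic monitoring
(PAM), with eco-acoustic index validation.

## The problem

Soundscape ecology compares habitats through summary statistics of field
recordings — eco-acoustic indices such as ACI, ADI, AEI, BI, NDSI, H, DSC
and ZCR. Autonomous recorders (Song-Meter-class, AudioMoth-class devices)
have strongly non-flat sensitivity curves: resonance peaks, case-induced
ripple, poor low-frequency response, and sometimes a DC offset. These
colorations bias the indices by hundreds of percent relative to a
reference class-1 sound level meter, making values incomparable across
devices and studies.

`ecoeq` implements an equalization protocol that aligns each recorder to
a reference meter:

1. **Curve computation.** Both instruments record the same white-noise
   stimulus (48 kHz, −18.74 dBFS RMS, 20 s). The reference take is
   amplified to the recorder's amplifier gain (+18 dB nominally), Welch
   PSDs are estimated with nfft equal to the filter order, and a
   linear-phase FIR of order *n* ∈ {512, 1024, 16384} is designed by
   frequency sampling from the magnitude grid

   `m(f_i) = sqrt( PSD_ref(f_i) / PSD_dev(f_i) )`.

2. **Application.** Field recordings are DC-corrected (mean subtraction),
   convolved with the FIR taps, and the first *n*/2 samples — the
   filter's constant group delay, 0.0053 s at order 512 up to 0.17 s at
   order 16,384 — are trimmed, so a 60 s take keeps 59.83 s at the
   largest order.

3. **Validation.** The residual mismatch is quantified by the amplitude
   RMSE between dB spectra,
   `RMSE_amp = sqrt( (1/n_f) Σ_i (Amp_slm(f_i) − Amp_rec(f_i))² )`,
   by per-index percentage errors
   `(Index_slm − Index_rec) / Index_slm`, and by assumption-gated paired
   tests (Shapiro–Wilk + Bartlett gate choosing between paired Student-t
   and Wilcoxon signed-rank, α = 0.05).

A synthetic module generates every input in silico — white-noise stimuli,
parametric device colorations (peaked, near-flat, rippled) and
soundscape-like scenes mixing low-frequency "anthropophony" noise with
2–10 kHz chirp "biophony" — so the whole protocol runs and is tested
without hardware.

## Worked example

```python
import ecoeq

# paired white-noise takes: reference meter vs a peaked recorder
profile = ecoeq.smm_like_profile()
stimulus = ecoeq.generate_white_noise(seed=1)          # 20 s, -18.74 dBFS
device_take = ecoeq.simulate_device(stimulus, profile)

curve = ecoeq.compute_curve(stimulus, device_take, order=1024, ref_gain_db=0.0)
print(f"group delay: {ecoeq.group_delay_seconds(curve):.4f} s")

# equalize a fresh colored recording and measure the spectral mismatch
fresh = ecoeq.generate_white_noise(seed=2)
colored = ecoeq.simulate_device(fresh, profile)
equalized = ecoeq.equalize(colored, curve)
n = len(equalized)
ref = ecoeq.estimate_psd(fresh.with_samples(fresh.samples[:n]), 1024)
pre = ecoeq.amplitude_rmse(ref, ecoeq.estimate_psd(
    colored.with_samples(colored.samples[:n]), 1024), fmin=500, fmax=15000)
post = ecoeq.amplitude_rmse(ref, ecoeq.estimate_psd(equalized, 1024),
                            fmin=500, fmax=15000)
print(f"amplitude RMSE: {pre:.2f} dB -> {post:.3f} dB")
```

prints

```
group delay: 0.0107 s
amplitude RMSE: 6.47 dB -> 0.003 dB
```

i.e. the 1024-tap filter delays the signal by 512 samples (10.7 ms), and
the recorder's ~6.5 dB spectral deviation from the reference collapses to
essentially zero after equalization.

The same pipeline is available from the shell:

```sh
ecoeq synth --out-dir fixtures --seed 1            # WAV fixtures + manifest
ecoeq curve --ref ref.wav --dev dev.wav --order 1024 -o curve.json
ecoeq apply --curve curve.json field.wav -o field_eq.wav
ecoeq indices recordings/ -o indices.csv
ecoeq validate --out-dir report --seed 1           # full synthetic battery
```

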