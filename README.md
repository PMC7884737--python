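# hemowave

Analysis toolkit for aortic pressure/flow waveforms of the kind recorded in
open-chest large-animal hemodynamics experiments (catheter pressures,
ultrasonic flow probe, ECG), aimed at quantifying arterial wave reflection
and stiffness — for example before and after stent-graft deployment
(endovascular aortic repair, EVAR), which stiffens the covered aortic
segment and enhances the wave reflected back toward the heart.

## What it computes

Given a multichannel recording (ECG, ascending aortic pressure `P`, aortic
flow `Q` and/or velocity `U`, optionally LV pressure) sampled uniformly at
1 kHz:

* **Ensemble beat** — beats aligned at the ECG R apex and averaged over
  eight beats to suppress beat-to-beat fluctuation.
* **Input impedance** — harmonics of the averaged beat,
  `Z(f_k) = P̂(k)/Q̂(k)`; `Z0 = mean(P)/mean(Q)` (afterload) and the
  characteristic impedance `Zc` as the mean modulus over 1–10 Hz.
* **Wave separation** — `Pf = (p + Zc·Q)/2`, `Pb = (p − Zc·Q)/2` with `p`
  the pressure above its diastolic minimum; reflection magnitude
  `RM = |Pb|/|Pf|` and reflection index `RI = RM/(1+RM)` from peak-trough
  amplitudes.
* **Wave intensity** — `WI = (dP/dt)(dU/dt)` from crude sample-to-sample
  differences (mmHg·m/s³): W1 (early-systolic forward peak), NW
  (mid-systolic negative reflected wave), W2 (end-ejection peak).
* **Stiffness** — percent diameter change `100·(Dmax−Dmin)/Dmin`, stiffness
  parameter `β = ln(SBP/DBP)/[(Dmax−Dmin)/Dmin]`, and local Bramwell–Hill
  pulse wave velocity `PWV = √(Ad·PP/(ρ·ΔA))` with ρ = 1060 kg/m³.
* **Statistics** — paired Wilcoxon signed-rank comparisons (asymptotic
  normal approximation without continuity correction; exact enumeration
  available) and Pearson correlation screening with one- and two-sided
  t-distribution p-values, reported as mean ± SE tables.

A synthetic single-tube generator produces pressure/flow/ECG recordings
with known characteristic impedance, reflection coefficient Γ and
round-trip delay 2τ, returning the exact per-sample forward/backward
ground truth — the validation substrate for every estimator above.

## Worked example

```python
from hemowave import (SyntheticConfig, generate_recording, detect_r_peaks,
                      ensemble_average, input_impedance, separate_waves,
                      wave_intensity)

config = SyntheticConfig(gamma=0.4, round_trip_delay_s=0.05,
                         ejection_fraction_of_cycle=0.24,
                         rr_jitter_sd_s=0, noise_sd_pressure_mmhg=0,
                         noise_sd_flow_ml_s=0)
record, truth = generate_recording(config)           # Zc_true = 62.8
seg = detect_r_peaks(record.channels["ecg"], record.fs_hz)
beat = ensemble_average(record, seg)                 # 8-beat ensemble
spectrum = input_impedance(beat)
sep = separate_waves(beat, spectrum.zc_dyn_s_cm5)
wi = wave_intensity(beat)
print(f"Zc = {spectrum.zc_dyn_s_cm5:.1f} dyn·s·cm⁻⁵")
print(f"RM = {sep.rm:.3f}  RI = {sep.ri:.3f}")
print(f"W1 = {wi.w1:.0f}  NW = {wi.nw:.0f} mmHg·m/s³")
```

prints

```
Zc = 61.4 dyn·s·cm⁻⁵
RM = 0.403  RI = 0.287
W1 = 18012  NW = -2725 mmHg·m/s³
```

The tube was built with Zc = 62.8 dyn·s·cm⁻⁵ and Γ = 0.4: the impedance
estimate lands within 2.3 %, the recovered reflection magnitude within
0.003 of Γ, and the mid-systolic negative wave (absent when Γ = 0) marks
the reflected wave returning 50 ms after ejection onset.

There is also a CLI:

```sh
hemowave simulate --config tube.txt rec.csv   # recording + .truth.json sidecar
hemowave analyze rec.csv metrics.json --diameters diameters.csv
hemowave compare metrics_all.csv report       # paired + correlation tables
```

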