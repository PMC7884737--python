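# Methods

## The measurement chain

The toolkit analyzes one recording at a time through a fixed chain:
R-peak detection → eight-beat ensemble averaging → ejection landmarks →
(a) Fourier input impedance, (b) linear wave separation, (c) wave
intensity → scalar summaries; stiffness indices come from scalar
ultrasound diameters plus the ensemble SBP/DBP. Paired statistics operate
on per-subject scalar tables downstream of the chain.

### Ensemble averaging

Beats span consecutive R apexes. Unequal beat lengths are harmonized by
linear resampling to the median RR length before pointwise averaging; the
operation is linear and idempotent on identical beats. Averaging n
independent-noise beats suppresses additive noise by ≈ 1/√n (≈ 0.354 for
the default n = 8), which the suite measures against noise-free twins of
the same synthetic recordings.

The R detector low-passes the ECG (8 ms moving average), squares its
gradient, smooths the energy (15 ms), thresholds at 30 % of the envelope
maximum with a 200 ms refractory period, and refines each detection to the
local ECG apex. This is deliberately minimal — adequate for clean
laboratory signals at SNR ≥ 10 dB, not a clinical QRS detector.

### Input impedance and Zc

The averaged beat is one period of a periodic signal; `Z(k) = P̂(k)/Q̂(k)`
on the discrete Fourier coefficients, with pressure in dyn/cm² and flow in
cm³/s (1 mmHg = 1333.22 dyn/cm², applied by a single conversion utility).
`Zc` is the unweighted arithmetic mean of harmonic moduli whose frequency
lies in the closed band [1, 10] Hz. A continuous-frequency average cannot
be formed from one periodic beat, so the band is interpreted on the beat's
own harmonics (at HR 120 bpm: 2, 4, 6, 8, 10 Hz); harmonic averaging of
moduli is used rather than interpolating a modulus curve. Harmonics whose
flow content falls below 10⁻⁶ of the fundamental are masked and excluded —
this matters because a half-sine ejection of duration Te has exact flow
spectral nulls at (2m+1)/(2Te) Hz, and dividing two near-zero coefficients
would otherwise inject garbage into the band mean.

### Wave separation

With `p = P − min(P)` (the diastolic offset is removed so the constant
baseline is not attributed to the forward wave):

    Pf = (p + Zc·Q)/2,   Pb = (p − Zc·Q)/2

Reconstruction `Pf + Pb + offset = P` and `(Pf − Pb)/Zc = Q` is exact by
construction and asserted to 10⁻⁹ relative. RM and RI use peak-trough
amplitudes of the two traces. Two referencing conventions coexist in the
literature — absolute forward-pressure level versus pulsatile amplitude —
and they give very different |Pb|/|Pf| ratios; this package reports the
traces and the amplitudes and computes RM/RI from amplitudes. The
separation is flow-based (Zc in dyn·s·cm⁻⁵); a velocity-based (ρc)
formulation is intentionally not duplicated here.

### Wave intensity

`WI = (dP/dt)(dU/dt)` with forward sample-to-sample differences at the
native rate and no smoothing by default (optional moving average, logged).
The time-normalized form is the default because the customary printed unit
mmHg·m/s³ is only dimensionally consistent with derivatives, not raw
increments; a `time_normalized=False` switch reproduces raw dP·dU (values
scale by 1/fs²).

Peak windows are phase-based because W1/NW/W2 are defined by systolic
phase, not fixed times: W1 = max over the first 40 % of ejection, W2 = max
from 60 % of ejection to 50 ms past end-ejection, NW = min strictly
between the W1 and W2 peak times. The fractions are overridable. NW is
reported as the trough value (a peak, not an area under the negative
lobe).

On the synthetic family the NW trough has a closed form worth knowing
when interpreting timing: for half-sine ejection, WI ∝ dPf² − dPb² and the
trough of cos²(x−φ) − cos²(x) sits at t = Te/4 + d/2, so the trough time
moves by *half* a change in the reflection delay d, not by the full delay.
The timing test asserts this analytic value.

### Stiffness indices

β = ln(SBP/DBP)/strain with strain = (Dmax−Dmin)/Dmin; percent diameter
change = 100·strain; Bramwell–Hill PWV = √(Ad·PP/(ρ·ΔA)) with circular
cross-sections (one B-mode diameter is measured; no ellipse data), PP in
Pa and ρ = 1060 kg/m³. Ascending-aortic pressures stand in for pressures
at the measurement site when the two differ (as in stent-graft protocols).
Aggregation across subjects must average per-subject values; plugging
group-mean diameters into these nonlinear formulas gives different numbers
(mean of ratios ≠ ratio of means), so no group-level index is ever
computed from group-mean inputs.

### Statistics

Wilcoxon signed-rank: zero differences dropped, mid-ranks for ties,
T = min(W⁺, W⁻), z = (T − n(n+1)/4)/√(n(n+1)(2n+1)/24) with *no*
continuity correction, two-sided normal tail. This convention is the
default because it is the one that yields p = 0.018 for n = 7 uniformly
signed differences, the behavior of common commercial statistics packages;
exact sign-flip enumeration (n ≤ 15) is available behind `method="exact"`
and gives 2/128 ≈ 0.016 for the same data. Pearson correlation p-values
come from t = r√(n−2)/√(1−r²) on n−2 df; the one-sided tail is reported
alongside the conventional two-sided value because small-sample screening
tables are often printed one-sided (r = 0.707, n = 7 → 0.038 one-sided vs
0.076 two-sided). A Spearman alternative (Pearson on ranks) is explicit,
never silently substituted. Descriptives are mean ± SE with SD at
ddof = 1.

## The synthetic generator

A uniform transmission line observed at its inlet: half-sine forward flow
per beat (smooth, zero in diastole, closed-form spectrum), forward
pressure Zc·Qf, one distal reflection site of coefficient Γ at one-way
delay τ. In `single` mode the backward wave is Γ·Pf(t − 2τ) and nothing
re-reflects; in `reverberant` mode the proximal boundary acts as a flow
source (pressure reflection +1) and the full geometric train
Σ Γᵏ·Pf₀(t − 2kτ) accrues to both components, truncated once Γᵏ < 10⁻⁶
(far below any noise floor; the series converges for Γ < 1). Jitter
perturbs beat periods only; noise is additive Gaussian per channel; the
ECG is a 20 ms triangular R complex with apex at each beat onset —
sufficient for the detector without modelling a full PQRST complex. The
LV pressure channel is a crude envelope (tracks aortic pressure during
ejection with 40 ms isovolumic ramps) that exists to exercise dP/dt
summaries, not to model ventricular mechanics.

Defaults portray an anesthetized large-animal preparation: HR 120 bpm,
DBP 90 mmHg, Zc 62.8 dyn·s·cm⁻⁵, peak flow 410 mL/s over 30 % of the
cycle (CO ≈ 4.7 L/min), probe area 3.0 cm² (≈ 19.5 mm aorta), Γ = 0.4,
2τ = 50 ms, RR jitter SD 5 ms, noise SD 0.5 mmHg / 5 mL/s.

Ground-truth recovery tests use a noise-free variant with ejection
narrowed to 24 % of the cycle (Te = 0.12 s) so that the flow spectral
nulls (12.5 Hz and up) stay outside the 1–10 Hz Zc band and all five band
harmonics carry flow energy; with 2τ = 50 ms the reflection-induced
impedance oscillations then average to within a few percent of Zc across
Γ ∈ {0, 0.1, 0.2, 0.4, 0.6}. The monotonicity of |Zc error| in Γ is
demonstrated at 2τ = 20 ms, where all band harmonics sit on the same side
of the oscillation and the bias is one-sided.

Two deliberate physical consequences of the simple construction: in
`single` mode the measured net flow is (1 − Γ)·forward flow, so cardiac
output equals stroke volume × HR only for Γ = 0 or in `reverberant` mode
(where the re-reflection train restores Q = Qf exactly); and the no-loss
tube makes input impedance, not just Zc, exactly flat when Γ = 0.

### What the generator does not emulate

No multi-branch arterial network, no viscoelastic or nonlinear wall, no
frequency-dependent (windkessel) load, no physiologic flow-wave shape
beyond the half-sine stand-in, no respiration or baseline drift, no
catheter-line resonance. Passing recovery tests therefore demonstrates
the *estimators'* correctness on data satisfying the single-tube
assumptions — not that real aortic recordings satisfy them.

## Numerical choices and degenerate inputs

* Unit conversions are ratios of per-dimension factors to a base unit, so
  any path between two units agrees to 10⁻¹².
* Reader rejects non-finite samples by default; opt-in linear
  interpolation logs the filled count. A `time_s` column must be uniform
  to 1 ppm.
* Ejection landmarks: onset at 5 % of peak flow, end at the first fall to
  ≤ max(0, 2 % of peak) after the flow peak — robust to baseline noise and
  overridable.
* Zero mean flow (|Q̂₀| ≤ 10⁻⁶ of the pulsatile scale) raises rather than
  emitting an unbounded Z0; an empty 1–10 Hz band raises from
  `characteristic_impedance` and surfaces as NaN Zc from the spectrum
  constructor.
* Degenerate stiffness inputs (Dmax = Dmin, PP ≤ 0, reversed pressures)
  raise; nothing returns an infinity. β at SBP = DBP is 0 by ln(1) = 0.
* Perfect correlation (|r| = 1) is flagged degenerate with a 0 p-value
  floor rather than dividing by zero.

## Problem sizes

Tests and the acceptance script use 12-beat recordings at 1 kHz
(~6000 samples), 8-beat ensembles of 500-sample beats, 10–20 seeds for
Monte-Carlo noise checks and 2000 replicates for the null-calibration
simulation; the whole suite runs in a few seconds on one core.

## Known limitations

* The R detector assumes upright, large R complexes and will not handle
  pathological or inverted ECG morphologies.
* Zc from one beat's harmonics is sensitive to where the band harmonics
  sample the reflection-induced impedance oscillation; with only five
  harmonics in-band the estimate can be biased by ~10 % for unfavorable
  delay/ejection combinations even on noise-free data.
* The flow↔velocity conversion area is a user input; no default is
  guessed because probe geometry varies.
* Asymptotic Wilcoxon p-values at n = 7 are approximations; the exact
  enumeration differs (0.016 vs 0.018 for uniform signs) and is available
  when the convention is not constrained.
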