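# squatmon

Six-IMU monitoring of resistance-exercise technique: from raw 9-axis
inertial streams to per-repetition classification of squat execution
errors, with a simulated real-time feedback loop.

Body-worn inertial sensing is an attractive way to supervise resistance
training when a human coach cannot watch — remote rehabilitation, home
workouts, or astronaut countermeasure training where the communication
delay rules out live guidance. `squatmon` implements the full processing
chain for a six-sensor montage (both shanks, both thighs, sacrum, sternum,
9-axis IMUs at 100 Hz) and a kinematic squat simulator that generates
labeled trials with analytic ground truth, so the entire pipeline is
testable without hardware.

## The pipeline

1. **Gravity-free reconstruction.** Each sensor's channels are low-pass
   filtered at 20 Hz; a Mahony complementary filter fuses gyroscope
   integration with accelerometer (and optionally magnetometer) direction
   corrections to track the sensor→Earth attitude quaternion q(t). The
   specific force f is projected into the Earth frame, gravity is
   subtracted, and the remainder is expressed back in the sensor frame:

       a₀g = R(q)ᵀ ( R(q) f − g ẑ ),   g = 9.80665 m/s²

   yielding the 36-signal "0g" dataset (3 gravity-free acceleration + 3
   angular-velocity channels × 6 sensors).
2. **Repetition segmentation.** A driver signal (by default the sacrum's
   Earth-vertical 0g acceleration, 2 Hz-smoothed and integrated to a
   drift-corrected vertical velocity) is scanned for valley→peak cycles;
   each repetition is delimited by the zero crossings before the valley
   and after the peak.
3. **Feature extraction.** 375 features per sensor (2250 total) from
   time- and frequency-domain signals: mean, SD, MAD, max, min, SMA,
   energy, IQR, entropy in both domains; Burg AR(4) coefficients and
   axis-pair correlations in time; spectral-peak frequency, power-weighted
   mean frequency, skewness and kurtosis in frequency. Robust scaling
   (median/IQR) and optional recursive feature elimination follow.
4. **Classification.** Five families — decision tree, random forest, KNN,
   RBF SVM, MLP — compared on a stratified 70/30 split and stratified
   10-fold cross-validation, scored with macro-averaged one-vs-rest
   metrics over the six classes

       CO (correct), KOT (knees over toes), VK (valgus knees),
       RB (rounded back), RH (raised heels), SH (shallow squat):

       accuracy    = mean_k (TP_k + TN_k) / N
       specificity = mean_k TN_k / (TN_k + FP_k)
       sensitivity = mean_k TP_k / (TP_k + FN_k)
       precision   = mean_k TP_k / (TP_k + FP_k)

5. **Real-time monitor.** A strictly causal replica of the batch chain
   (single-pass filters, incremental Mahony, online cycle detection)
   classifies each repetition as it completes and reports the 6-class
   probability vector plus corrective advice for every error class above a
   mixed-error threshold (default 0.25) — e.g. KOT together with RH.

Paired-sensor agreement statistics (Pearson R and band-averaged magnitude
squared coherence from Welch cross-spectra) are included for validating
one sensor system against another worn co-located.

## Worked example

```python
from squatmon import (
    SquatSimConfig, SquatLabel, simulate_squat_trial,
    simulate_microgravity, segment_repetitions,
)
from squatmon.pipeline import benchmark_to_dataset, fit_model
from squatmon.squat_synth import make_benchmark
from squatmon.realtime import online_monitor, stream

# one labeled trial: 10 knees-over-toes squats
trial, truth = simulate_squat_trial(
    SquatSimConfig(n_reps=10, label=SquatLabel.KOT, seed=7))
zg = simulate_microgravity(trial)          # 36 gravity-free signals
segs = segment_repetitions(zg)
print(len(segs))                           # 10

# train on the default benchmark (6 classes × 5 subjects × 10 reps)
bench = make_benchmark(n_subjects=5, seed=42)
ds = benchmark_to_dataset(bench)           # 300 × 2250 feature table
model = fit_model(ds, algo="MLP", seed=42)
print(round(model.holdout.accuracy, 3))    # 1.0 on the held-out 30 %

# replay the trial through the causal monitor
events = online_monitor(stream(trial), model)
print(events[0].label.name, events[0].advice)   # KOT ['KOT']
```

The same flow is available from the shell:

```bash
squatmon simulate --label KOT --reps 10 --out kot.csv
squatmon --seed 42 train --algo MLP --out model.bin
squatmon monitor kot.csv --model model.bin        # JSON-line events
```

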