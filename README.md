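# adlmotion

Bilateral upper-limb neuromotor analysis of two activities of daily
living — drinking from a cup and eating with a spoon — from a wearable
device that records surface EMG of six shoulder muscles (PM, AD, MD,
PD, UT, LT) at 1000 Hz alongside an arm-worn IMU orientation stream at
100 Hz, with movement phases annotated from 30 fps video.  The package
is aimed at movement-analysis and rehabilitation researchers who need
reproducible activation-envelope and joint-angle summaries of
multi-cycle ADL recordings, and a simulator to validate the analysis
end to end.

## What it computes

Each recording holds five movement cycles (with 5 s rests) divided into
seven phases: start-to-reach, grasp, transport-to-mouth, in-mouth,
return-to-table, return-to-start, rest.  For a cycle annotated by
boundaries *b₀ < … < b₇* the phase durations are
*dₖ = 100·(bₖ − bₖ₋₁)/(b₇ − b₀)* % of cycle, aggregated across trials
as mean ± sample SD into a phase schedule.

**EMG branch** — 12-bit ADC counts are converted to millivolts around
the bipolar mid-scale, *mV = (count − 2048)·1600/4095*, DC-removed and
full-wave rectified, smoothed with a centred 1000-sample (1 s) moving
average, segmented into cycles, resampled to 9000 points on the
0–100 % cycle axis, averaged within and then across subjects (both in
mV and min–max normalized to 0–1), and summarized as each muscle's
peak amplitude (mV) and peak time (% of cycle).

**IMU branch** — orientation quaternions are decomposed into intrinsic
Z-Y-X Euler angles (yaw, pitch, roll), unwrapped, smoothed with a
100-sample (1 s) moving average, mapped onto anatomically signed axes
(E/F on yaw, ABD/ADD on roll, LR/MR on pitch, with limb-specific
signs), zero-aligned at each cycle's start, resampled to 9000 points,
averaged, and summarized as each motion's signed extremum (degrees) and
its cycle position.

Because the original human recordings are not publicly available, the
package ships a synthetic-recording generator
(`adlmotion.synth`): phase durations drawn around the published task
schedules, EMG as amplitude-modulated Gaussian noise with phase-locked
bursts, angles as raised-cosine lobes — all injected parameters are
stored in JSON sidecars, so every pipeline stage is validated by
parameter recovery.

## Worked example

```sh
adl simulate --task drinking -n 4 -k 5 -s 7 -o demo_ds
adl run demo_ds -o demo_out
adl report demo_out
```

prints (abridged):

```
== Phase schedule ==
 Phases Interval of Mean Time (%) Mean Duration ± SDT (%)
      1               [0.0, 18.1]              18.1 ± 4.0
      2              [18.1, 21.6]               3.5 ± 2.2
      ...
      7             [84.8, 100.0]              15.2 ± 2.0

== EMG peaks ==
         Arm Muscle  Mean Time of Amplitude Peak (%)  Mean Amplitude Contraction Peak (mV)
    Dominant     AD                             41.2                                   0.7
    Dominant     UT                             37.1                                   0.5
    ...

== Joint-motion peaks ==
         Arm Motion  Mean Time of Amplitude Peak (%)  Mean Arm Joint Range of Motion (°)
    Dominant    ADD                             48.2                               -28.7
    Dominant     LR                             45.3                                19.1
    ...
```

Reading the output: this 4-subject simulated drinking cohort spends
most of the cycle in phase 4 (in-mouth, 23.8 % of the cycle here); the
anterior deltoid envelope peaks at 41.2 % of the cycle (0.7 mV),
i.e. in phase 4, and the dominant arm adducts to −28.7° at 48.2 % of
the cycle — all close to the burst/lobe parameters the simulator
injected (AD burst at 42.0 %, adduction lobe of −28.1° at 47.7 %,
slightly attenuated by the 1 s smoother).  `adl check-schedule
drinking` audits the published drinking schedule table and flags its
two internal inconsistencies (phase 4 by 0.1, phase 6 by 0.8).

The same analyses are available as library calls
(`adlmotion.synth.simulate_dataset`, `adlmotion.report.run_pipeline`)
— see `docs/methods.md` for the model details and design choices.

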