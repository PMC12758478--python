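# pvchr — robustness of the PVC-frequency / heart-rate correlation

Frequent premature ventricular complexes (PVCs) are routinely characterised
by the sign of the linear correlation between PVC frequency and heart rate
(HR) in a Holter recording: patients are labelled **positive** (more PVCs at
faster heart rates), **negative**, or **neutral**, and the label informs
beta-blocker and ablation decisions.  `pvchr` is a toolkit for asking how
trustworthy that label is.  It classifies multi-day beat-annotation
recordings under different measurement methodologies — interval durations of
1 hour, 10 minutes, or 1 minute; optional aggregation of minutes by heart
rate at 1-bpm spacing; linear or log-linear scale — and across different
24-hour periods of the same recording, then quantifies the consistency of
the resulting label set.

It is aimed at cardiac-electrophysiology researchers and biostatisticians
working with ambulatory ECG annotations (or, since patient Holter data
rarely travel, with the bundled mechanism-level simulator).

## The statistics at the core

For a set of intervals with mean heart rate $X$ and hourly-scaled PVC count
$Y$:

$$r = \frac{\mathrm{Cov}(X,Y)}{\sigma_X\,\sigma_Y},\qquad
  B = \frac{\mathrm{Cov}(X,Y)}{\sigma_X^2},$$

with a two-sided Wald test $t = r\sqrt{n-2}/\sqrt{1-r^2}$ on $n-2$ degrees
of freedom.  A section is **positive** if $r>0,\ p<.05$, **negative** if
$r<0,\ p<.05$, **neutral** otherwise.  Day-to-day consistency of the daily
labels $c$ is measured by the normalized Shannon entropy

$$H = -\frac{1}{\log_2 3}\sum_{c} p(c)\,\log_2 p(c) \in [0,1],$$

which is 0 exactly when every day gets the same class, and by the
probability that two 24-hour sections drawn without replacement agree.
Rhythm structure is described by NIB values (the number of intervening
sinus beats between consecutive PVCs; NIB 1 is bigeminy); a stable NIB-$k$
rhythm with blocked compensatory pauses obeys the analytical law
$\text{PVCs/min} = \mathrm{HR}/(k+1)$.

The simulator generates multi-day records (circadian HR variation,
autocorrelated minute-scale jitter, 30-second noise dropouts) under four
known PVC mechanisms — fixed-NIB stable rhythms, logistic HR-dependent
ectopy, a Gaussian "hump" giving an inverted-parabola PVC-HR relationship,
and pure parasystole (a protected ectopic pacemaker, which produces a
*negative* PVC-HR correlation because the non-refractory fraction of time
shrinks as HR rises).

## Worked example

A single mechanism can flip its classification between days purely because
the two days sample different parts of a nonlinear PVC-HR relationship:

```python
from pvchr import *

mech = MechanismConfig(kind=MechanismKind.HUMP_HR, hump_peak_hr=81,
                       hump_width=12, hump_max_prob=0.5)
spec = SimulationSpec(
    record_id="DEMO", days=2, mechanism=mech,
    hr_profile=(CircadianProfile(64, 8, jitter_sd=2),    # day below the peak
                CircadianProfile(98, 8, jitter_sd=2)),   # day above the peak
    seed=4,
)
rec = simulate_record(spec)
print(f"{rec.record_id}: {rec.n_beats} beats, PVC burden {rec.pvc_burden:.1%}")

for res in classify_record(rec, (Methodology(60.0),)):
    day = "whole record" if res.day_index < 0 else f"day {res.day_index}"
    print(f"{day:>12}:  r={res.r:+.3f}  B={res.slope_B:+.2f}  "
          f"p={res.p_value:.2e}  ->  {res.label.value}")

labels = [r.label.value for r in classify_record(rec, (Methodology(60.0),))
          if r.day_index >= 0]
print("daily labels:", labels)
print(f"normalized entropy: {entropy_normalized(labels):.3f}")
```

prints

```
DEMO: 233331 beats, PVC burden 16.0%
       day 0:  r=+0.929  B=+62.61  p=0.00e+00  ->  positive
       day 1:  r=-0.924  B=-73.07  p=0.00e+00  ->  negative
whole record:  r=+0.271  B=+6.70  p=8.40e-50  ->  positive
daily labels: ['positive', 'negative']
normalized entropy: 0.631
```

The same patient is confidently positive on one day and confidently
negative on the next ($|r| > 0.9$ both days); the slope $B$ is in PVCs per
hour per bpm.  The nonzero entropy flags the inconsistency that a
single-day recording would hide.

A command-line pipeline wraps the same library:

```sh
pvchr simulate --preset cohort --n-records 48 --days 2 --seed 0 --out recs/
pvchr classify recs/SYN*.csv --out classifications.csv
pvchr consistency classifications.csv --out-prefix cohort
pvchr plot recs/SYN000.csv --kind nib --out-prefix fig
```

Input records are two-column CSV (`time_s,label` with N/V labels, noise
mask as a `start_s,end_s` sidecar); plain-text WFDB annotation exports are
also accepted (`--format wfdb-text`).

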