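# hrvguide

Tools for resting heart-rate-variability (HRV) measurement workflows and
HRV-guided day-to-day exercise prescription, built around beat-to-beat
RR-interval recordings such as those exported by a reference ECG or a
Bluetooth chest-strap app.

`hrvguide` is aimed at sport scientists and developers validating an HRV
measurement route against a gold standard, and at anyone building
day-to-day training logic on daily LnrMSSD monitoring. It covers:

* **RR-interval I/O** — plain-text/CSV RR files (milliseconds, one beat
  per line, `# key=value` headers) and daily LnrMSSD history CSVs.
* **Preprocessing** — trimming the one-minute stabilization period;
  artifact/ectopic-beat detection by the 0.25 s deviation-from-mean rule;
  replacement by cubic-spline interpolation in cumulative time; and the
  acceptance gate that rejects recordings with ≥ 20% corrected beats.
* **Time-domain HRV** — rMSSD, the root mean square of successive
  RR-interval differences, `rMSSD = sqrt(mean((RR_{i+1} − RR_i)^2))`, its
  natural logarithm LnrMSSD, and mean HR, over the standard 5-minute
  window and the ultra-short first minute.
* **Method-agreement statistics** — Shapiro–Wilk normality gate, paired
  comparisons with Bonferroni scaling, Cohen's d (on paired differences)
  with interpretation bands, Pearson r with bands, ICC(2,1) with an
  F-based confidence interval, SEM (absolute and % of the group mean),
  the minimal detectable change `MDC = 1.96 × SEM × √2`, and Bland–Altman
  bias with 95% limits of agreement.
* **Training engine** — a one-month baseline profile defining the
  smallest worthwhile change zone `SWC = mean ± 0.5 × SD` of daily
  LnrMSSD; the trailing 7-day rolling average; the day-to-day decision
  rule (inside SWC → high intensity, outside → low then rest); and
  star/level gamified progression over a 12-week, 3-sessions-per-week
  programme.
* **Synthetic data** — a seeded generator of paced-breathing resting
  recordings (RSA sinusoid + calibrated Gaussian beat noise), planted
  artifacts with ground truth, paired-device jitter, and daily LnrMSSD
  histories, so every stage is testable end to end without any
  recordings on disk.

## Worked example

Simulate a 6-minute resting recording with a few artifacts, clean it,
and analyze both windows:

```console
$ hrvguide simulate --out rest.rr --seed 7 --artifact-rate 0.03
INFO wrote 413 beats (370 s) to rest.rr
$ hrvguide clean rest.rr --out rest_clean.rr
INFO corrected 11/346 beats (3.2%): accepted
$ hrvguide analyze rest_clean.rr
window  n_beats  rmssd_ms  ln_rmssd  mean_rr_ms  mean_hr_bpm
  1min       68 52.146578  3.954059  894.451925    67.080184
  5min      335 49.813852  3.908293  896.347906    66.938294
```

3.2% of beats deviated more than 0.25 s from the recording mean and were
replaced by the cubic spline — well below the 20% rejection gate. The
ultra-short (1-min) LnrMSSD of 3.95 sits close to the 5-min value of
3.91: the agreement that makes one-minute measurements practical for
daily monitoring.

Prescribe a 12-week programme from a 120-day daily history (the first 30
days form the baseline):

```console
$ hrvguide simulate --out history.csv --seed 7 --history-days 120
$ hrvguide prescribe --history history.csv --out decisions.csv
INFO SWC [3.834, 4.001] from 30 baseline days; 36 decisions written to decisions.csv
$ head -4 decisions.csv
date,rolling_avg,in_swc,intensity,session_id,level
2023-02-01,3.869972566012113,True,low,1.0,1
2023-02-03,3.8292270661239747,False,low,2.0,1
2023-02-06,3.9020407878581693,True,high,3.0,1
```

The first training day is always low intensity; thereafter the 7-day
rolling LnrMSSD against the SWC zone drives each decision.

A full two-device validation study (paired ECG/app recordings, two
trials per position for 20 subjects) runs with:

```console
$ hrvguide simulate --out data/ --seed 4 --study-subjects 20
$ hrvguide validate --input data/ --out report/
```

producing per-position device-agreement tables, 1-min vs 5-min duration
comparisons, and trial-retrial reliability (ICC, SEM%, MDC) as CSVs plus
a text summary.

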