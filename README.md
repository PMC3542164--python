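# robustqc

Robust univariate outlier screening for quality-indicator data, and the
Monte Carlo machinery to calibrate it.

Large indicator databases (hospital nursing-quality registries, adverse-event
rates, utilisation measures) screen every incoming quantitative measure for
potential outliers before aggregation: each flagged value goes back to the
reporting site for confirmation, so a screen that over-flags wastes real staff
time at both ends. The standard screens are distance-based with a robust
scale, and most indicator distributions are strongly right-skewed — which is
exactly where the screens disagree. `robustqc` implements the three common
univariate rules, handles the degenerate zero-inflated indicators that break
them, and quantifies their false-alarm behaviour on skewed data.

## The screens

For observations x₁,…,xₙ of one indicator, with x̄ the sample mean:

* **IQR screen** — scale σ̂ = (Q₃ − Q₁)/1.355; flag when |xᵢ − x̄|/σ̂ ≥ 2.24.
* **MAD screen** — scale σ̂ = median|xᵢ − median(x)|/0.666; same rule.
* **MCD screen** — location T and scatter C from the h-observation subset
  (h = ⌊(n+2)/2⌋ by default) of minimal variance; in one dimension the optimal
  subset is a contiguous window of the sorted sample, found exactly. C is
  rescaled by a consistency factor so it estimates σ² under normality; flag
  when the squared robust distance D² = (xᵢ − T)²/C ≥ 5.02.

The divisors 1.355 and 0.666 make IQR and MAD consistent for the normal σ;
2.24 is the N(0,1) quantile at 0.9875 and 5.02 the χ²₁ quantile at 0.975, so
each screen targets a 2.5% flag rate on clean normal data. A screen whose
scale estimate degenerates to zero (e.g. an indicator that is mostly exact
zeros) reports `status="failed"` with no flags instead of guessing.

The Monte Carlo studies draw Gamma(α, β) samples with fixed mean μ = αβ = 8
and skewness γ = 2/√α from 0 (normal) to ≈3.5, optionally planting gross
outliers from N(60, 9/4), and summarise per-screen flag rates, detection
rates and false-alarm rates over replicates.

## Worked example

```python
from robustqc import SimulationConfig, run_false_alarm_study

config = SimulationConfig(skewness_presets=(0.0, 1.0, 2.0, 3.0),
                          replicates_R=100, seed=0)
cells = run_false_alarm_study(config)
```

(`examples/false_alarm_vs_skewness.py`) prints:

```
skewness   IQR      MAD      MCD     (mean flagged proportion, target 0.025)
  0.000  0.0249   0.0226   0.0260
  1.000  0.0348   0.0354   0.0751
  2.000  0.0603   0.0737   0.2272
  3.000  0.0874   0.1315   0.3511
```

Each number is the mean proportion of clean n = 1000 observations flagged,
i.e. the false-alarm rate. All three screens hold their ≈2.5% target on
normal data; as skewness grows the MCD screen inflates fastest (flagging 35%
of clean data at γ = 3), MAD follows, and IQR drifts least. The other
examples screen a small CSV of indicators end-to-end
(`examples/screen_indicator_table.py`) and measure detection of planted gross
outliers (`examples/planted_outlier_detection.py`) — all screens detect 100%
of values planted at 60, and differ only in how many clean values they drag
along.

There is also a thin CLI for screening tabular data and running the studies:

```
robustqc screen --input indicators.csv --output-dir reports/
robustqc simulate-false-alarm --replicates 500 --output-dir study/
```

Input CSVs are tidy tables with columns `unit_id, indicator, value`.

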