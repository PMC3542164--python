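"""Screen a small indicator table for potential outliers with all three rules.

Builds a CSV of two simulated indicators — a well-behaved one with a gross
data-entry error planted at 60, and a zero-inflated rare-event indicator —
then runs the IQR, MAD and MCD screens and prints the summary report.
"""

import tempfile
from pathlib import Path

import numpy as np

from robustqc import (
    DistributionSpec,
    IndicatorSample,
    PlantSpec,
    gamma_params_from_skewness,
    plant_outliers,
    read_indicator_table,
    screen,
    simulate_indicator,
    write_sample_csv,
    write_screening_report,
)

workdir = Path(tempfile.mkdtemp())

falls = plant_outliers(
    simulate_indicator(
        DistributionSpec.gamma(gamma_params_from_skewness(8.0, 1.0)), 499, seed=1
    ),
    PlantSpec(count_m=1, outlier_mean=60.0),
    seed=2,
)
rare_events = simulate_indicator(
    DistributionSpec.zero_inflated_gamma(
        0.8, gamma_params_from_skewness(8.0, 2.0)
    ),
    500,
    seed=3,
)
table = workdir / "indicators.csv"
write_sample_csv({"total_falls": falls, "vesicant_piv": rare_events}, table)

samples = read_indicator_table(table)
results = {
    name: {m: screen(sample, m) for m in ("iqr", "mad", "mcd")}
    for name, sample in samples.items()
}
rows = write_screening_report(
    results, samples, workdir / "summary.csv", workdir / "flags.csv"
)

print(f"{'indicator':<14} {'method':<6} {'flagged':>7} {'rate':>7} status")
for row in rows:
    print(
        f"{row.indicator:<14} {row.method:<6} {row.n_flagged:>7} "
        f"{row.flag_rate:>7.4f} {row.status}"
    )

planted_value = falls.values[falls.truth_labels][0]
stat = results["total_falls"]["iqr"].statistics[
    np.argmax(samples["total_falls"].values == planted_value)
]
print(
    f"\nThe planted error ({planted_value:.1f}) scores |x - mean|/sigma_hat = "
    f"{stat:.1f} on the IQR screen, far above the 2.24 cutoff, so every method "
    "flags it. The zero-inflated indicator has a zero median and zero MAD, so "
    "the MAD and MCD screens report 'failed' (they cannot estimate scale) "
    "rather than flagging arbitrarily; with 80% zeros even the quartiles "
    "coincide and the IQR screen fails too."
)
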