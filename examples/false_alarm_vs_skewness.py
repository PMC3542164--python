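"""How the false-alarm rate of each screen inflates with skewness.

Runs a reduced false-alarm study (R = 100 replicates of n = 1000) on a small
skewness grid and prints the mean flagged proportion per screen. On clean
data every flag is a false alarm, so a well-calibrated screen should stay
near its 2.5% design target.
"""

from robustqc import SimulationConfig, run_false_alarm_study

config = SimulationConfig(
    skewness_presets=(0.0, 1.0, 2.0, 3.0),
    replicates_R=100,
    seed=0,
)
cells = {
    (c.preset_skewness, c.method): c for c in run_false_alarm_study(config)
}

print("skewness   IQR      MAD      MCD     (mean flagged proportion, target 0.025)")
for preset in config.skewness_presets:
    rates = [cells[(preset, m)].mean_flag_rate for m in ("iqr", "mad", "mcd")]
    print(f"{preset:7.3f}  {rates[0]:.4f}   {rates[1]:.4f}   {rates[2]:.4f}")

print(
    "\nAt skewness 0 all three screens sit near the nominal 2.5%. As skewness "
    "grows the MCD screen inflates fastest (its chi-squared cutoff assumes "
    "normality), the MAD follows, and the IQR drifts least — so on skewed "
    "indicators the MCD would send several times more units for manual "
    "recheck than the ad-hoc rules, at the same nominal level."
)
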