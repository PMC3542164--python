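"""Can the screens find true outliers hidden in skewed data?

Per replicate, 990 clean Gamma(mean 8) draws are mixed with 10 gross
outliers from Normal(60, 9/4) — values of a different regime entirely, as a
systematic reporting error would produce. A reduced study (R = 100) prints,
per screen, the detection rate among the planted values and the false-alarm
rate among the clean ones.
"""

from robustqc import PlantSpec, SimulationConfig, run_planted_outlier_study

config = SimulationConfig(
    skewness_presets=(1.0, 3.0),
    replicates_R=100,
    seed=0,
    plant=PlantSpec(count_m=10, outlier_mean=60.0, outlier_variance=9.0 / 4.0),
)
cells = run_planted_outlier_study(config)

print("skewness method  detected  false-rate  overall")
for c in cells:
    print(
        f"{c.preset_skewness:7.1f} {c.method:>6}   {c.detection_rate_planted:.3f}"
        f"     {c.false_rate_clean:.4f}   {c.overall_rate:.4f}"
    )

print(
    "\nEvery screen finds all 10 planted outliers in every replicate "
    "(detection 1.000): gross errors are easy. The cost differs: at skewness "
    "3 the MCD screen also flags over a third of the *clean* observations, "
    "versus under a tenth for the IQR screen — the overall column is the "
    "per-replicate identity (10*detected + 990*false)/1000."
)
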