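"""Build the 52-feature dyad-level table for a small cohort.

Each conversation segment contributes one row: 36 baseline-normalized
individual features (mean and absolute difference of the two
participants' 18 per-participant features) plus 16 synchrony features
(DTW distance, nonlinear interdependence, band coherence and zero-lag
correlation for HR, respiration rate, EDA and temperature).
"""

from dyadaffect import build_dataset, default_effect_config, generate_cohort

cohort = generate_cohort(3, default_effect_config(), seed=5)
ds = build_dataset(cohort)

print(f"{len(ds.df)} rows (dyads x 4 scenarios), "
      f"{len(ds.feature_columns)} features")
cols = ["dyad_id", "label", "mean_of_mean_hr", "mean_of_n_scr",
        "mean_of_delta_temp", "xcorr_hr"]
print(ds.df[cols].round(2).to_string(index=False))

# mean_of_mean_hr / mean_of_n_scr rise in the high-arousal rows (values
# are baseline-subtracted, so ~0 means "like the resting baseline");
# xcorr_hr and mean_of_delta_temp are higher in positive-valence rows,
# where the generator couples the two participants more strongly.
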