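"""Extract per-pixel signal features and fold in the control region.

Shows the three feature families on one pixel (Fourier coefficients of
the curve, the fitted relaxation decay, the lumped bioheat coefficients)
and what control integration does to the baseline feature.
"""

from adtherm import (
    CohortConfig,
    Protocol,
    extract_features,
    integrate_control,
    simulate_cohort,
)

config = CohortConfig(
    n_dogs=4,
    masses_per_dog_probs=(1.0, 0.0, 0.0),
    malignancy_prevalence=0.5,
    exact_prevalence=True,
    protocol=Protocol(grid_side=5),
    rng_seed=7,
)
records = simulate_cohort(config)
site, control = extract_features(records, config.protocol)
print(f"{len(site.data)} site pixel rows x {len(site.feature_columns)} features")

row = site.data.iloc[0]
print(f"pixel (0,0) of {row.mass_id} ({row.label}):")
print(f"  decay_lambda     = {row.decay_lambda:.4f} 1/s   (relaxation rate)")
print(f"  pennes_lambda_p  = {row.pennes_lambda_p:.4f} 1/s (full-curve fit)")
print(f"  fourier_relax_a1 = {row.fourier_relax_a1:+.4f} C  (1st cosine harmonic)")
print(f"  baseline_c       = {row.baseline_c:.2f} C       (resting temperature)")

integrated = integrate_control(site, control)
means = integrated.data.groupby("label")["baseline_c"].mean()
print("\nafter control integration (site minus control-grid mean):")
for label, value in means.items():
    print(f"  mean baseline difference, {label:9s}: {value:+.3f} C")
# benign masses sit near 0 (site matches control); malignant masses keep
# their ~+1 C resting elevation -- the effect the classifier feeds on.
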