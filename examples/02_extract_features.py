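"""Extract the 110-feature radiomic texture vector from a synthetic cohort.

Each patient yields 55 features per modality image (15 histogram, 20
gray-level co-occurrence, 8 gray-level difference, 12 Fourier spectral)
concatenated T2W-then-ADC into 110 named features.
"""

from radstrat import CohortSpec, extract_table, generate_cohort

cohort = generate_cohort(CohortSpec(n_high=14, n_lower=54, image_size=64, seed=42))
table = extract_table(cohort)

print(f"feature table: {table.shape[0]} patients x {table.shape[1] - 2} features"
      " (+ label + reader score)")
print("\nfirst feature of each family (first patient):")
for name in ("t2w_hist_mean", "t2w_glcm_energy", "t2w_gldm_mean", "t2w_fft_spectral_entropy"):
    print(f"  {name:28s} {table.iloc[0][name]:.4f}")

by_class = table.groupby("label")["adc_hist_mean"].mean()
print("\nmean ADC-modality intensity by risk class (the planted contrast):")
for label, value in by_class.items():
    print(f"  {label:6s} {value:.1f}")
print("lower ADC intensity in the high-risk class mirrors the association of "
      "restricted diffusion with tumor aggressiveness.")
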