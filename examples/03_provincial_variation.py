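"""Provincial heterogeneity: coverage-EC gaps and their correlation.

Uses the province-varying preset (logit-scale province effects on the
screening and quality probabilities) to emulate a health system whose
provinces perform very differently.
"""

from htcover import GenerationMode, assess, generate_cohort, province_varying_preset

preset = province_varying_preset(n_persons=150_000, n_provinces=76)
result = assess(generate_cohort(preset, GenerationMode(mode="stochastic", seed=1)))

nat = result.national
print(result.provinces.head(10).to_string(index=False))
print(f"\nprovinces:                  {nat.n_provinces}")
print(f"provincial mean EC:         {100 * nat.provincial_mean_ec:.1f}%")
print(f"provincial EC range:        {100 * nat.provincial_min_ec:.1f}%"
      f" - {100 * nat.provincial_max_ec:.1f}%")
print(f"coverage-EC gap (min/mean/max): {100 * nat.gap_min:.1f}% /"
      f" {100 * nat.gap_mean:.1f}% / {100 * nat.gap_max:.1f}%")
print(f"Pearson r (coverage vs EC): {nat.pearson_r:.3f}  (p = {nat.p_value:.2g})")

# EC never exceeds coverage in any province (Q <= 1), the gap is the
# effectiveness shortfall among the screened, and coverage and EC are
# strongly linearly related because coverage dominates the product Q x U.
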