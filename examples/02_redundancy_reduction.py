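"""Detect and merge a planted near-duplicate item with Unique Variable
Analysis (weighted topological overlap + adaptive alpha + one-factor merge)."""

from psychnet import SyntheticSpec, generate_factor_data, run_uva

spec = SyntheticSpec(
    n_respondents=600, n_factors=3, items_per_factor=5,
    loading=0.7, factor_corr=0.2, seed=7,
    redundancy_pairs=(("3", 0.15),),  # clone of item 3, latent noise sd 0.15
)
data, _ = generate_factor_data(spec)
reduced, report = run_uva(data)

print(f"items: {data.n_items} -> {reduced.n_items} after {report.rounds} round(s)")
print(f"corrected alpha: {report.alpha_corrected:.4f} "
      f"over {len(report.pvalues)} overlap tests")
print("merged composites:", report.merge_map)
# Expected output: exactly the planted pair ('3', '3r') collapses into the
# composite '3_3r'; its column now holds the one-factor score of the pair.
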