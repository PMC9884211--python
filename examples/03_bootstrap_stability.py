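"""Bootstrap exploratory graph analysis: how stable are the detected
dimensions under resampling?"""

from psychnet import (
    EgaSettings,
    SyntheticSpec,
    bootstrap_ega,
    generate_factor_data,
    median_network,
    spinglass_partition,
    stability_report,
)

spec = SyntheticSpec(
    n_respondents=800, n_factors=3, items_per_factor=5,
    loading=0.7, factor_corr=0.2, seed=3,
)
data, _ = generate_factor_data(spec)
settings = EgaSettings(correlation="pearson", restarts=5, n_lambda=60)
ens = bootstrap_ega(data, B=30, seed=11, settings=settings)

med = median_network(ens)
part = spinglass_partition(med, seed=11, restarts=10)
rep = stability_report(ens)

print(f"median network: {med.n_edges} edges; {part.n_communities} communities")
print("community-count distribution:", rep.ncomm)
print("lowest item stability:", min(rep.item_stability.values()))
print("structural consistency per dimension:", rep.structural_consistency)
# With this well-separated structure the modal community count equals the
# planted 3, every item sits in its community in ~all replicates, and each
# dimension's exact item set recurs in most replicates.
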