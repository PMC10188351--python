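"""Age-expression correlation screen across a multi-dataset collection.

Per dataset (case samples only) each gene is Spearman-correlated with age;
genes are kept when the correlation sign agrees in all datasets but one, and
per-dataset p-values are combined with the direction-aware Stouffer method.
"""

from geroscreen import SimulationConfig, simulate_collection
from geroscreen.age_correlation import (
    per_dataset_correlations,
    screen_age_correlated,
    sign_lists_per_dataset,
    significant_gene_lists,
    upset_counts,
)

cfg = SimulationConfig.default(seed=42)
collection, truth = simulate_collection(cfg)

combined = screen_age_correlated(collection, alpha=0.05)  # min_support = 11 of 12
lists = significant_gene_lists(combined)
print(f"{len(lists['positive'])} genes positively sign-consistent in >= 11/12 datasets,"
      f" {len(lists['positive_significant'])} significant (combined p < 0.05)")
print(f"{len(lists['negative'])} negatively sign-consistent,"
      f" {len(lists['negative_significant'])} significant")
print("\ntop of the combined table (smaller combined_p = stronger age trend):")
print(combined.head(5).to_string(index=False))

# UpSet-style exact intersection counts of the per-dataset positive lists
per_ds = per_dataset_correlations(collection)
upset = upset_counts(sign_lists_per_dataset(per_ds)["positive"], min_degree=11)
full = upset[upset["degree"] == 12]
print(f"\ngenes positively correlated in all 12 datasets: "
      f"{int(full['count'].sum()) if len(full) else 0}")
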