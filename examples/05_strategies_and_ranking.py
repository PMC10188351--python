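"""The three target-selection strategies and the transparent ranking.

S1: significantly positively age-correlated genes whose high expression is
significantly associated with worse survival (inhibition candidates).
S2: significantly negatively age-correlated genes whose low expression is
associated with worse survival (activation candidates).
S3: all significantly age-correlated genes intersected with an external
aging-target list. Candidates are then ranked by an equal-weight sum of
scaled evidence channels.
"""

from pathlib import Path

from geroscreen import SimulationConfig, simulate_collection
from geroscreen.age_correlation import screen_age_correlated
from geroscreen.expression_meta import combine_de, de_collection
from geroscreen.strategy_engine import (
    build_evidence,
    rank_targets,
    read_gene_list,
    strategy1,
    strategy2,
    strategy3,
)
from geroscreen.survival_screen import screen_survival

cfg = SimulationConfig.default(seed=42)
collection, truth = simulate_collection(cfg)

combined = screen_age_correlated(collection)
sig = sorted(combined.loc[combined["significant"]
                          & combined["sign"].isin(["positive", "negative"]), "gene"])
surv = screen_survival(collection.get("DS01"), sig)
meta_de = combine_de(de_collection(collection))

s1 = strategy1(combined, surv)
s2 = strategy2(combined, surv)
aging_list = read_gene_list(Path(__file__).parent / "aging_targets_demo.txt")
s3 = strategy3(combined, aging_list)

for res in (s1, s2, s3):
    print(f"{res.strategy_id}: {len(res.genes)} genes -> {', '.join(res.genes[:8])}"
          + (" ..." if len(res.genes) > 8 else ""))
print("\nS1 provenance (which cohorts fired):")
print(s1.provenance.head(5).round(6).to_string(index=False))

candidates = sorted(set(s1.genes) | set(s2.genes) | set(s3.genes))
ranked = rank_targets(candidates, build_evidence(combined, meta_de, surv))
print("\ntop-ranked candidates (equal-weight scaled evidence; score in [0,1]):")
print(ranked.head(5).round(4).to_string(index=False))
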