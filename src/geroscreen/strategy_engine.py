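"""Target-selection strategies and a transparent weighted ranking.

Three deterministic set-algebra strategies over the upstream screens:

* **S1** — genes significantly positively age-correlated whose *high*
  expression is significantly associated with worse survival in at least one
  age cohort (inhibition candidates).
* **S2** — genes significantly negatively age-correlated whose *low*
  expression is significantly associated with worse survival in at least one
  cohort (activation candidates).
* **S3** — all significantly age-correlated genes (both signs) intersected
  with an externally supplied list of aging-associated target symbols
  (case-insensitive match, exact matches reported in provenance).

``rank_targets`` is a deliberately transparent weighted-sum ranking over
user-named evidence channels (minmax-scaled and oriented per channel). It is
a configurable stub, not a reimplementation of any proprietary multi-model
AI scoring engine.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .datasets import ValidationError

logger = logging.getLogger("geroscreen")


@dataclass
class StrategyResult:
    """A named gene set with per-gene provenance of the criteria that fired."""

    strategy_id: str
    genes: list[str]
    provenance: pd.DataFrame


def _significant_by_sign(combined_corr: pd.DataFrame, sign: str) -> pd.DataFrame:
    mask = (combined_corr["sign"] == sign) & combined_corr["significant"]
    return combined_corr.loc[mask]


def _survival_hits(survival_results: pd.DataFrame, direction: str) -> pd.DataFrame:
    mask = survival_results["significant"] & (survival_results["direction"] == direction)
    return survival_results.loc[mask]


def _survival_strategy(strategy_id: str, combined_corr: pd.DataFrame,
                       survival_results: pd.DataFrame,
                       corr_sign: str, harm_direction: str) -> StrategyResult:
    corr_hits = _significant_by_sign(combined_corr, corr_sign).set_index("gene")
    surv_hits = _survival_hits(survival_results, harm_direction)
    rows = []
    for gene in sorted(set(corr_hits.index) & set(surv_hits["gene"])):
        cohorts = sorted(surv_hits.loc[surv_hits["gene"] == gene, "cohort"])
        rows.append({
            "gene": gene,
            "corr_sign": corr_sign,
            "combined_p": corr_hits.loc[gene, "combined_p"],
            "survival_direction": harm_direction,
            "cohorts": ";".join(cohorts),
        })
    prov = pd.DataFrame(rows, columns=["gene", "corr_sign", "combined_p",
                                       "survival_direction", "cohorts"])
    return StrategyResult(strategy_id=strategy_id,
                          genes=list(prov["gene"]), provenance=prov)


def strategy1(combined_corr: pd.DataFrame, survival_results: pd.DataFrame) -> StrategyResult:
    """Positively age-correlated (significant) AND high expression worse in >= 1 cohort."""
    return _survival_strategy("S1", combined_corr, survival_results,
                              "positive", "high_worse")


def strategy2(combined_corr: pd.DataFrame, survival_results: pd.DataFrame) -> StrategyResult:
    """Negatively age-correlated (significant) AND low expression worse in >= 1 cohort."""
    return _survival_strategy("S2", combined_corr, survival_results,
                              "negative", "low_worse")


def strategy3(combined_corr: pd.DataFrame, aging_genes) -> StrategyResult:
    """Significant age-correlated genes (both signs) intersected with an aging list.

    Symbols are matched case-insensitively; provenance records whether each
    match was exact or required case folding, and the gene's correlation sign.
    """
    aging_genes = [g.strip() for g in aging_genes if str(g).strip()]
    if not aging_genes:
        raise ValidationError("strategy 3 requires a non-empty aging gene list")
    sig = combined_corr.loc[combined_corr["significant"]
                            & combined_corr["sign"].isin(["positive", "negative"])]
    by_upper = {str(g).upper(): g for g in sig["gene"]}
    rows = []
    for symbol in aging_genes:
        hit = by_upper.get(symbol.upper())
        if hit is None:
            continue
        rows.append({
            "gene": hit,
            "aging_list_symbol": symbol,
            "match": "exact" if symbol == hit else "case_fold",
            "corr_sign": sig.set_index("gene").loc[hit, "sign"],
        })
    prov = pd.DataFrame(rows, columns=["gene", "aging_list_symbol", "match", "corr_sign"])
    if len(prov):
        prov = prov.sort_values("gene", kind="mergesort").reset_index(drop=True)
    else:
        logger.warning("strategy 3: no overlap between significant genes and aging list")
    return StrategyResult(strategy_id="S3", genes=list(prov["gene"]), provenance=prov)


def read_gene_list(path) -> list[str]:
    """One symbol per line; blank lines and '#' comments ignored."""
    symbols = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            symbols.append(line)
    return symbols


@dataclass
class Channel:
    """One evidence channel for ranking: a named numeric per-gene score."""

    name: str
    weight: float
    higher_is_better: bool = True


@dataclass
class RankingConfig:
    """Weighted-sum ranking configuration; weights must be >= 0 and sum to 1.

    The default channels are combined correlation p (smaller better), absolute
    scaled combined LFC (larger better) and the best survival chi-square
    (larger better), equally weighted.
    """

    channels: list[Channel] = field(default_factory=lambda: [
        Channel("combined_p", 1 / 3, higher_is_better=False),
        Channel("abs_combined_lfc_scaled", 1 / 3, higher_is_better=True),
        Channel("best_survival_chi2", 1 / 3, higher_is_better=True),
    ])

    def validate(self) -> None:
        weights = np.array([c.weight for c in self.channels], dtype=float)
        if (weights < 0).any():
            raise ValidationError("ranking weights must be nonnegative")
        if abs(weights.sum() - 1.0) > 1e-9:
            raise ValidationError(f"ranking weights must sum to 1, got {weights.sum()}")


def build_evidence(combined_corr: pd.DataFrame,
                   meta_de: pd.DataFrame | None = None,
                   survival_results: pd.DataFrame | None = None) -> pd.DataFrame:
    """Default per-gene evidence table feeding the ranking channels."""
    ev = combined_corr.set_index("gene")[["combined_p"]].copy()
    if meta_de is not None and len(meta_de):
        scaled = meta_de.set_index("gene")["combined_lfc_scaled"].abs()
        ev["abs_combined_lfc_scaled"] = scaled.reindex(ev.index)
    else:
        ev["abs_combined_lfc_scaled"] = np.nan
    if survival_results is not None and len(survival_results):
        best = (survival_results.loc[survival_results["evaluable"]]
                .groupby("gene")["logrank_chi2"].max())
        ev["best_survival_chi2"] = best.reindex(ev.index)
    else:
        ev["best_survival_chi2"] = np.nan
    return ev


def rank_targets(genes, evidence: pd.DataFrame,
                 cfg: RankingConfig | None = None) -> pd.DataFrame:
    """Rank candidate genes by a weighted sum of minmax-scaled evidence channels.

    Each channel is minmax-scaled to [0, 1] over the candidate genes and
    oriented so 1 is best; missing values take the channel's worst value (0)
    with a logged count. Ties in the final score break lexicographically.
    """
    cfg = cfg or RankingConfig()
    cfg.validate()
    genes = sorted(set(genes))
    out = pd.DataFrame(index=pd.Index(genes, name="gene"))
    score = np.zeros(len(genes))
    for ch in cfg.channels:
        if ch.name not in evidence.columns:
            raise ValidationError(f"evidence table lacks channel {ch.name!r}")
        col = evidence[ch.name].reindex(genes).astype(float)
        n_missing = int(col.isna().sum())
        if n_missing:
            logger.warning("ranking channel %s: %d genes missing; assigned worst value",
                           ch.name, n_missing)
        vals = col.to_numpy()
        finite = vals[~np.isnan(vals)]
        if finite.size and finite.max() > finite.min():
            scaled = (vals - finite.min()) / (finite.max() - finite.min())
        else:
            scaled = np.full_like(vals, 0.5)
        if not ch.higher_is_better:
            scaled = 1.0 - scaled
        scaled = np.where(np.isnan(scaled), 0.0, scaled)
        out[f"scaled_{ch.name}"] = scaled
        score += ch.weight * scaled
    out["score"] = score
    out = out.reset_index().sort_values(["score", "gene"],
                                        ascending=[False, True], kind="mergesort")
    out.insert(1, "rank", range(1, len(out) + 1))
    return out.reset_index(drop=True)
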