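"""Case-vs-control differential expression and cross-dataset meta-analysis.

Per dataset, the log2 fold change is the difference of group means on the
log2 expression scale and the p-value comes from Welch's two-sample t-test,
BH-adjusted within the dataset. Across datasets, a gene's combined LFC is the
arithmetic mean of its per-dataset LFCs, p-values are combined with the
direction-aware Stouffer method (sign taken from each dataset's LFC) and the
combined p-values are BH-adjusted across genes. A symmetric minmax-scaled
LFC column (combined LFC divided by the largest absolute combined LFC) is
reported alongside the raw log2-scale value.

The per-dataset test is deliberately pluggable: any callable mapping
(case matrix, control matrix) -> (lfc, p) arrays can replace Welch's t, e.g.
a moderated-variance variant.
"""

from __future__ import annotations

import logging
import warnings
from typing import Callable, Iterable

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, stouffer_signed
from .datasets import DatasetCollection, ExpressionDataset

logger = logging.getLogger("geroscreen")

DE_COLUMNS = ["gene", "dataset_id", "lfc", "p", "q"]


def welch_de(case: np.ndarray, control: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t-test; returns (lfc, two-sided p).

    Genes with zero variance in both groups get p = 1 (no evidence under the
    test's assumptions, whatever the mean difference).
    """
    lfc = case.mean(axis=1) - control.mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # flat genes trigger scipy's precision-loss warning; they get p = 1 below
        warnings.simplefilter("ignore", RuntimeWarning)
        _, p = stats.ttest_ind(case, control, axis=1, equal_var=False)
    both_flat = (case.var(axis=1) == 0) & (control.var(axis=1) == 0)
    p = np.where(both_flat | np.isnan(p), 1.0, p)
    return lfc, np.clip(p, 1e-300, 1.0)


def de_dataset(ds: ExpressionDataset,
               test: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]] = welch_de,
               min_per_group: int = 2) -> pd.DataFrame:
    """Per-gene case-vs-control differential expression for one dataset.

    Returns columns gene, dataset_id, lfc, p, q (BH within dataset). Datasets
    lacking ``min_per_group`` samples in either group are excluded with a
    warning (empty frame).
    """
    case_mask = ds.case_mask().values
    n_case, n_ctrl = int(case_mask.sum()), int((~case_mask).sum())
    if n_case < min_per_group or n_ctrl < min_per_group:
        logger.warning("%s: %d case / %d control samples; dataset excluded from DE",
                       ds.dataset_id, n_case, n_ctrl)
        return pd.DataFrame(columns=DE_COLUMNS)
    mat = ds.values.to_numpy()
    lfc, p = test(mat[:, case_mask], mat[:, ~case_mask])
    return pd.DataFrame({
        "gene": ds.genes,
        "dataset_id": ds.dataset_id,
        "lfc": lfc,
        "p": p,
        "q": bh_adjust(p),
    })


def de_collection(collection: DatasetCollection,
                  test: Callable = welch_de) -> pd.DataFrame:
    """Concatenated per-dataset DE tables for a whole collection."""
    frames = [de_dataset(ds, test=test) for ds in collection]
    frames = [df for df in frames if len(df)]
    if not frames:
        return pd.DataFrame(columns=DE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def combine_de(per_dataset: pd.DataFrame | Iterable[pd.DataFrame],
               alpha: float = 0.05) -> pd.DataFrame:
    """Meta-analysis of per-dataset DE results.

    Columns: gene, combined_lfc (mean of per-dataset LFCs over datasets
    measuring the gene), combined_lfc_scaled (symmetric minmax: divided by
    max |combined_lfc| across genes, hence in [-1, 1]), combined_p
    (direction-aware Stouffer), combined_q (BH across genes), n_datasets,
    n_significant_up / n_significant_down (per-dataset q < alpha with the
    matching LFC sign).
    """
    if not isinstance(per_dataset, pd.DataFrame):
        per_dataset = pd.concat(list(per_dataset), ignore_index=True)
    if not len(per_dataset):
        return pd.DataFrame(columns=[
            "gene", "combined_lfc", "combined_lfc_scaled", "combined_p",
            "combined_q", "n_datasets", "n_significant_up", "n_significant_down"])

    def _one(g: pd.DataFrame) -> pd.Series:
        z, p = stouffer_signed(g["p"].to_numpy(), g["lfc"].to_numpy())
        sig = g["q"] < alpha
        return pd.Series({
            "combined_lfc": g["lfc"].mean(),
            "combined_p": p,
            "n_datasets": len(g),
            "n_significant_up": int((sig & (g["lfc"] > 0)).sum()),
            "n_significant_down": int((sig & (g["lfc"] < 0)).sum()),
        })

    out = per_dataset.groupby("gene", sort=True).apply(_one, include_groups=False)
    max_abs = out["combined_lfc"].abs().max()
    out["combined_lfc_scaled"] = (
        out["combined_lfc"] / max_abs if max_abs > 0 else 0.0)
    out["combined_q"] = bh_adjust(out["combined_p"].to_numpy())
    out = out.reset_index()
    for col in ("n_datasets", "n_significant_up", "n_significant_down"):
        out[col] = out[col].astype(int)
    cols = ["gene", "combined_lfc", "combined_lfc_scaled", "combined_p",
            "combined_q", "n_datasets", "n_significant_up", "n_significant_down"]
    out = out[cols].sort_values(["combined_p", "gene"], kind="mergesort")
    return out.reset_index(drop=True)
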