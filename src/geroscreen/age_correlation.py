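"""Age-expression correlation screening across datasets.

Per dataset, Spearman rank correlation between each gene's expression and age
is computed on case samples only (average ranks for ties, two-sided p from
the large-sample t approximation). Genes are then filtered by cross-dataset
sign consistency — a gene must carry the same correlation sign in at least
``min_support`` of the datasets where it is measured (default: all but one) —
and per-dataset p-values are combined with the direction-aware Stouffer
method. A gene is called significant when its combined two-sided p-value
falls below ``alpha`` (default 0.05, uncorrected across genes; an optional BH
layer can be applied downstream).
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust, stouffer_signed
from .datasets import DatasetCollection, ExpressionDataset, ValidationError

logger = logging.getLogger("geroscreen")

CORRELATION_COLUMNS = ["gene", "dataset_id", "rho", "p", "n_used"]


def _spearman_vs_vector(values: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Spearman rho and two-sided t-approximation p against one vector.

    Matches scipy.stats.spearmanr (average ranks, t reference with n-2 df).
    Rows with zero rank variance return NaN.
    """
    n = y.size
    rx = stats.rankdata(values, axis=1)
    ry = stats.rankdata(y)
    rx = rx - rx.mean(axis=1, keepdims=True)
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum(axis=1) * (ry**2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (rx @ ry) / denom
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(rho), np.nan, np.clip(p, 1e-300, 1.0))
    return rho, p


def spearman_exact_p(x, y) -> tuple[float, float]:
    """Spearman rho with an exact permutation two-sided p-value (n <= 9).

    Enumerates all n! pairings; p is the fraction with |rho| at least as
    extreme as observed. Intended for tiny samples where the t approximation
    is unreliable.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n > 9:
        raise ValidationError("exact permutation p-value limited to n <= 9")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)

    def _rho(a, b):
        a = a - a.mean()
        b = b - b.mean()
        d = math.sqrt((a**2).sum() * (b**2).sum())
        return float(a @ b / d) if d > 0 else np.nan

    observed = _rho(rx, ry)
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        total += 1
        if abs(_rho(rx[list(perm)], ry)) >= abs(observed) - 1e-12:
            count += 1
    return observed, count / total


def correlate_dataset(ds: ExpressionDataset, min_n: int = 3) -> pd.DataFrame:
    """Per-gene Spearman correlation between expression and age on case samples.

    Returns a DataFrame with columns gene, dataset_id, rho, p, n_used. Genes
    with zero expression variance among the used samples are omitted (count
    logged). Datasets with fewer than ``min_n`` usable case samples are
    skipped with a warning and yield an empty frame.
    """
    usable = ds.case_mask() & ds.metadata["age"].notna()
    n_used = int(usable.sum())
    if n_used < min_n:
        logger.warning("%s: only %d case samples with age (<%d); dataset skipped",
                       ds.dataset_id, n_used, min_n)
        return pd.DataFrame(columns=CORRELATION_COLUMNS)
    sub = ds.values.loc[:, usable.values].to_numpy()
    ages = ds.metadata.loc[usable, "age"].to_numpy(dtype=float)
    rho, p = _spearman_vs_vector(sub, ages)
    keep = ~np.isnan(rho)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: %d zero-variance genes omitted from correlation",
                    ds.dataset_id, n_dropped)
    out = pd.DataFrame({
        "gene": np.asarray(ds.genes)[keep],
        "dataset_id": ds.dataset_id,
        "rho": rho[keep],
        "p": p[keep],
        "n_used": n_used,
    })
    return out


def stouffer_combine(rhos, p_values) -> tuple[float, float]:
    """Direction-aware Stouffer combination of per-dataset Spearman results.

    Per-dataset signed z_i = sign(rho_i) * Phi^-1(1 - p_i/2); equal weights;
    combined two-sided p from |Z|.
    """
    return stouffer_signed(p_values, rhos)


def _support_table(results: pd.DataFrame) -> pd.DataFrame:
    grp = results.groupby("gene", sort=True)
    table = pd.DataFrame({
        "n_pos": grp["rho"].apply(lambda r: int((r > 0).sum())),
        "n_neg": grp["rho"].apply(lambda r: int((r < 0).sum())),
        "n_datasets_measured": grp["rho"].size(),
    })
    return table


def sign_support(results: pd.DataFrame, min_support: int) -> tuple[list[str], list[str]]:
    """Cross-dataset sign-consistency filter.

    A gene enters the positive list iff rho > 0 in at least ``min_support`` of
    the datasets where it is measured (negative list analogously; rho == 0
    counts for neither sign). A gene can never appear in both lists: if both
    counts reach the threshold the larger one wins and an exact tie excludes
    the gene.
    """
    if min_support < 1:
        raise ValidationError("min_support must be >= 1")
    table = _support_table(results)
    pos, neg = [], []
    for gene, row in table.iterrows():
        p_ok = row["n_pos"] >= min_support
        n_ok = row["n_neg"] >= min_support
        if p_ok and n_ok:
            if row["n_pos"] > row["n_neg"]:
                pos.append(gene)
            elif row["n_neg"] > row["n_pos"]:
                neg.append(gene)
            # exact tie: neither list
        elif p_ok:
            pos.append(gene)
        elif n_ok:
            neg.append(gene)
    return sorted(pos), sorted(neg)


def combine_results(results: pd.DataFrame, min_support: int,
                    alpha: float = 0.05, bh: bool = False) -> pd.DataFrame:
    """Combine per-dataset correlation results into one row per gene.

    Columns: gene, sign (positive/negative/none from the sign-support filter),
    support, n_datasets_measured, stouffer_z, combined_p, significant. The
    Stouffer combination always uses every dataset where the gene is measured.
    With ``bh=True`` significance is assessed on BH-adjusted combined p-values
    (off by default — the screen applies the alpha threshold directly to the
    combined p).
    """
    pos, neg = sign_support(results, min_support)
    pos_set, neg_set = set(pos), set(neg)
    table = _support_table(results)
    combined = results.groupby("gene", sort=True).apply(
        lambda g: pd.Series(stouffer_combine(g["rho"].to_numpy(), g["p"].to_numpy()),
                            index=["stouffer_z", "combined_p"]),
        include_groups=False,
    )
    out = table.join(combined)
    out["sign"] = "none"
    out.loc[out.index.isin(pos_set), "sign"] = "positive"
    out.loc[out.index.isin(neg_set), "sign"] = "negative"
    out["support"] = out[["n_pos", "n_neg"]].max(axis=1)
    out.loc[out["sign"] == "positive", "support"] = out["n_pos"]
    out.loc[out["sign"] == "negative", "support"] = out["n_neg"]
    if bh:
        out["combined_q"] = bh_adjust(out["combined_p"].to_numpy())
        out["significant"] = out["combined_q"] < alpha
    else:
        out["significant"] = out["combined_p"] < alpha
    out = out.reset_index().rename(columns={"index": "gene"})
    cols = ["gene", "sign", "support", "n_pos", "n_neg", "n_datasets_measured",
            "stouffer_z", "combined_p", "significant"]
    if bh:
        cols.append("combined_q")
    out = out[cols].sort_values(["combined_p", "gene"], kind="mergesort")
    return out.reset_index(drop=True)


def screen_age_correlated(collection: DatasetCollection,
                          min_support: int | None = None,
                          alpha: float = 0.05,
                          min_n: int = 3,
                          bh: bool = False) -> pd.DataFrame:
    """Full age-correlation screen over a collection.

    Runs per-dataset Spearman correlation (case samples only), the
    sign-consistency filter and the Stouffer combination. ``min_support``
    defaults to one less than the number of datasets that contribute
    correlation results (the "all but one" rule).
    """
    per_dataset = [correlate_dataset(ds, min_n=min_n) for ds in collection]
    per_dataset = [df for df in per_dataset if len(df)]
    if len(per_dataset) < 2:
        raise ValidationError(
            "age-correlation screen requires >= 2 datasets with usable age metadata")
    results = pd.concat(per_dataset, ignore_index=True)
    n_used = results["dataset_id"].nunique()
    if min_support is None:
        min_support = max(1, n_used - 1)
    return combine_results(results, min_support=min_support, alpha=alpha, bh=bh)


def per_dataset_correlations(collection: DatasetCollection, min_n: int = 3) -> pd.DataFrame:
    """Concatenated per-dataset correlation tables for a whole collection."""
    frames = [correlate_dataset(ds, min_n=min_n) for ds in collection]
    frames = [df for df in frames if len(df)]
    if not frames:
        return pd.DataFrame(columns=CORRELATION_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def significant_gene_lists(combined: pd.DataFrame) -> dict[str, list[str]]:
    """Positive / negative sign-consistent gene lists, split by significance."""
    out = {}
    for sign in ("positive", "negative"):
        mask = combined["sign"] == sign
        out[sign] = sorted(combined.loc[mask, "gene"])
        out[f"{sign}_significant"] = sorted(
            combined.loc[mask & combined["significant"], "gene"])
    return out


def sign_lists_per_dataset(results: pd.DataFrame) -> dict[str, dict[str, set[str]]]:
    """Per-dataset positively / negatively correlated gene sets."""
    out: dict[str, dict[str, set[str]]] = {"positive": {}, "negative": {}}
    for dataset_id, grp in results.groupby("dataset_id"):
        out["positive"][dataset_id] = set(grp.loc[grp["rho"] > 0, "gene"])
        out["negative"][dataset_id] = set(grp.loc[grp["rho"] < 0, "gene"])
    return out


def upset_counts(gene_lists: dict[str, set[str]], min_degree: int = 1) -> pd.DataFrame:
    """Exact-subset intersection counts over per-dataset gene lists.

    For every subset of datasets with at least ``min_degree`` members, counts
    the genes belonging to exactly that subset — the tabular content of an
    UpSet plot. Returns one boolean membership column per dataset plus
    ``degree`` and ``count``, sorted by degree then count (descending).
    """
    if not gene_lists:
        raise ValidationError("upset_counts requires at least one gene list")
    ids = sorted(gene_lists)
    membership: Counter[tuple[bool, ...]] = Counter()
    all_genes = set().union(*gene_lists.values())
    for gene in all_genes:
        pattern = tuple(gene in gene_lists[d] for d in ids)
        membership[pattern] += 1
    rows = []
    for pattern, count in membership.items():
        degree = sum(pattern)
        if degree >= min_degree:
            rows.append(dict(zip(ids, pattern), degree=degree, count=count))
    out = pd.DataFrame(rows, columns=[*ids, "degree", "count"])
    if len(out):
        out = out.sort_values(["degree", "count", *ids],
                              ascending=[False, False] + [False] * len(ids),
                              kind="mergesort").reset_index(drop=True)
    return out
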