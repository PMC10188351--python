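import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from geroscreen.age_correlation import (
    combine_results,
    correlate_dataset,
    screen_age_correlated,
    sign_lists_per_dataset,
    sign_support,
    spearman_exact_p,
    stouffer_combine,
    upset_counts,
)
from geroscreen.datasets import DatasetCollection
from geroscreen.simulate import SimulationConfig, simulate_collection

import oracles
from conftest import make_dataset


def _dataset_with(expr_rows, ages, dataset_id="DS"):
    genes = list(expr_rows)
    values = np.array([expr_rows[g] for g in genes], dtype=float)
    return make_dataset(dataset_id, genes=genes, n_samples=values.shape[1],
                        frac_case=1.0, values=values, ages=np.asarray(ages, float))


class TestSpearmanPerDataset:
    def test_perfect_monotone_and_antitone(self):
        ages = np.arange(30.0, 40.0)
        ds = _dataset_with({"UP": ages.copy(), "DOWN": ages[::-1].copy()}, ages)
        res = correlate_dataset(ds).set_index("gene")
        assert res.loc["UP", "rho"] == 1.0
        assert res.loc["DOWN", "rho"] == -1.0
        assert res.loc["UP", "n_used"] == 10

    def test_five_point_rank_formula(self):
        # ranks of age (30,40,35,50,60) = (1,3,2,4,5); sum d^2 = 2
        # rho = 1 - 6*2 / (5*24) = 0.9
        ds = _dataset_with({"G": [1, 2, 3, 4, 5]}, [30, 40, 35, 50, 60])
        res = correlate_dataset(ds).set_index("gene")
        assert res.loc["G", "rho"] == pytest.approx(0.9, abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_spearmanr(self, seed):
        rng = np.random.default_rng(seed)
        n = 25
        ages = rng.uniform(20, 80, n)
        rows = {f"G{i}": rng.normal(size=n) + (0.05 * i) * ages for i in range(8)}
        rows["TIED"] = np.round(rng.normal(size=n))  # exercises average ranks
        ds = _dataset_with(rows, ages)
        res = correlate_dataset(ds).set_index("gene")
        for gene, row_vals in rows.items():
            rho, p = stats.spearmanr(row_vals, ages)
            assert res.loc[gene, "rho"] == pytest.approx(rho, abs=1e-12)
            assert res.loc[gene, "p"] == pytest.approx(p, abs=1e-12)

    def test_zero_variance_genes_omitted_and_small_dataset_skipped(self):
        ages = np.arange(30.0, 38.0)
        ds = _dataset_with({"FLAT": np.ones(8), "OK": ages + 0.0}, ages)
        res = correlate_dataset(ds)
        assert list(res["gene"]) == ["OK"]
        tiny = _dataset_with({"G": [1, 2]}, [30, 40])
        assert correlate_dataset(tiny).empty

    def test_exact_permutation_p_for_tiny_n(self):
        # perfect monotone n=5: only the identity permutation of ranks attains
        # |rho| >= 1, plus its reversal -> p = 2/120
        rho, p = spearman_exact_p([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 120)


class TestStouffer:
    def test_single_study_identity(self):
        z, p = stouffer_combine([0.6], [0.05])
        assert p == pytest.approx(0.05, rel=1e-12)
        assert z > 0

    def test_opposite_signs_cancel(self):
        z, p = stouffer_combine([0.4, -0.4], [0.02, 0.02])
        assert z == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("k", [2, 4, 9])
    def test_equal_p_same_sign_closed_form(self, k):
        z, p = stouffer_combine([0.5] * k, [0.05] * k)
        z_expected = np.sqrt(k) * stats.norm.isf(0.025)
        assert z == pytest.approx(z_expected, abs=1e-10)
        assert p == pytest.approx(2 * stats.norm.sf(z_expected), rel=1e-10)


def _random_results_table(rng, n_datasets, n_genes, missing_frac=0.2):
    rows = []
    for d in range(n_datasets):
        for g in range(n_genes):
            if rng.random() < missing_frac:
                continue
            rho = rng.uniform(-1, 1)
            rows.append({"gene": f"G{g}", "dataset_id": f"D{d}",
                         "rho": rho, "p": rng.uniform(1e-6, 1), "n_used": 30})
    return pd.DataFrame(rows)


class TestSignSupport:
    @pytest.mark.parametrize("seed", [10, 11, 12])
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        results = _random_results_table(rng, n_datasets=5, n_genes=20)
        min_support = int(rng.integers(1, 6))
        by_gene = {g: list(grp["rho"]) for g, grp in results.groupby("gene")}
        expected = oracles.naive_sign_lists(by_gene, min_support)
        assert sign_support(results, min_support) == expected

    def test_eleven_of_twelve_rule(self):
        rows = [{"gene": "HIT", "dataset_id": f"D{d}", "rho": 0.3, "p": 0.1, "n_used": 30}
                for d in range(11)]
        rows.append({"gene": "HIT", "dataset_id": "D11", "rho": -0.2, "p": 0.5, "n_used": 30})
        rows += [{"gene": "MISS", "dataset_id": f"D{d}",
                  "rho": 0.3 if d < 10 else -0.2, "p": 0.1, "n_used": 30}
                 for d in range(12)]
        pos, neg = sign_support(pd.DataFrame(rows), min_support=11)
        assert pos == ["HIT"] and neg == []

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=1, max_value=6))
    def test_increasing_min_support_is_monotone(self, seed, min_support):
        rng = np.random.default_rng(seed)
        results = _random_results_table(rng, n_datasets=6, n_genes=12)
        pos1, neg1 = sign_support(results, min_support)
        pos2, neg2 = sign_support(results, min_support + 1)
        assert set(pos2) <= set(pos1) and set(neg2) <= set(neg1)
        assert not set(pos1) & set(neg1)


def _naive_screen(collection, min_support, alpha):
    """Direct per-gene reimplementation of the whole screen (scipy-based)."""
    per_gene: dict[str, list[tuple[float, float]]] = {}
    n_datasets_used = 0
    for ds in collection:
        cases = (ds.metadata["group"] == "case") & ds.metadata["age"].notna()
        if cases.sum() < 3:
            continue
        n_datasets_used += 1
        ages = ds.metadata.loc[cases, "age"].to_numpy()
        for gene in ds.genes:
            vals = ds.values.loc[gene, cases.values].to_numpy()
            if np.ptp(vals) == 0:
                continue
            rho, p = stats.spearmanr(vals, ages)
            per_gene.setdefault(gene, []).append((rho, p))
    out = {}
    for gene, pairs in per_gene.items():
        rhos = np.array([r for r, _ in pairs])
        ps = np.clip([p for _, p in pairs], 1e-300, 1 - 1e-16)
        z = float((np.sign(rhos) * stats.norm.isf(np.array(ps) / 2)).sum()
                  / np.sqrt(len(pairs)))
        p_comb = 2 * stats.norm.sf(abs(z))
        n_pos, n_neg = int((rhos > 0).sum()), int((rhos < 0).sum())
        if n_pos >= min_support and (n_pos > n_neg or n_neg < min_support):
            sign = "positive"
        elif n_neg >= min_support and (n_neg > n_pos or n_pos < min_support):
            sign = "negative"
        else:
            sign = "none"
        out[gene] = (sign, z, p_comb, p_comb < alpha)
    return out


class TestScreen:
    @pytest.mark.parametrize("seed", [21, 22])
    def test_full_screen_equals_naive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        datasets = []
        genes = [f"G{i}" for i in range(15)]
        for d in range(4):
            sub = [g for g in genes if rng.random() > 0.2]  # platform gaps
            datasets.append(make_dataset(f"D{d}", genes=sub,
                                         n_samples=int(rng.integers(10, 25)),
                                         seed=seed * 10 + d))
        collection = DatasetCollection(datasets=datasets)
        combined = screen_age_correlated(collection, min_support=3, alpha=0.05)
        expected = _naive_screen(collection, min_support=3, alpha=0.05)
        assert set(combined["gene"]) == set(expected)
        for _, row in combined.iterrows():
            sign, z, p, sig = expected[row["gene"]]
            assert row["sign"] == sign
            assert row["stouffer_z"] == pytest.approx(z, abs=1e-10)
            assert row["combined_p"] == pytest.approx(p, abs=1e-12)
            assert bool(row["significant"]) == sig

    def test_significant_sign_matches_z_direction(self):
        cfg = SimulationConfig.default(seed=4)
        cfg.survival_dataset_samples = 80  # survival not needed here
        collection, _ = simulate_collection(cfg)
        combined = screen_age_correlated(collection)
        sig = combined[combined["significant"] & (combined["sign"] != "none")]
        assert len(sig) > 0
        pos = sig["sign"] == "positive"
        assert (sig.loc[pos, "stouffer_z"] > 0).all()
        assert (sig.loc[~pos, "stouffer_z"] < 0).all()

    def test_vacuous_min_support_empties_sign_lists(self):
        rng = np.random.default_rng(0)
        results = _random_results_table(rng, n_datasets=3, n_genes=8, missing_frac=0)
        combined = combine_results(results, min_support=4)
        assert (combined["sign"] == "none").all()


class TestUpsetCounts:
    def test_disjoint_and_identical_lists(self):
        disjoint = {"A": {"g1", "g2"}, "B": {"g3"}}
        table = upset_counts(disjoint, min_degree=2)
        assert table.empty or (table["count"] == 0).all()
        identical = {d: {"a", "b", "c", "d", "e"} for d in ("A", "B", "C")}
        table = upset_counts(identical, min_degree=3)
        assert len(table) == 1 and table.loc[0, "count"] == 5

    @pytest.mark.parametrize("seed", [31, 32])
    def test_matches_exhaustive_set_algebra(self, seed):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(30)]
        lists = {f"D{d}": {g for g in genes if rng.random() < 0.4}
                 for d in range(4)}
        table = upset_counts(lists, min_degree=1)
        expected = oracles.exact_subset_counts(lists, min_degree=1)
        got = {}
        for _, row in table.iterrows():
            members = frozenset(d for d in lists if row[d])
            got[members] = int(row["count"])
        assert got == expected

    def test_counts_from_per_dataset_correlations(self):
        rows = [
            {"gene": "a", "dataset_id": "D1", "rho": 0.5, "p": 0.1, "n_used": 10},
            {"gene": "a", "dataset_id": "D2", "rho": 0.4, "p": 0.1, "n_used": 10},
            {"gene": "b", "dataset_id": "D1", "rho": -0.5, "p": 0.1, "n_used": 10},
        ]
        lists = sign_lists_per_dataset(pd.DataFrame(rows))
        assert lists["positive"] == {"D1": {"a"}, "D2": {"a"}}
        assert lists["negative"]["D1"] == {"b"}
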