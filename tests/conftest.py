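import numpy as np
import pandas as pd
import pytest

from geroscreen.datasets import ExpressionDataset


def make_dataset(dataset_id="DS", genes=None, n_samples=10, seed=0,
                 frac_case=0.6, with_age=True, with_survival=False,
                 values=None, ages=None):
    """Small in-memory ExpressionDataset for unit tests."""
    rng = np.random.default_rng(seed)
    genes = list(genes) if genes is not None else [f"G{i}" for i in range(5)]
    samples = [f"{dataset_id}_S{j}" for j in range(n_samples)]
    if values is None:
        values = rng.normal(8.0, 1.0, size=(len(genes), n_samples))
    vals = pd.DataFrame(values, index=pd.Index(genes, name="gene_id"),
                        columns=samples)
    n_case = int(round(frac_case * n_samples))
    group = np.array(["case"] * n_case + ["control"] * (n_samples - n_case))
    meta = pd.DataFrame({
        "group": group,
        "age": (ages if ages is not None
                else (rng.uniform(20, 80, n_samples) if with_age else np.nan)),
        "os_time": np.nan,
        "os_event": np.nan,
    }, index=pd.Index(samples, name="sample_id"))
    if with_survival:
        meta["os_time"] = rng.exponential(400, n_samples)
        meta["os_event"] = (rng.random(n_samples) < 0.7).astype(float)
    return ExpressionDataset.from_frames(dataset_id, vals, meta)


@pytest.fixture
def tiny_dataset():
    return make_dataset(n_samples=8, seed=1)


def make_survival_dataset(dataset_id="SURV", n=300, genes=None, seed=0,
                          effect_gene=None, loghr=0.0, cohort=None,
                          baseline_hazard=0.002, censor_at=1200.0):
    """Survival dataset where one gene's expression optionally drives hazard
    (within one cohort if ``cohort`` given, else everywhere)."""
    rng = np.random.default_rng(seed)
    genes = list(genes) if genes is not None else [f"G{i}" for i in range(6)]
    samples = [f"{dataset_id}_S{j}" for j in range(n)]
    ages = rng.uniform(20, 80, n)
    expr = rng.standard_normal((len(genes), n)) + 8.0
    eta = np.zeros(n)
    if effect_gene is not None:
        centred = expr[genes.index(effect_gene)] - 8.0
        if cohort == "young":
            mask = ages < 45
        elif cohort == "middle":
            mask = (ages >= 45) & (ages <= 60)
        elif cohort == "senior":
            mask = ages > 60
        else:
            mask = np.ones(n, dtype=bool)
        eta[mask] = loghr * centred[mask]
    times = rng.exponential(1.0 / (baseline_hazard * np.exp(eta)))
    events = (times <= censor_at).astype(float)
    times = np.minimum(times, censor_at)
    vals = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"), columns=samples)
    meta = pd.DataFrame({"group": "case", "age": ages,
                         "os_time": times, "os_event": events},
                        index=pd.Index(samples, name="sample_id"))
    return ExpressionDataset.from_frames(dataset_id, vals, meta)
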