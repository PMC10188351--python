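"""Synthetic multi-cohort expression collections with planted, recoverable structure.

The generator emulates the input layout of a multi-dataset target screen: K
cohorts with heterogeneous sample sizes over a shared gene universe, where

* designated genes carry an age-correlated expression signal of a chosen
  Spearman strength and sign (with a per-dataset sign-concordance knob),
* designated genes carry a case-vs-control log2 fold-change shift,
* one designated large cohort carries overall-survival metadata whose hazard
  is log-linear in the expression of chosen genes within chosen age cohorts
  (mirroring the role a large clinical cohort such as TCGA plays in the real
  screen — the remaining cohorts have no survival metadata).

Ages are uniform over ``age_range``. Age-correlated genes are linear in age
plus Gaussian noise; the slope is calibrated so the expected Spearman rho
matches the target via the bivariate-normal rank-correlation relation
``rho_S = (6/pi) * arcsin(rho_P / 2)``. Control samples carry no age effect
(the correlation screen uses case samples only). Survival times are
exponential with constant baseline hazard and administrative censoring at the
follow-up horizon ``tau = -ln(censor_rate) / baseline_hazard``, so the
expected censored fraction under the baseline is ``censor_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import (
    CohortSpec,
    COHORTS,
    DatasetCollection,
    ExpressionDataset,
    ValidationError,
)


def spearman_to_pearson(rho_s: float) -> float:
    """Pearson correlation with the same Spearman rho under bivariate normality."""
    return 2.0 * np.sin(np.pi * rho_s / 6.0)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic collection.

    Planted effects are keyed by gene symbol: ``planted_pos_corr`` /
    ``planted_neg_corr`` map gene -> target Spearman rho (positive resp.
    negative), ``planted_lfc`` maps gene -> true case-vs-control log2 fold
    change, and ``survival_effect`` maps gene -> {cohort: log hazard ratio per
    unit of centred expression} applied inside the designated survival
    dataset. ``concordance`` is the probability that a planted correlation
    keeps its sign in any given dataset.
    """

    n_datasets: int = 12
    genes_total: int = 500
    samples_per_dataset: tuple[int, int] = (80, 80)
    frac_case: float = 0.75
    age_range: tuple[float, float] = (20.0, 80.0)
    planted_pos_corr: dict[str, float] = field(default_factory=dict)
    planted_neg_corr: dict[str, float] = field(default_factory=dict)
    concordance: float = 1.0
    planted_lfc: dict[str, float] = field(default_factory=dict)
    survival_effect: dict[str, dict[str, float]] = field(default_factory=dict)
    survival_dataset_samples: int = 1500
    baseline_hazard: float = 0.0015  # per day; median ~460 d
    censor_rate: float = 0.2
    noise_sd: float = 1.0
    cohort_spec: CohortSpec = field(default_factory=CohortSpec)
    seed: int = 0

    @property
    def gene_universe(self) -> list[str]:
        return [f"G{i:04d}" for i in range(1, self.genes_total + 1)]

    def validate(self) -> None:
        if not 0.0 <= self.concordance <= 1.0:
            raise ValidationError(f"concordance must be in [0,1], got {self.concordance}")
        if not 0.0 < self.frac_case < 1.0:
            raise ValidationError("frac_case must be in (0,1)")
        if not 0.0 <= self.censor_rate < 1.0:
            raise ValidationError("censor_rate must be in [0,1)")
        universe = set(self.gene_universe)
        for name, planted in (("planted_pos_corr", self.planted_pos_corr),
                              ("planted_neg_corr", self.planted_neg_corr)):
            for gene, rho in planted.items():
                if gene not in universe:
                    raise ValidationError(f"{name}: gene {gene!r} not in universe")
                if not abs(rho) < 1.0:
                    raise ValidationError(f"{name}: |rho| must be < 1, got {rho}")
        if set(self.planted_pos_corr) & set(self.planted_neg_corr):
            raise ValidationError("a gene cannot be planted with both correlation signs")
        if (any(r <= 0 for r in self.planted_pos_corr.values())
                or any(r >= 0 for r in self.planted_neg_corr.values())):
            raise ValidationError("planted rho sign must match its list")
        for gene, effects in self.survival_effect.items():
            if gene not in universe:
                raise ValidationError(f"survival_effect: gene {gene!r} not in universe")
            for cohort in effects:
                if cohort not in COHORTS:
                    raise ValidationError(f"survival_effect: unknown cohort {cohort!r}")
        for gene in self.planted_lfc:
            if gene not in universe:
                raise ValidationError(f"planted_lfc: gene {gene!r} not in universe")

    @classmethod
    def default(cls, seed: int = 0) -> "SimulationConfig":
        """The default study conditions: 12 cohorts of 60 cases + 20 controls,
        30 genes per correlation sign at |rho| = 0.5 and full concordance,
        20 planted fold-change genes at |LFC| = 1, and a 600-sample survival
        cohort where ten positively age-correlated genes are harmful when high
        in seniors (log-HR +0.8) and ten negatively age-correlated genes are
        harmful when low in the young (log-HR -0.8)."""
        cfg = cls(seed=seed)
        genes = cfg.gene_universe
        cfg.planted_pos_corr = {g: 0.5 for g in genes[0:30]}
        cfg.planted_neg_corr = {g: -0.5 for g in genes[30:60]}
        cfg.survival_effect = {g: {"senior": 0.8} for g in genes[0:10]}
        cfg.survival_effect.update({g: {"young": -0.8} for g in genes[30:40]})
        cfg.planted_lfc = {g: 1.0 for g in genes[60:70]}
        cfg.planted_lfc.update({g: -1.0 for g in genes[70:80]})
        return cfg

    @classmethod
    def null(cls, genes_total: int = 1000, n_datasets: int = 12,
             samples_per_dataset: tuple[int, int] = (80, 80),
             seed: int = 0) -> "SimulationConfig":
        """A collection with no planted effects (every gene null)."""
        return cls(n_datasets=n_datasets, genes_total=genes_total,
                   samples_per_dataset=samples_per_dataset,
                   survival_dataset_samples=samples_per_dataset[1], seed=seed)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("samples_per_dataset", "age_range"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "cohort_spec" in raw:
            raw["cohort_spec"] = CohortSpec(**raw["cohort_spec"])
        return cls(**raw)


@dataclass
class SyntheticTruth:
    """Per-gene ground-truth labels for a simulated collection."""

    table: pd.DataFrame  # one row per gene in the universe

    def genes_with_corr_sign(self, sign: str) -> list[str]:
        return list(self.table.loc[self.table["corr_sign"] == sign, "gene"])

    def genes_with_survival_direction(self, cohort: str, direction: str) -> list[str]:
        col = f"survival_direction_{cohort}"
        return list(self.table.loc[self.table[col] == direction, "gene"])

    @property
    def null_corr_genes(self) -> list[str]:
        return self.genes_with_corr_sign("none")


def _assign_cohort_labels(ages: np.ndarray, spec: CohortSpec) -> np.ndarray:
    labels = np.full(ages.shape, "middle", dtype=object)
    labels[ages < spec.young_max] = "young"
    labels[ages > spec.senior_min] = "senior"
    return labels


def simulate_collection(config: SimulationConfig) -> tuple[DatasetCollection, SyntheticTruth]:
    """Generate a DatasetCollection and its ground truth; reproducible from seed.

    Dataset ``DS01`` is the designated survival cohort: it has
    ``survival_dataset_samples`` samples and is the only one with os_time /
    os_event metadata (on case samples).
    """
    config.validate()
    genes = config.gene_universe
    gene_index = {g: i for i, g in enumerate(genes)}
    n_genes = len(genes)
    age_lo, age_hi = config.age_range
    sd_age = (age_hi - age_lo) / np.sqrt(12.0)
    mid_age = (age_hi + age_lo) / 2.0

    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_datasets + 1)
    rng_global = np.random.default_rng(children[0])
    baseline = rng_global.uniform(4.0, 12.0, size=n_genes)

    # slope magnitude per planted gene so that the expected Spearman matches
    # the target at the configured noise level
    slopes: dict[str, float] = {}
    for planted in (config.planted_pos_corr, config.planted_neg_corr):
        for gene, rho_s in planted.items():
            rho_p = spearman_to_pearson(abs(rho_s))
            if config.noise_sd == 0.0:
                signal_sd = 1.0  # pure monotone signal: rank correlation is exact
            else:
                signal_sd = config.noise_sd * rho_p / np.sqrt(1.0 - rho_p**2)
            slopes[gene] = np.sign(rho_s) * signal_sd / sd_age

    datasets = []
    for d in range(config.n_datasets):
        rng = np.random.default_rng(children[d + 1])
        dataset_id = f"DS{d + 1:02d}"
        is_survival_ds = d == 0
        if is_survival_ds:
            n = config.survival_dataset_samples
        else:
            lo, hi = config.samples_per_dataset
            n = int(rng.integers(lo, hi + 1))
        n_case = int(round(config.frac_case * n))
        is_case = np.zeros(n, dtype=bool)
        is_case[rng.permutation(n)[:n_case]] = True
        ages = rng.uniform(age_lo, age_hi, size=n)

        expr = baseline[:, None] + config.noise_sd * rng.standard_normal((n_genes, n))
        # per-dataset sign concordance of planted correlations
        flip = {}
        for gene in slopes:
            flip[gene] = rng.random() < (1.0 - config.concordance)
        age_dev = ages - mid_age
        for gene, slope in slopes.items():
            eff = -slope if flip[gene] else slope
            row = gene_index[gene]
            expr[row, is_case] += eff * age_dev[is_case]
        for gene, lfc in config.planted_lfc.items():
            expr[gene_index[gene], is_case] += lfc

        meta = pd.DataFrame({
            "group": np.where(is_case, "case", "control"),
            "age": ages,
            "os_time": np.nan,
            "os_event": np.nan,
        }, index=pd.Index([f"{dataset_id}_S{j + 1:04d}" for j in range(n)],
                          name="sample_id"))

        if is_survival_ds:
            cohorts = _assign_cohort_labels(ages, config.cohort_spec)
            eta = np.zeros(n)
            for gene, effects in config.survival_effect.items():
                centred = expr[gene_index[gene]] - baseline[gene_index[gene]]
                for cohort, loghr in effects.items():
                    in_cohort = cohorts == cohort
                    eta[in_cohort] += loghr * centred[in_cohort]
            hazard = config.baseline_hazard * np.exp(eta)
            raw_times = rng.exponential(1.0 / hazard)
            if config.censor_rate > 0.0:
                tau = -np.log(config.censor_rate) / config.baseline_hazard
            else:
                tau = np.inf
            event = raw_times <= tau
            os_time = np.minimum(raw_times, tau)
            meta.loc[is_case, "os_time"] = os_time[is_case]
            meta.loc[is_case, "os_event"] = event[is_case].astype(float)

        values = pd.DataFrame(expr, index=pd.Index(genes, name="gene_id"),
                              columns=meta.index.astype(str))
        datasets.append(ExpressionDataset.from_frames(dataset_id, values, meta))

    truth = _build_truth(config)
    return DatasetCollection(datasets=datasets), truth


def _build_truth(config: SimulationConfig) -> SyntheticTruth:
    rows = []
    for gene in config.gene_universe:
        if gene in config.planted_pos_corr:
            sign, rho = "positive", config.planted_pos_corr[gene]
        elif gene in config.planted_neg_corr:
            sign, rho = "negative", config.planted_neg_corr[gene]
        else:
            sign, rho = "none", 0.0
        row = {
            "gene": gene,
            "corr_sign": sign,
            "true_rho": rho,
            "true_lfc": config.planted_lfc.get(gene, 0.0),
        }
        effects = config.survival_effect.get(gene, {})
        for cohort in COHORTS:
            loghr = effects.get(cohort, 0.0)
            row[f"loghr_{cohort}"] = loghr
            if loghr > 0:
                direction = "high_worse"
            elif loghr < 0:
                direction = "low_worse"
            else:
                direction = "none"
            row[f"survival_direction_{cohort}"] = direction
        rows.append(row)
    return SyntheticTruth(table=pd.DataFrame(rows))


def truth_table(truth: SyntheticTruth) -> pd.DataFrame:
    """Tabular export of the ground truth; one row per gene."""
    return truth.table.copy()


def write_truth(truth: SyntheticTruth, path) -> Path:
    path = Path(path)
    truth.table.to_csv(path, index=False)
    return path


def read_truth(path) -> SyntheticTruth:
    return SyntheticTruth(table=pd.read_csv(path))
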