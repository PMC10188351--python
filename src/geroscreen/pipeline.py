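"""End-to-end pipeline orchestration, run manifests and report reconciliation.

``run_pipeline`` executes correlate -> differential expression -> survival ->
strategies -> rank over a dataset collection, writing every stage's table as
CSV into a run directory plus a JSON run manifest with the SHA-256 hash and
row count of each output. The pipeline is a pure function of (config, input
files): identical inputs produce byte-identical outputs and manifests.

``render_report`` re-reads a completed run directory, verifies the file
hashes, recounts the stage tables and emits a summary (counts per stage,
UpSet intersection tables, survival heatmap, strategy gene lists); any
discrepancy between manifest and files is reported as a reconciliation
failure.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import age_correlation as ac
from . import expression_meta as em
from . import strategy_engine as se
from . import survival_screen as sv
from .datasets import CohortSpec, DatasetCollection, ValidationError, load_collection

logger = logging.getLogger("geroscreen")

FLOAT_FORMAT = "%.12g"


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on; thresholds default to the
    screening rules this pipeline implements (sign support = all datasets but
    one, alpha = 0.05 on combined and log-rank p, cohort bounds 45/60 years)."""

    manifest: Path
    out_dir: Path
    min_support: int | None = None  # None -> n_age_datasets - 1
    alpha_corr: float = 0.05
    alpha_de: float = 0.05
    alpha_surv: float = 0.05
    young_max: float = 45.0
    senior_min: float = 60.0
    survival_dataset_id: str | None = None  # None -> most survival samples
    aging_list: Path | None = None
    ranking: se.RankingConfig = field(default_factory=se.RankingConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_corr", "alpha_de", "alpha_surv"):
            a = getattr(self, name)
            if not 0.0 < a < 1.0:
                raise ValidationError(f"{name} must be in (0,1), got {a}")
        self.manifest = Path(self.manifest)
        self.out_dir = Path(self.out_dir)
        if self.aging_list is not None:
            self.aging_list = Path(self.aging_list)

    @property
    def cohort_spec(self) -> CohortSpec:
        return CohortSpec(young_max=self.young_max, senior_min=self.senior_min)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        base = path.parent
        for key in ("manifest", "out_dir", "aging_list"):
            if raw.get(key) is not None:
                raw[key] = base / raw[key]
        if "ranking" in raw:
            raw["ranking"] = se.RankingConfig(
                channels=[se.Channel(**c) for c in raw["ranking"]])
        return cls(**raw)

    def to_dict(self) -> dict:
        return {
            "manifest": str(self.manifest),
            "min_support": self.min_support,
            "alpha_corr": self.alpha_corr,
            "alpha_de": self.alpha_de,
            "alpha_surv": self.alpha_surv,
            "young_max": self.young_max,
            "senior_min": self.senior_min,
            "survival_dataset_id": self.survival_dataset_id,
            "aging_list": None if self.aging_list is None else str(self.aging_list),
            "ranking": [{"name": c.name, "weight": c.weight,
                         "higher_is_better": c.higher_is_better}
                        for c in self.ranking.channels],
            "seed": self.seed,
        }


def sha256_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _write_csv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)


def _pick_survival_dataset(collection: DatasetCollection,
                           dataset_id: str | None):
    if dataset_id is not None:
        return collection.get(dataset_id)
    best, best_n = None, 0
    for ds in collection:
        n = int(ds.metadata["os_time"].notna().sum())
        if n > best_n:
            best, best_n = ds, n
    if best is None:
        raise ValidationError("no dataset in the collection has survival metadata")
    return best


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run the full screen; returns the run manifest (also written as JSON).

    Stage outputs (CSV) land in ``cfg.out_dir``; any stage failure raises
    :class:`StageError` naming the stage, with earlier outputs retained.
    """
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    files: dict[str, Path] = {}
    counts: dict[str, int] = {}
    stage_log: list[dict] = []

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:  # noqa: BLE001 - re-raised with stage context
            raise StageError(name, exc) from exc
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        stage_log.append({"stage": name,
                          "seconds": round(time.perf_counter() - t0, 3)})
        return result

    collection = _stage("load", lambda: load_collection(cfg.manifest))

    def _correlate():
        per_ds = ac.per_dataset_correlations(collection)
        n_used = per_ds["dataset_id"].nunique()
        min_support = cfg.min_support or max(1, n_used - 1)
        combined = ac.combine_results(per_ds, min_support=min_support,
                                      alpha=cfg.alpha_corr)
        lists = ac.sign_lists_per_dataset(per_ds)
        upset_pos = ac.upset_counts(lists["positive"], min_degree=min_support)
        upset_neg = ac.upset_counts(lists["negative"], min_degree=min_support)
        _write_csv(per_ds, out / "per_dataset_correlations.csv")
        _write_csv(combined, out / "combined_correlations.csv")
        _write_csv(upset_pos, out / "upset_positive.csv")
        _write_csv(upset_neg, out / "upset_negative.csv")
        for name in ("per_dataset_correlations", "combined_correlations",
                     "upset_positive", "upset_negative"):
            files[name] = out / f"{name}.csv"
        counts["datasets_correlated"] = int(n_used)
        counts["min_support"] = int(min_support)
        for sign in ("positive", "negative"):
            m = combined["sign"] == sign
            counts[f"{sign}_sign_consistent"] = int(m.sum())
            counts[f"{sign}_significant"] = int((m & combined["significant"]).sum())
        return combined

    combined = _stage("correlate", _correlate)

    def _de():
        per_ds = em.de_collection(collection)
        meta = em.combine_de(per_ds, alpha=cfg.alpha_de)
        _write_csv(per_ds, out / "de_per_dataset.csv")
        _write_csv(meta, out / "de_meta.csv")
        files["de_per_dataset"] = out / "de_per_dataset.csv"
        files["de_meta"] = out / "de_meta.csv"
        counts["de_datasets"] = int(per_ds["dataset_id"].nunique()) if len(per_ds) else 0
        counts["de_significant_genes"] = int((meta["combined_q"] < cfg.alpha_de).sum())
        return meta

    meta_de = _stage("de", _de)

    def _survival():
        ds = _pick_survival_dataset(collection, cfg.survival_dataset_id)
        sig_genes = sorted(combined.loc[combined["significant"]
                                        & combined["sign"].isin(["positive", "negative"]),
                                        "gene"])
        results = sv.screen_survival(ds, sig_genes, spec=cfg.cohort_spec,
                                     alpha=cfg.alpha_surv)
        heat = sv.heatmap_table(results)
        _write_csv(results, out / "survival_results.csv")
        _write_csv(heat, out / "survival_heatmap.csv", index=True)
        files["survival_results"] = out / "survival_results.csv"
        files["survival_heatmap"] = out / "survival_heatmap.csv"
        counts["survival_dataset"] = 0  # replaced below; keep key order stable
        counts["survival_genes_tested"] = len(sig_genes)
        counts["survival_stratifying_genes"] = len(sv.stratifying_genes(results))
        counts["survival_dataset"] = len(ds.samples)
        return results

    survival_results = _stage("survival", _survival)

    def _strategies():
        s1 = se.strategy1(combined, survival_results)
        s2 = se.strategy2(combined, survival_results)
        strategies = {"S1": s1, "S2": s2}
        if cfg.aging_list is not None:
            aging = se.read_gene_list(cfg.aging_list)
            strategies["S3"] = se.strategy3(combined, aging)
        for sid, res in strategies.items():
            path = out / f"strategy_{sid}.csv"
            _write_csv(res.provenance, path)
            files[f"strategy_{sid}"] = path
            counts[f"strategy_{sid}_genes"] = len(res.genes)
        return strategies

    strategies = _stage("strategies", _strategies)

    def _rank():
        candidates = sorted(set().union(*(set(r.genes) for r in strategies.values())))
        evidence = se.build_evidence(combined, meta_de, survival_results)
        ranked = se.rank_targets(candidates, evidence, cfg.ranking)
        _write_csv(ranked, out / "ranked_targets.csv")
        files["ranked_targets"] = out / "ranked_targets.csv"
        counts["ranked_targets"] = len(ranked)
        return ranked

    _stage("rank", _rank)

    manifest = {
        "config": cfg.to_dict(),
        "counts": counts,
        "files": {name: {"path": path.name,
                         "sha256": sha256_file(path),
                         "rows": _count_rows(path)}
                  for name, path in sorted(files.items())},
    }
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def _count_rows(path: Path) -> int:
    with open(path) as fh:
        return max(0, sum(1 for _ in fh) - 1)  # minus header


def render_report(run_dir) -> dict:
    """Reconcile and summarize a completed run directory.

    Re-hashes every manifest file and recounts its rows; the returned report
    has ``ok=False`` and lists the mismatches if anything was tampered with or
    is missing. Also writes ``report.md`` with the stage counts, strategy gene
    lists and the survival heatmap.
    """
    run_dir = Path(run_dir)
    manifest_path = run_dir / "run_manifest.json"
    if not manifest_path.exists():
        raise ValidationError(f"{run_dir}: run_manifest.json not found")
    manifest = json.loads(manifest_path.read_text())
    failures = []
    for name, entry in manifest["files"].items():
        path = run_dir / entry["path"]
        if not path.exists():
            failures.append({"file": name, "problem": "missing"})
            continue
        digest = sha256_file(path)
        if digest != entry["sha256"]:
            failures.append({"file": name, "problem": "hash mismatch"})
        rows = _count_rows(path)
        if rows != entry["rows"]:
            failures.append({"file": name, "problem": f"row count {rows} != {entry['rows']}"})

    report = {
        "ok": not failures,
        "reconciliation_failures": failures,
        "counts": manifest["counts"],
        "strategies": {},
    }
    for sid in ("S1", "S2", "S3"):
        key = f"strategy_{sid}"
        if key in manifest["files"] and (run_dir / manifest["files"][key]["path"]).exists():
            prov = pd.read_csv(run_dir / manifest["files"][key]["path"])
            report["strategies"][sid] = list(prov["gene"]) if "gene" in prov else []

    lines = ["# geroscreen run report", ""]
    lines.append("## Reconciliation")
    lines.append("OK" if report["ok"] else f"FAILED: {failures}")
    lines.append("")
    lines.append("## Stage counts")
    for key, val in manifest["counts"].items():
        lines.append(f"- {key}: {val}")
    lines.append("")
    for sid, genes in report["strategies"].items():
        lines.append(f"## Strategy {sid} ({len(genes)} genes)")
        lines.append(", ".join(genes) if genes else "(empty)")
        lines.append("")
    heat_entry = manifest["files"].get("survival_heatmap")
    if heat_entry and (run_dir / heat_entry["path"]).exists():
        heat = pd.read_csv(run_dir / heat_entry["path"], index_col=0)
        lines.append("## Survival heatmap (red = significant split)")
        lines.append(heat.to_string())
        lines.append("")
    (run_dir / "report.md").write_text("\n".join(lines))
    return report
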