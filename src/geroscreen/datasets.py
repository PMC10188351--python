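"""Data model for multi-dataset expression collections with clinical metadata.

One :class:`ExpressionDataset` holds a single cohort's gene-by-sample matrix of
normalized, log2-scale expression together with per-sample clinical metadata
(group label, age in years, overall-survival time in days and event status).
A :class:`DatasetCollection` groups several cohorts over a shared gene
universe. Expression is assumed already normalized and log2-transformed
upstream; the readers validate structure but never re-normalize.

File formats are plain TSV/CSV: expression with genes in rows and a
``gene_id`` header column, metadata with columns
``sample_id, group, age, os_time, os_event`` (``os_event`` is 1 for an
observed death, 0 for censoring). A YAML manifest lists the datasets of a
collection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("geroscreen")

VALID_GROUPS = ("case", "control")
METADATA_COLUMNS = ("group", "age", "os_time", "os_event")


class ValidationError(ValueError):
    """Raised when an input file or data structure violates the data contract."""


def _sep_for(path: Path, fmt: str | None) -> str:
    if fmt is None:
        fmt = "csv" if Path(path).suffix.lower() == ".csv" else "tsv"
    if fmt not in ("tsv", "csv"):
        raise ValidationError(f"unknown format {fmt!r}; expected 'tsv' or 'csv'")
    return "\t" if fmt == "tsv" else ","


def read_expression(path, fmt: str | None = None) -> pd.DataFrame:
    """Read a gene-by-sample expression matrix.

    The first column holds gene symbols, the header row holds sample ids and
    the body is numeric (log2-scale normalized expression). Duplicate gene
    rows are collapsed by their mean with a logged warning; duplicate sample
    ids are a hard error.
    """
    path = Path(path)
    sep = _sep_for(path, fmt)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(sep)
    sample_ids = header[1:]
    dupes = pd.Index(sample_ids)[pd.Index(sample_ids).duplicated()].unique()
    if len(dupes):
        raise ValidationError(f"{path}: duplicate sample ids in header: {list(dupes)}")
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    if raw.shape[0] == 0:
        raise ValidationError(f"{path}: no data rows")
    try:
        # astype(float) converts via strtod and round-trips %.17g output exactly
        values = raw.astype(float)
    except (ValueError, TypeError):
        for col in raw.columns:
            coerced = pd.to_numeric(raw[col], errors="coerce")
            bad = coerced.isna() & raw[col].notna()
            if bad.any():
                gene = raw.index[bad][0]
                raise ValidationError(
                    f"{path}: non-numeric value {raw.loc[gene, col]!r} "
                    f"at gene {gene!r}, sample {col!r}"
                ) from None
        raise
    values = values.astype(float)
    values.index = values.index.astype(str)
    values.index.name = "gene_id"
    if values.index.duplicated().any():
        n_dup = int(values.index.duplicated().sum())
        logger.warning("%s: %d duplicate gene rows collapsed by mean", path, n_dup)
        order = values.index.drop_duplicates()
        values = values.groupby(level=0, sort=False).mean().loc[order]
    return values


def _parse_os_event(series: pd.Series, path) -> pd.Series:
    mapping = {"1": 1.0, "0": 0.0, "1.0": 1.0, "0.0": 0.0,
               "event": 1.0, "censored": 0.0}
    out = pd.Series(np.nan, index=series.index, dtype=float)
    for idx, val in series.items():
        if pd.isna(val) or str(val).strip() == "":
            continue
        key = str(val).strip().lower()
        if key not in mapping:
            raise ValidationError(
                f"{path}: invalid os_event value {val!r} for sample {idx!r} "
                "(expected 1/0 or event/censored)"
            )
        out.loc[idx] = mapping[key]
    return out


def read_metadata(path, fmt: str | None = None) -> pd.DataFrame:
    """Read per-sample clinical metadata keyed by sample id.

    Required columns: ``sample_id`` and ``group`` (case/control). Optional:
    ``age`` (years), ``os_time`` (days) and ``os_event`` (1 = death observed,
    0 = censored). Blank or NA cells become missing; ``os_event`` must be
    present for exactly the samples that have ``os_time``.
    """
    path = Path(path)
    sep = _sep_for(path, fmt)
    raw = pd.read_csv(path, sep=sep, dtype=str)
    for col in ("sample_id", "group"):
        if col not in raw.columns:
            raise ValidationError(f"{path}: required column {col!r} missing")
    if raw["sample_id"].duplicated().any():
        dupes = raw.loc[raw["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample ids: {dupes}")
    meta = pd.DataFrame(index=pd.Index(raw["sample_id"].astype(str), name="sample_id"))
    group = raw["group"].astype(str).str.strip().str.lower().values
    bad = sorted(set(group) - set(VALID_GROUPS))
    if bad:
        raise ValidationError(
            f"{path}: unknown group labels {bad}; expected one of {list(VALID_GROUPS)}"
        )
    meta["group"] = group
    for col in ("age", "os_time"):
        if col in raw.columns:
            try:
                meta[col] = raw[col].to_numpy(dtype=object).astype(float)
            except (ValueError, TypeError) as exc:
                raise ValidationError(f"{path}: non-numeric {col!r} value ({exc})") from None
        else:
            meta[col] = np.nan
    if "os_event" in raw.columns:
        meta["os_event"] = _parse_os_event(
            pd.Series(raw["os_event"].values, index=meta.index), path
        ).values
    else:
        meta["os_event"] = np.nan
    mismatched = meta.index[meta["os_time"].notna() != meta["os_event"].notna()]
    if len(mismatched):
        raise ValidationError(
            f"{path}: os_time/os_event present without the other for samples: "
            f"{list(mismatched)}"
        )
    if (meta["age"].dropna() < 0).any() or (meta["os_time"].dropna() < 0).any():
        raise ValidationError(f"{path}: negative age or os_time")
    return meta


@dataclass
class ExpressionDataset:
    """One cohort: expression matrix plus aligned per-sample clinical metadata.

    ``values`` is a genes x samples DataFrame; ``metadata`` is indexed by
    sample id, in the same order as ``values.columns``, with columns
    ``group``, ``age``, ``os_time`` and ``os_event`` (1.0/0.0/NaN).
    """

    dataset_id: str
    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.values.index.duplicated().any():
            raise ValidationError(f"{self.dataset_id}: duplicate gene symbols")
        if self.values.columns.duplicated().any():
            raise ValidationError(f"{self.dataset_id}: duplicate sample ids")
        if not self.metadata.index.equals(self.values.columns.astype(str).rename("sample_id")):
            raise ValidationError(
                f"{self.dataset_id}: metadata samples do not match matrix samples; "
                "use ExpressionDataset.from_frames to align"
            )
        if not self.metadata["group"].isin(VALID_GROUPS).all():
            raise ValidationError(f"{self.dataset_id}: invalid group labels")
        if (self.metadata["os_time"].notna() != self.metadata["os_event"].notna()).any():
            raise ValidationError(f"{self.dataset_id}: os_time/os_event pairing violated")

    @classmethod
    def from_frames(cls, dataset_id: str, values: pd.DataFrame,
                    metadata: pd.DataFrame) -> "ExpressionDataset":
        """Build a dataset, restricting and ordering metadata to the matrix samples.

        Matrix samples absent from the metadata are a hard error; metadata
        samples absent from the matrix are dropped with a logged count.
        """
        values = values.copy()
        values.columns = values.columns.astype(str)
        missing = [s for s in values.columns if s not in metadata.index]
        if missing:
            raise ValidationError(
                f"{dataset_id}: samples missing from metadata: {missing}"
            )
        extra = metadata.index.difference(values.columns)
        if len(extra):
            logger.info("%s: dropped %d metadata samples not in matrix",
                        dataset_id, len(extra))
        meta = metadata.loc[values.columns, list(METADATA_COLUMNS)].copy()
        meta.index.name = "sample_id"
        return cls(dataset_id=dataset_id, values=values, metadata=meta)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def case_mask(self) -> pd.Series:
        return self.metadata["group"] == "case"

    def to_dir(self, out_dir, fmt: str = "tsv") -> tuple[Path, Path]:
        """Write ``<id>_expression`` and ``<id>_metadata`` files; returns paths."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        sep = "\t" if fmt == "tsv" else ","
        expr_path = out_dir / f"{self.dataset_id}_expression.{fmt}"
        meta_path = out_dir / f"{self.dataset_id}_metadata.{fmt}"
        # %.17g guarantees binary round-trip of float64 values
        self.values.to_csv(expr_path, sep=sep, float_format="%.17g")
        meta = self.metadata.copy()
        meta["os_event"] = meta["os_event"].map(
            lambda v: "" if pd.isna(v) else str(int(v)))
        meta.to_csv(meta_path, sep=sep, float_format="%.17g")
        return expr_path, meta_path


def load_dataset(dataset_id: str, expression_path, metadata_path,
                 fmt: str | None = None) -> ExpressionDataset:
    values = read_expression(expression_path, fmt=fmt)
    metadata = read_metadata(metadata_path, fmt=fmt)
    return ExpressionDataset.from_frames(dataset_id, values, metadata)


@dataclass
class DatasetCollection:
    """A list of cohorts sharing a gene universe (union of member gene lists)."""

    datasets: list[ExpressionDataset] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [ds.dataset_id for ds in self.datasets]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate dataset ids: {ids}")

    @property
    def gene_universe(self) -> list[str]:
        universe: set[str] = set()
        for ds in self.datasets:
            universe.update(ds.genes)
        return sorted(universe)

    def __iter__(self):
        return iter(self.datasets)

    def __len__(self) -> int:
        return len(self.datasets)

    def get(self, dataset_id: str) -> ExpressionDataset:
        for ds in self.datasets:
            if ds.dataset_id == dataset_id:
                return ds
        raise KeyError(dataset_id)


def assemble_collection(parts) -> DatasetCollection:
    """Assemble a DatasetCollection from datasets or (id, values, metadata) triples.

    Metadata is restricted and ordered to each matrix's samples. The function
    is idempotent: re-assembling its own output changes nothing.
    """
    datasets = []
    for part in parts:
        if isinstance(part, ExpressionDataset):
            datasets.append(ExpressionDataset.from_frames(
                part.dataset_id, part.values, part.metadata))
        else:
            dataset_id, values, metadata = part
            datasets.append(ExpressionDataset.from_frames(dataset_id, values, metadata))
    return DatasetCollection(datasets=datasets)


def write_collection(collection: DatasetCollection, out_dir,
                     manifest_name: str = "manifest.yaml", fmt: str = "tsv") -> Path:
    """Write every dataset plus a YAML manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for ds in collection:
        expr_path, meta_path = ds.to_dir(out_dir, fmt=fmt)
        entries.append({
            "dataset_id": ds.dataset_id,
            "expression": expr_path.name,
            "metadata": meta_path.name,
        })
    manifest_path = out_dir / manifest_name
    with open(manifest_path, "w") as fh:
        yaml.safe_dump({"datasets": entries}, fh, sort_keys=False)
    return manifest_path


def load_collection(manifest_path) -> DatasetCollection:
    """Load a DatasetCollection from a YAML manifest (paths relative to it)."""
    manifest_path = Path(manifest_path)
    with open(manifest_path) as fh:
        manifest = yaml.safe_load(fh)
    if not manifest or "datasets" not in manifest:
        raise ValidationError(f"{manifest_path}: manifest has no 'datasets' entry")
    base = manifest_path.parent
    datasets = []
    for entry in manifest["datasets"]:
        expr = base / entry["expression"]
        meta = base / entry["metadata"]
        for p in (expr, meta):
            if not p.exists():
                raise ValidationError(
                    f"dataset {entry['dataset_id']!r}: file not found: {p}")
        datasets.append(load_dataset(entry["dataset_id"], expr, meta))
    return DatasetCollection(datasets=datasets)


@dataclass(frozen=True)
class CohortSpec:
    """Age-cohort boundaries in years.

    ``young_max`` is the exclusive upper bound of the young cohort and
    ``senior_min`` the exclusive lower bound of the senior cohort; ages in
    [young_max, senior_min] fall in the middle cohort (both ends inclusive).
    """

    young_max: float = 45.0
    senior_min: float = 60.0

    def __post_init__(self) -> None:
        if self.young_max > self.senior_min:
            raise ValidationError(
                f"young_max ({self.young_max}) must be <= senior_min ({self.senior_min})")


COHORTS = ("young", "middle", "senior")
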