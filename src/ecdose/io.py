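"""Tabular readers/writers and run configuration.

TSV is the canonical dialect; CSV is accepted on read (sniffed from the
header line). Count matrices are genes x samples with the gene id in the
first column; a separate sample sheet maps sample id to dose and
replicate.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import ConstructMeta, ReporterDataset
from .model import DEFAULT_DOSES
from .pipeline import CountMatrix

__all__ = [
    "read_counts",
    "write_counts",
    "read_samples",
    "read_reporters",
    "write_reporters",
    "RunConfig",
]


def _sep(path: Path) -> str:
    with open(path, "r", newline="") as fh:
        header = fh.readline()
    return "," if ("," in header and "\t" not in header) else "\t"


def read_counts(counts_path, samples_path=None) -> CountMatrix | pd.DataFrame:
    """Read a count matrix (and, if given, its sample sheet).

    Validates that every entry is a nonnegative integer and that gene
    ids are unique; parse errors name the offending gene and sample.
    With ``samples_path`` a :class:`~ecdose.pipeline.CountMatrix` is
    returned, otherwise the raw DataFrame.
    """
    counts_path = Path(counts_path)
    df = pd.read_csv(counts_path, sep=_sep(counts_path), index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{counts_path}: duplicated gene id {dup!r}")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            gene = df.index[numeric.isna()][0]
            raise ValueError(
                f"{counts_path}: non-numeric count at gene {gene!r}, sample {col!r}"
            )
        if (numeric < 0).any():
            gene = df.index[numeric < 0][0]
            raise ValueError(
                f"{counts_path}: negative count at gene {gene!r}, sample {col!r}"
            )
        if not np.allclose(numeric, np.rint(numeric)):
            gene = df.index[numeric != np.rint(numeric)][0]
            raise ValueError(
                f"{counts_path}: non-integer count at gene {gene!r}, sample {col!r}"
            )
        df[col] = numeric.astype(np.int64)
    if samples_path is None:
        return df
    samples = read_samples(samples_path)
    return CountMatrix(counts=df, samples=samples)


def write_counts(cm: CountMatrix, counts_path, samples_path=None) -> None:
    cm.counts.to_csv(counts_path, sep="\t")
    if samples_path is not None:
        cm.samples.to_csv(samples_path, sep="\t")


def read_samples(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path), index_col=0)
    missing = {"dose_nM", "replicate"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {sorted(missing)}")
    df["dose_nM"] = df["dose_nM"].astype(float)
    return df


def read_reporters(path, constructs: dict[str, ConstructMeta]) -> ReporterDataset:
    path = Path(path)
    df = pd.read_csv(path, sep=_sep(path))
    return ReporterDataset(data=df, constructs=constructs)


def write_reporters(data: ReporterDataset, path) -> None:
    data.data.to_csv(path, sep="\t", index=False)


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run; round-trips via YAML."""

    seed: int = 0
    out_dir: str = "results"
    doses: tuple[float, ...] = DEFAULT_DOSES
    min_total: float = 500.0
    pseudocount: float | None = None  # response-feature epsilon; None = 1e-6 * max
    n_genes_per_archetype: int = 100
    reporter_sigma: float = 0.1
    reporter_replicates: int = 3
    n_starts: int = 20
    counts: str | None = None  # optional real inputs
    samples: str | None = None
    reporters: str | None = None

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "doses" in raw:
            raw["doses"] = tuple(float(d) for d in raw["doses"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        data = dataclasses.asdict(self)
        data["doses"] = list(self.doses)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)

    def to_json(self) -> str:
        data = dataclasses.asdict(self)
        data["doses"] = list(self.doses)
        return json.dumps(data, indent=2, sort_keys=True)
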