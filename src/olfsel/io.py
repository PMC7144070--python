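"""Readers and writers for the plain-text formats the pipeline consumes.

Counts: TSV, first column gene id, remaining columns samples.
Metadata: TSV with columns sample_id, regime, treatment, replicate_line, bio_rep.
Dose-response: CSV with columns concentration, mean_pi, se, n.
Descriptors: CSV, first column odorant name, remaining columns numeric.
Annotation: GMT (term, description, then tab-separated gene ids).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .behavior import DoseResponseCurve
from .odorspace import DescriptorMatrix

__all__ = [
    "read_counts", "write_counts",
    "read_metadata", "write_metadata",
    "read_dose_response", "read_descriptors",
    "read_gmt", "write_gmt",
    "read_gene_list", "write_gene_list",
]

_META_COLUMNS = ["sample_id", "regime", "treatment", "replicate_line", "bio_rep"]


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.astype(int)


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t")
    missing = [c for c in _META_COLUMNS if c not in meta.columns]
    if missing:
        raise ValueError(f"metadata is missing column(s) {missing}")
    return meta


def write_metadata(metadata: pd.DataFrame, path) -> None:
    metadata.to_csv(path, sep="\t", index=False)


def read_dose_response(path) -> DoseResponseCurve:
    df = pd.read_csv(path)
    for col in ("concentration", "mean_pi"):
        if col not in df.columns:
            raise ValueError(f"dose-response CSV is missing column {col!r}")
    df = df.sort_values("concentration")
    return DoseResponseCurve(
        concentrations=tuple(df["concentration"].astype(float)),
        mean_pi=tuple(df["mean_pi"].astype(float)),
        se=tuple(df["se"].astype(float)) if "se" in df else (),
        n=tuple(df["n"].astype(int)) if "n" in df else (),
    )


def read_descriptors(path) -> DescriptorMatrix:
    return DescriptorMatrix.from_csv(path)


def read_gmt(path) -> dict[str, set]:
    """GMT: one term per line — term id, description, then gene ids."""
    annotation: dict[str, set] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        annotation[fields[0]] = set(g for g in fields[2:] if g)
    return annotation


def write_gmt(annotation: Mapping[str, set], path, descriptions: Mapping[str, str] | None = None) -> None:
    lines = []
    for term, genes in annotation.items():
        desc = (descriptions or {}).get(term, "na")
        lines.append("\t".join([term, desc, *sorted(genes)]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gene_list(path) -> set:
    return {line.strip() for line in Path(path).read_text().splitlines() if line.strip()}


def write_gene_list(genes, path) -> None:
    Path(path).write_text("\n".join(sorted(genes)) + "\n")
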