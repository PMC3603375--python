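"""Readers and writers for the plain-text formats used across the pipeline.

Expression travels as TSV with probes in rows (first column the probe ID,
header row of sample IDs); clinical tables as CSV; signature models as JSON;
gene-set collections as GMT (tab-separated: name, description, genes...).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix

__all__ = [
    "read_expression_tsv",
    "write_expression_tsv",
    "read_clinical_csv",
    "write_clinical_csv",
    "read_gmt",
    "write_gmt",
    "read_exclusion_list",
]


def write_expression_tsv(matrix: ExpressionMatrix, path) -> None:
    df = matrix.values.copy()
    df.index.name = "probe_id"
    df.to_csv(path, sep="\t", na_rep="NA")


def read_expression_tsv(path, dataset_id: str | None = None) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    df.index = df.index.astype(str)
    return ExpressionMatrix(values=df.astype(float), dataset_id=dataset_id)


def write_clinical_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_clinical_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, dtype={"sample_id": str})


def read_exclusion_list(path) -> list[str]:
    """Plain text, one sample ID per line; blank lines and '#' comments skipped."""
    out: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def read_gmt(path) -> dict[str, set[str]]:
    """Parse a GMT gene-set file into {set name: set of gene symbols}.

    The second (description) column is discarded; duplicate set names raise.
    """
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
        name = fields[0]
        if name in sets:
            raise ValueError(f"duplicate gene-set name {name!r}")
        genes = {g for g in fields[2:] if g}
        if not genes:
            raise ValueError(f"gene set {name!r} is empty")
        sets[name] = genes
    return sets


def write_gmt(sets: dict[str, set[str]], path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *sorted(genes)])
        for name, genes in sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonable) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
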