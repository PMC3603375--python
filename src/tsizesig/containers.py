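"""Core in-memory containers for expression and clinical data.

An :class:`ExpressionMatrix` holds a genes x samples block of log-scale
measurements (log2 ratios for two-channel discovery arrays, log2 intensities
for single-channel validation arrays).  Missing values are encoded as NaN in
``values``; the boolean ``mask`` property mirrors them.  Two-channel arrays
may additionally carry per-spot mean intensities (the A of an MA plot) and
per-spot quality flags from the image analysis software.

Clinical annotation travels as a plain :class:`pandas.DataFrame` with a
documented column dictionary (see :data:`CLINICAL_COLUMNS`); helper
functions validate it and load the packaged discovery-cohort table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CLINICAL_COLUMNS",
    "validate_clinical",
    "load_table1_clinical",
]


#: Column dictionary for clinical tables.  Optional columns may be absent.
CLINICAL_COLUMNS = {
    "sample_id": "unique sample identifier (string)",
    "stage": "T category, 'T1' or 'T2' (derived from size_cm)",
    "size_cm": "largest tumor diameter in cm, > 0",
    "grade": "histological grade 1-3 (printed intermediate values like '1-2' allowed)",
    "node": "lymph node status 0/1/2; positive means > 0",
    "er": "estrogen receptor status, 'Positive'/'Negative'",
    "pgr": "progesterone receptor status, 'Positive'/'Negative'",
    "subtype": "molecular subtype label (optional)",
    "dataset_id": "source dataset identifier (optional; validation compendia)",
    "dmfs_months": "distant-metastasis-free survival time in months (optional)",
    "dmfs_event": "1 = distant metastasis observed, 0 = censored (optional)",
    "recurrence": "recurrence/metastasis annotation ('Yes', 'New BC' or empty)",
    "deceased": "vital status annotation ('Yes' or empty)",
}


@dataclass
class ExpressionMatrix:
    """Genes x samples expression block with optional spot-level metadata.

    Parameters
    ----------
    values
        DataFrame indexed by probe ID with sample IDs as columns.  NaN marks
        a missing measurement.
    gene_symbols
        Optional Series mapping probe ID -> gene symbol (NaN = unannotated).
    intensity
        Optional per-spot mean log-intensity (A values), same shape as
        ``values``; present on two-channel discovery arrays only.
    flags
        Optional boolean per-spot poor-quality indicator, same shape as
        ``values``.
    dataset_id
        Optional label of the originating dataset (validation compendia).
    """

    values: pd.DataFrame
    gene_symbols: pd.Series | None = None
    intensity: pd.DataFrame | None = None
    flags: pd.DataFrame | None = None
    dataset_id: str | None = None
    sample_datasets: pd.Series | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate probe IDs: {list(dupes)[:5]}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample IDs: {list(dupes)[:5]}")
        vals = self.values.to_numpy(dtype=float)
        finite_or_nan = np.isfinite(vals) | np.isnan(vals)
        if not finite_or_nan.all():
            raise ValueError("expression values must be finite or NaN")
        for name in ("intensity", "flags"):
            other = getattr(self, name)
            if other is not None and other.shape != self.values.shape:
                raise ValueError(f"{name} shape {other.shape} != values shape {self.values.shape}")
        if self.gene_symbols is not None:
            self.gene_symbols = self.gene_symbols.reindex(self.values.index)

    # -- basic accessors ---------------------------------------------------
    @property
    def probe_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def mask(self) -> pd.DataFrame:
        """Boolean missing-value indicator (True = missing)."""
        return self.values.isna()

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.copy(),
            gene_symbols=None if self.gene_symbols is None else self.gene_symbols.copy(),
            intensity=None if self.intensity is None else self.intensity.copy(),
            flags=None if self.flags is None else self.flags.copy(),
            dataset_id=self.dataset_id,
            sample_datasets=None if self.sample_datasets is None else self.sample_datasets.copy(),
        )

    def subset_probes(self, probes) -> "ExpressionMatrix":
        probes = pd.Index(probes)
        return ExpressionMatrix(
            values=self.values.loc[probes],
            gene_symbols=None if self.gene_symbols is None else self.gene_symbols.loc[probes],
            intensity=None if self.intensity is None else self.intensity.loc[probes],
            flags=None if self.flags is None else self.flags.loc[probes],
            dataset_id=self.dataset_id,
            sample_datasets=self.sample_datasets,
        )


def validate_clinical(table: pd.DataFrame, require: tuple[str, ...] = ("sample_id",)) -> None:
    """Check a clinical table against the column dictionary.

    Raises ``ValueError`` on a missing required column, a non-positive tumor
    size, a stage inconsistent with the 2 cm rule, or an event indicator
    outside {0, 1}.
    """
    for col in require:
        if col not in table.columns:
            raise ValueError(f"clinical table missing required column {col!r}")
    if "size_cm" in table.columns:
        sizes = pd.to_numeric(table["size_cm"], errors="coerce")
        if (sizes <= 0).any():
            raise ValueError("size_cm must be positive")
        if "stage" in table.columns:
            expected = np.where(sizes <= 2.0, "T1", "T2")
            observed = table["stage"].astype(str).to_numpy()
            bad = (observed != expected) & sizes.notna().to_numpy() & (sizes <= 5.0).to_numpy()
            if bad.any():
                raise ValueError(
                    f"stage inconsistent with the 2 cm rule for samples "
                    f"{table.loc[bad, 'sample_id'].tolist()}"
                )
    if "dmfs_event" in table.columns:
        ev = table["dmfs_event"].dropna()
        if not ev.isin([0, 1]).all():
            raise ValueError("dmfs_event must be 0 or 1")


def load_table1_clinical() -> pd.DataFrame:
    """Load the packaged 46-patient discovery-cohort clinical table.

    The table transcribes the published patient characteristics: stage,
    tumor size, grade, node status, ER/PgR status, recurrence/metastasis
    annotation ('Yes' or 'New BC') and vital status.  Grade is kept as
    printed (one sample carries the intermediate value '1-2').
    """
    with resources.files("tsizesig.data").joinpath("table1_clinical.csv").open() as fh:
        table = pd.read_csv(fh, dtype={"sample_id": str, "grade": str}, keep_default_na=False)
    table["size_cm"] = table["size_cm"].astype(float)
    table["node"] = table["node"].astype(int)
    validate_clinical(table, require=("sample_id", "stage", "size_cm"))
    return table


def numeric_grade(grade: pd.Series) -> pd.Series:
    """Coerce printed grades to numeric, mapping intermediates like '1-2' up.

    An intermediate call records uncertainty between adjacent grades; the
    higher grade is used so downstream ordinal encodings stay in 1-3.
    """
    def _coerce(g: str) -> float:
        g = str(g).strip()
        if "-" in g:
            return float(g.split("-")[-1])
        return float(g)

    return grade.map(_coerce)
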