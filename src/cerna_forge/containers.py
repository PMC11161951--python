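"""Core in-memory containers shared across the pipeline.

Expression data live in a :class:`pandas.DataFrame` (features in rows,
samples in columns) wrapped with the RNA class and abundance unit so that
downstream stages can refuse inputs in the wrong layer (e.g. running the
count-based exact test on FPKM values).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

RNA_CLASSES = ("mRNA", "lncRNA", "circRNA", "miRNA")
UNITS = ("count", "FPKM", "RPM", "TPM")

#: nucleotide length ranges used for validation and simulation, per class
LENGTH_RANGES = {
    "mRNA": (200, 10_000),
    "lncRNA": (200, 10_000),
    "circRNA": (100, 2_000),
    "miRNA": (18, 25),
}


@dataclass
class ExpressionMatrix:
    """A feature x sample abundance matrix tagged with RNA class and unit.

    Parameters
    ----------
    data
        DataFrame with feature ids as index and sample ids as columns.
        Values must be finite and non-negative; integer-valued when
        ``unit == "count"``.
    rna_class
        One of ``mRNA``, ``lncRNA``, ``circRNA``, ``miRNA``.
    unit
        One of ``count``, ``FPKM``, ``RPM``, ``TPM``.
    """

    data: pd.DataFrame
    rna_class: str
    unit: str = "count"

    def __post_init__(self) -> None:
        if self.rna_class not in RNA_CLASSES:
            raise ValueError(f"unknown RNA class {self.rna_class!r}")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature ids: {dupes[:5]}")
        if self.data.columns.has_duplicates:
            raise ValueError("duplicate sample ids")
        values = self.data.to_numpy()
        if values.size:
            if not np.all(np.isfinite(values)):
                raise ValueError("expression values must be finite")
            if np.any(values < 0):
                raise ValueError("expression values must be non-negative")
            if self.unit == "count" and not np.allclose(values, np.round(values)):
                raise ValueError("count matrices must be integer-valued")
        self.data.index.name = "feature_id"
        self.data.columns.name = None

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def vector(self, feature_id: str) -> np.ndarray:
        """Expression of one feature across samples, in column order."""
        return self.data.loc[feature_id].to_numpy(dtype=float)


@dataclass
class FeatureAnnotation:
    """Per-feature annotation: RNA class, length, and linked genes.

    ``host_gene`` is the source gene of a circRNA (absent for intergenic
    circRNAs); ``cis_gene`` is the cis-regulated gene of a lncRNA.
    miRNA records never carry either field.
    """

    table: pd.DataFrame  # index: feature id; columns: rna_class, length, host_gene, cis_gene

    REQUIRED = ("rna_class", "length")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.table.columns:
                raise ValueError(f"annotation missing column {col!r}")
        for col in ("host_gene", "cis_gene"):
            if col not in self.table.columns:
                self.table[col] = pd.NA
        if self.table.index.has_duplicates:
            raise ValueError("duplicate feature ids in annotation")
        bad_class = set(self.table["rna_class"]) - set(RNA_CLASSES)
        if bad_class:
            raise ValueError(f"unknown RNA classes in annotation: {sorted(bad_class)}")
        lengths = self.table["length"]
        if (lengths < 1).any():
            raise ValueError("feature lengths must be >= 1 nt")
        mirna = self.table[self.table["rna_class"] == "miRNA"]
        if mirna["host_gene"].notna().any() or mirna["cis_gene"].notna().any():
            raise ValueError("miRNA features must not carry host_gene/cis_gene")

    def features_of_class(self, rna_class: str) -> list[str]:
        return list(self.table.index[self.table["rna_class"] == rna_class])

    def class_of(self, feature_id: str) -> str:
        return str(self.table.at[feature_id, "rna_class"])

    def length_of(self, feature_id: str) -> int:
        return int(self.table.at[feature_id, "length"])

    def host_gene_of(self, feature_id: str):
        value = self.table.at[feature_id, "host_gene"]
        return None if pd.isna(value) else str(value)

    def cis_gene_of(self, feature_id: str):
        value = self.table.at[feature_id, "cis_gene"]
        return None if pd.isna(value) else str(value)

    @property
    def n_features(self) -> int:
        return len(self.table)
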