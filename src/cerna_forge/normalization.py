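"""Per-class abundance normalization: FPKM, RPM and TPM.

Each RNA class is normalized against its own library pool, mirroring the
three library types of a whole-transcriptome experiment: mRNA and lncRNA
share one rRNA-depleted library (FPKM over the combined column totals),
circRNAs are quantified from back-splice junction reads (RPM), and miRNAs
from the small-RNA library (TPM, i.e. tags per million — small-RNA "TPM"
carries no length term because every tag is a full molecule).
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FeatureAnnotation

__all__ = ["compute_fpkm", "compute_rpm", "compute_tpm", "combined_library_totals"]


def combined_library_totals(*matrices: ExpressionMatrix) -> pd.Series:
    """Per-sample count totals pooled over several matrices (same samples)."""
    if not matrices:
        raise ValueError("at least one matrix required")
    samples = matrices[0].sample_ids
    for em in matrices[1:]:
        if em.sample_ids != samples:
            raise ValueError("matrices disagree on sample ids/order")
    total = sum(em.data.sum(axis=0) for em in matrices)
    return total


def _check_counts(counts: ExpressionMatrix) -> None:
    if counts.unit != "count":
        raise ValueError(f"expected raw counts, got unit {counts.unit!r}")


def compute_fpkm(
    counts: ExpressionMatrix,
    annotation: FeatureAnnotation,
    library_totals: pd.Series | None = None,
) -> ExpressionMatrix:
    """Fragments per kilobase per million mapped fragments.

    FPKM = count * 1e9 / (length_nt * library_total), where the library
    total is the per-sample column sum over the mRNA+lncRNA pool. Pass
    ``library_totals`` (from :func:`combined_library_totals`) to use the
    pooled denominator; otherwise the matrix's own column sums are used.
    """
    _check_counts(counts)
    missing = [f for f in counts.feature_ids if f not in annotation.table.index]
    if missing:
        raise ValueError(f"features without annotation/length: {missing[:5]}")
    lengths = annotation.table.loc[counts.feature_ids, "length"].to_numpy(dtype=float)
    totals = counts.data.sum(axis=0) if library_totals is None else library_totals.loc[counts.sample_ids]
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero library total for samples {bad}")
    values = counts.data.to_numpy(dtype=float) * 1e9 / (
        lengths[:, None] * totals.to_numpy(dtype=float)[None, :]
    )
    return ExpressionMatrix(
        pd.DataFrame(values, index=counts.feature_ids, columns=counts.sample_ids),
        counts.rna_class,
        "FPKM",
    )


def _per_million(counts: ExpressionMatrix, unit: str) -> ExpressionMatrix:
    _check_counts(counts)
    totals = counts.data.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero column total for samples {bad}")
    values = counts.data.to_numpy(dtype=float) * 1e6 / totals.to_numpy(dtype=float)[None, :]
    return ExpressionMatrix(
        pd.DataFrame(values, index=counts.feature_ids, columns=counts.sample_ids),
        counts.rna_class,
        unit,
    )


def compute_rpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Reads per million circRNA junction reads; columns sum to 1e6."""
    if counts.rna_class != "circRNA":
        raise ValueError("RPM applies to circRNA junction counts")
    return _per_million(counts, "RPM")


def compute_tpm(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Tags per million small-RNA clean tags; columns sum to 1e6."""
    if counts.rna_class != "miRNA":
        raise ValueError("TPM applies to miRNA tag counts")
    return _per_million(counts, "TPM")
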