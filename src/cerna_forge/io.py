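"""Text-format readers and writers for every artifact in the pipeline.

All tables are UTF-8, tab-delimited with a header row; floating-point
output uses a fixed "%.10g" format so identical inputs produce
byte-identical files. Readers validate and report malformed rows with
their line numbers; ``read(write(x)) == x`` for every pair.
"""
from __future__ import annotations

import json
from pathlib import Path


import pandas as pd

from .cerna import TargetMap
from .containers import ExpressionMatrix, FeatureAnnotation
from .simulate import SimulationConfig, TruthTable, generate_bundle

FLOAT_FORMAT = "%.10g"


# ---------------------------------------------------------------------------
# expression matrices (+ sidecar metadata)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = matrix.data.copy()
    if matrix.unit == "count":
        data = data.astype(int)
    data.index.name = "feature_id"
    data.to_csv(path, sep="\t", float_format=FLOAT_FORMAT)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(
        json.dumps({"rna_class": matrix.rna_class, "unit": matrix.unit}, indent=0)
        + "\n",
        encoding="utf-8",
    )
    return path


def read_expression_matrix(path, rna_class: str | None = None,
                           unit: str | None = None) -> ExpressionMatrix:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text(encoding="utf-8"))
        rna_class = rna_class or meta["rna_class"]
        unit = unit or meta["unit"]
    if rna_class is None or unit is None:
        raise ValueError(f"no sidecar metadata for {path}; pass rna_class and unit")
    data = pd.read_csv(path, sep="\t", index_col="feature_id")
    if data.index.has_duplicates:
        dupes = data.index[data.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate feature ids {dupes[:5]}")
    return ExpressionMatrix(data, rna_class, unit)


# ---------------------------------------------------------------------------
# annotation / design / truth


def write_annotation(annotation: FeatureAnnotation, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table = annotation.table.copy()
    table.index.name = "feature_id"
    table.to_csv(path, sep="\t", na_rep="")
    return path


def read_annotation(path) -> FeatureAnnotation:
    table = pd.read_csv(
        Path(path), sep="\t", index_col="feature_id",
        dtype={"rna_class": str, "host_gene": "string", "cis_gene": "string"},
    )
    for col in ("host_gene", "cis_gene"):
        values = table[col].replace("", pd.NA).astype(object)
        values[pd.isna(values)] = None
        table[col] = values
    return FeatureAnnotation(table)


def write_design(design: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    design[["sample_id", "group"]].to_csv(path, sep="\t", index=False)
    return path


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(Path(path), sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in design.columns:
            raise ValueError(f"{path}: design table missing column {col!r}")
    if design["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample ids in design")
    return design


def write_truth(truth: TruthTable, path) -> Path:
    """Single TSV: DE rows, planted-triplet rows and decoy-triplet rows."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("record_type\tid1\tid2\tid3\tlog2fc\n")
        for fid in sorted(truth.de_features):
            fh.write(f"de\t{fid}\t\t\t{truth.de_features[fid]:.10g}\n")
        for s, m, t in sorted(truth.planted_triplets):
            fh.write(f"triplet\t{s}\t{m}\t{t}\t\n")
        for s, m, t in sorted(truth.decoy_triplets):
            fh.write(f"decoy\t{s}\t{m}\t{t}\t\n")
    return path


def read_truth(path) -> TruthTable:
    de: dict[str, float] = {}
    planted: list[tuple[str, str, str]] = []
    decoys: list[tuple[str, str, str]] = []
    with open(Path(path), encoding="utf-8") as fh:
        header = fh.readline()
        if not header.startswith("record_type"):
            raise ValueError(f"{path}: not a truth table")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValueError(f"{path}:{lineno}: expected 5 fields, got {len(parts)}")
            kind, a, b, c, lfc = parts
            if kind == "de":
                de[a] = float(lfc)
            elif kind == "triplet":
                planted.append((a, b, c))
            elif kind == "decoy":
                decoys.append((a, b, c))
            else:
                raise ValueError(f"{path}:{lineno}: unknown record type {kind!r}")
    return TruthTable(de, planted, decoys)


# ---------------------------------------------------------------------------
# target map / GMT / SIF


def write_targets(target_map: TargetMap, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("mirna\ttarget\n")
        for mirna, target in target_map.pairs():
            fh.write(f"{mirna}\t{target}\n")
    return path


def read_targets(path) -> TargetMap:
    pairs = []
    with open(Path(path), encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header[:2] != ["mirna", "target"]:
            raise ValueError(f"{path}: expected header 'mirna<TAB>target'")
        for lineno, line in enumerate(fh, start=2):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not all(parts):
                raise ValueError(f"{path}:{lineno}: malformed relation row")
            pairs.append((parts[0], parts[1]))
    if not pairs:
        raise ValueError(f"{path}: empty target map")
    return TargetMap.from_pairs(pairs)


def write_gmt(term_map: dict[str, tuple[str, list[str]]], path) -> Path:
    """Standard GMT: term <TAB> description <TAB> member genes..."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for term_id in sorted(term_map):
            description, members = term_map[term_id]
            fh.write("\t".join([term_id, description, *members]) + "\n")
    return path


def read_gmt(path) -> dict[str, tuple[str, list[str]]]:
    terms: dict[str, tuple[str, list[str]]] = {}
    with open(Path(path), encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs term, description and >= 1 gene"
                )
            term_id, description, *members = parts
            if term_id in terms:
                raise ValueError(f"{path}:{lineno}: duplicate term {term_id!r}")
            terms[term_id] = (description, members)
    return terms


def read_sif(path) -> list[tuple[str, str, str]]:
    edges = []
    with open(Path(path), encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: SIF rows are a<TAB>relation<TAB>b")
            edges.append(tuple(parts))
    return edges


# ---------------------------------------------------------------------------
# bundle writer (simulate CLI)


def write_bundle(bundle: dict, outdir) -> dict[str, Path]:
    """Write a generated bundle to ``outdir`` in the standard file layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config: SimulationConfig = bundle["config"]
    paths: dict[str, Path] = {}
    for cls, matrix in bundle["counts"].items():
        paths[f"counts_{cls}"] = write_expression_matrix(
            matrix, outdir / f"counts_{cls}.tsv"
        )
    paths["annotation"] = write_annotation(bundle["annotation"], outdir / "annotation.tsv")
    design = pd.DataFrame(
        {
            "sample_id": config.sample_ids,
            "group": [g for g in config.group_names for _ in range(config.n_replicates)],
        }
    )
    paths["design"] = write_design(design, outdir / "design.tsv")
    paths["targets"] = write_targets(bundle["target_map"], outdir / "targets.tsv")
    paths["terms"] = write_gmt(bundle["terms"], outdir / "terms.gmt")
    paths["truth"] = write_truth(bundle["truth"], outdir / "truth.tsv")
    return paths


def simulate_to_dir(config: SimulationConfig, outdir) -> dict[str, Path]:
    """Generate a bundle from ``config`` and write it to ``outdir``."""
    return write_bundle(generate_bundle(config), outdir)
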