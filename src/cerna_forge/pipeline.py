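"""End-to-end orchestration: normalize -> DE -> enrichment -> ceRNA -> export.

Configuration is a flat key=value text file (overridable per key), and a
run manifest capturing the config hash, seed and package version is
written next to the outputs, so a run is fully reproducible from its
output directory alone.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .cerna import (
    build_cerna_network,
    export_network,
    select_coexpr_pairs,
    select_mirna_pairs,
)
from .containers import RNA_CLASSES
from .diffexpr import run_de
from .enrichment import enrich_terms, map_to_genes
from .io import (
    FLOAT_FORMAT,
    read_annotation,
    read_design,
    read_expression_matrix,
    read_gmt,
    read_targets,
    write_expression_matrix,
)
from .normalization import combined_library_totals, compute_fpkm, compute_rpm, compute_tpm

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and thresholds for one pipeline run."""

    counts_dir: str
    annotation: str
    targets: str
    terms: str
    design: str
    outdir: str
    scc_max: float = -0.7
    pcc_min: float = 0.9
    alpha_sponge: float = 0.05
    alpha_de: float = 0.05
    lfc_min: float = 1.0
    universe: str = "de"  # "de" | "map": miRNA universe for the sponge test
    seed: int = 0

    def __post_init__(self) -> None:
        if not -1.0 <= self.scc_max <= 1.0:
            raise ValueError("scc_max must lie in [-1, 1]")
        if not -1.0 <= self.pcc_min <= 1.0:
            raise ValueError("pcc_min must lie in [-1, 1]")
        for name in ("alpha_sponge", "alpha_de"):
            if not 0.0 < getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")
        if self.universe not in ("de", "map"):
            raise ValueError("universe must be 'de' or 'map'")

    @classmethod
    def from_file(cls, path, overrides: dict | None = None) -> "PipelineConfig":
        """Parse a flat key=value config file; '#' starts a comment line."""
        values: dict[str, str] = {}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            values[key.strip()] = value.strip()
        if overrides:
            values.update({k: str(v) for k, v in overrides.items()})
        field_types = {f.name: f.type for f in dataclasses.fields(cls)}
        unknown = set(values) - set(field_types)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced: dict = {}
        for key, raw in values.items():
            ftype = field_types[key]
            if ftype == "float":
                coerced[key] = float(raw)
            elif ftype == "int":
                coerced[key] = int(raw)
            else:
                coerced[key] = raw
        return cls(**coerced)

    def content_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


_NORMALIZERS = {"mRNA": "FPKM", "lncRNA": "FPKM", "circRNA": "RPM", "miRNA": "TPM"}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and return the run report (also written as JSON).

    Stages: read inputs, per-class normalization, per-class DE + screening,
    per-class term enrichment of the mapped gene lists, three-filter
    ceRNA network construction, and export. Any stage error aborts with the
    stage name attached. Deterministic given config + inputs.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stage = "read_inputs"
    try:
        counts_dir = Path(config.counts_dir)
        counts = {
            cls: read_expression_matrix(counts_dir / f"counts_{cls}.tsv",
                                        rna_class=cls, unit="count")
            for cls in RNA_CLASSES
        }
        annotation = read_annotation(config.annotation)
        target_map = read_targets(config.targets)
        term_map = read_gmt(config.terms)
        design = read_design(config.design)

        stage = "normalize"
        rna_totals = combined_library_totals(counts["mRNA"], counts["lncRNA"])
        normalized = {
            "mRNA": compute_fpkm(counts["mRNA"], annotation, rna_totals),
            "lncRNA": compute_fpkm(counts["lncRNA"], annotation, rna_totals),
            "circRNA": compute_rpm(counts["circRNA"]),
            "miRNA": compute_tpm(counts["miRNA"]),
        }
        for cls, matrix in normalized.items():
            write_expression_matrix(matrix, outdir / f"normalized_{cls}.tsv")

        stage = "differential_expression"
        de_tables: dict[str, pd.DataFrame] = {}
        de_sets: dict[str, set[str]] = {}
        for cls in RNA_CLASSES:
            table = run_de(counts[cls], design,
                           lfc_min=config.lfc_min, alpha=config.alpha_de)
            table.to_csv(outdir / f"de_{cls}.tsv", sep="\t", float_format=FLOAT_FORMAT)
            de_tables[cls] = table
            de_sets[cls] = set(table.index[table["status"] != "ns"])
            logger.info("DE %s: %d features, %d significant",
                        cls, len(table), len(de_sets[cls]))

        stage = "enrichment"
        background = set()
        for _, members in term_map.values():
            background.update(members)
        enrichment_report = {}
        for cls in RNA_CLASSES:
            genes = map_to_genes(sorted(de_sets[cls]), annotation, cls,
                                 target_map=target_map)
            in_bg = sorted(set(genes) & background)
            dropped = len(genes) - len(in_bg)
            if dropped:
                logger.info("enrichment %s: %d genes outside the annotated background",
                            cls, dropped)
            table = enrich_terms(in_bg, term_map, background)
            table.to_csv(outdir / f"enrichment_{cls}.tsv", sep="\t", index=False,
                         float_format=FLOAT_FORMAT)
            enrichment_report[cls] = {
                "source_genes": len(in_bg),
                "dropped_unannotated": dropped,
                "terms_p_lt_0.05": int((table["pvalue"] < 0.05).sum()),
            }

        stage = "cerna_network"
        mirna_pairs = select_mirna_pairs(normalized, target_map, de_sets,
                                         scc_max=config.scc_max)
        coexpr_pairs = select_coexpr_pairs(normalized, de_sets,
                                           pcc_min=config.pcc_min)
        if config.universe == "de":
            universe_size = len(set(target_map.mirnas) & de_sets["miRNA"])
        else:
            universe_size = target_map.universe_size
        universe_size = max(universe_size, 1)
        class_of = {f: cls for cls, em in normalized.items() for f in em.feature_ids}
        network = build_cerna_network(
            mirna_pairs, coexpr_pairs, target_map,
            alpha=config.alpha_sponge, universe_size=universe_size,
            class_of=class_of,
        )

        stage = "export"
        export_network(network, outdir)
        report = {
            "features_per_class": {cls: counts[cls].n_features for cls in RNA_CLASSES},
            "de_per_class": {
                cls: {
                    "up": int((de_tables[cls]["status"] == "up").sum()),
                    "down": int((de_tables[cls]["status"] == "down").sum()),
                    "total": len(de_sets[cls]),
                }
                for cls in RNA_CLASSES
            },
            "enrichment": enrichment_report,
            "network": {
                "nodes_per_class": network.node_counts(),
                "pairs": network.pair_counts(),
                "n_mirna_pairs_anticorr": len(mirna_pairs),
                "n_coexpr_pairs": len(coexpr_pairs),
                "n_sponge_tests": len(network.sponge_tests),
            },
        }
        (outdir / "report.json").write_text(
            json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        manifest = {
            "config_hash": config.content_hash(),
            "seed": config.seed,
            "version": __version__,
            "config": dataclasses.asdict(config),
        }
        (outdir / "run_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


# ---------------------------------------------------------------------------
# RT-qPCR relative quantification


def relative_quantification(
    target_ct_case: float,
    ref_ct_case: float,
    target_ct_ctrl: float,
    ref_ct_ctrl: float,
) -> float:
    """Relative expression by the 2^-ddCT method.

    dCT = target CT - reference CT per condition; ddCT = dCT_case -
    dCT_control; the relative quantity is 2**(-ddCT) (1 when ddCT = 0).
    """
    cts = (target_ct_case, ref_ct_case, target_ct_ctrl, ref_ct_ctrl)
    for ct in cts:
        if not (ct > 0 and ct == ct and ct != float("inf")):
            raise ValueError("CT values must be finite and positive")
    delta_case = target_ct_case - ref_ct_case
    delta_ctrl = target_ct_ctrl - ref_ct_ctrl
    return float(2.0 ** -(delta_case - delta_ctrl))
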