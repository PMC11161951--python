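"""Hypergeometric term enrichment of DE-derived gene lists.

Each RNA class is mapped to a gene list before testing: mRNAs stand for
themselves, circRNAs for their host (source) genes — intergenic circRNAs
are dropped — lncRNAs for their cis-regulated genes, and miRNAs for their
mRNA targets from the interaction map. Per term, the enrichment P is the
hypergeometric upper tail

    P = 1 - sum_{i=0}^{m-1} C(M,i) C(N-M, n-i) / C(N, n)

with N annotated genes, n source genes, M genes in the term and m source
genes in the term. BH FDR across terms is reported alongside the raw P.
"""
from __future__ import annotations

import logging

import pandas as pd

from .cerna import TargetMap
from .containers import FeatureAnnotation
from .stats import bh_adjust, hypergeom_tail

logger = logging.getLogger(__name__)

__all__ = ["map_to_genes", "enrich_terms"]


def map_to_genes(
    de_features,
    annotation: FeatureAnnotation,
    rna_class: str,
    target_map: TargetMap | None = None,
) -> list[str]:
    """Translate a DE feature list into a deduplicated gene list.

    mRNA -> the feature itself; circRNA -> host gene (intergenic circRNAs
    dropped); lncRNA -> cis gene; miRNA -> mRNA-class targets from the
    interaction map. Dropped features are logged with counts.
    """
    de_features = list(de_features)
    missing = [f for f in de_features if f not in annotation.table.index]
    if missing:
        raise ValueError(f"features missing from annotation: {missing[:5]}")
    genes: set[str] = set()
    dropped = 0
    if rna_class == "mRNA":
        genes.update(de_features)
    elif rna_class == "circRNA":
        for fid in de_features:
            host = annotation.host_gene_of(fid)
            if host is None:
                dropped += 1
            else:
                genes.add(host)
    elif rna_class == "lncRNA":
        for fid in de_features:
            cis = annotation.cis_gene_of(fid)
            if cis is None:
                dropped += 1
            else:
                genes.add(cis)
    elif rna_class == "miRNA":
        if target_map is None:
            raise ValueError("miRNA gene mapping requires a target map")
        mrna = set(annotation.features_of_class("mRNA"))
        for fid in de_features:
            targets = target_map.targets_of(fid) & mrna
            if not targets:
                dropped += 1
            genes.update(targets)
    else:
        raise ValueError(f"unknown RNA class {rna_class!r}")
    if dropped:
        logger.info("map_to_genes(%s): dropped %d of %d features without a gene",
                    rna_class, dropped, len(de_features))
    return sorted(genes)


def enrich_terms(
    source_genes,
    term_map: dict[str, tuple[str, list[str]]],
    background=None,
) -> pd.DataFrame:
    """Hypergeometric enrichment of ``source_genes`` against every term.

    ``background`` defaults to the union of all term members (all genes
    with any annotation); source genes outside it are an error. Returns a
    table with N, n, M, m, pvalue and BH FDR per term, sorted by p then id.
    """
    source = set(source_genes)
    if background is None:
        background = set()
        for _, members in term_map.values():
            background.update(members)
    else:
        background = set(background)
    offenders = sorted(source - background)
    if offenders:
        raise ValueError(f"source genes absent from background: {offenders[:10]}")
    N = len(background)
    n = len(source)
    rows = []
    for term_id in sorted(term_map):
        description, members = term_map[term_id]
        term_genes = set(members) & background
        M = len(term_genes)
        m = len(source & term_genes)
        p = hypergeom_tail(m, N, M, n)
        rows.append((term_id, description, N, n, M, m, p))
    table = pd.DataFrame(
        rows, columns=["term_id", "description", "N", "n", "M", "m", "pvalue"]
    )
    table["fdr"] = bh_adjust(table["pvalue"]) if len(table) else []
    return (
        table.sort_values(["pvalue", "term_id"], kind="mergesort")
        .reset_index(drop=True)
    )
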