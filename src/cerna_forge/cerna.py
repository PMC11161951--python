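"""ceRNA (competing endogenous RNA) network construction.

A sponge candidate (circRNA or lncRNA) and an mRNA enter the network when
three filters all pass, mirroring standard ceRNA practice:

1. each member is anti-correlated with at least one shared miRNA that
   targets it (Spearman rank correlation below ``scc_max``, default -0.7),
2. sponge and mRNA are positively co-expressed (Pearson above ``pcc_min``,
   default 0.9),
3. the number of miRNAs they share is larger than expected by chance,
   assessed with a hypergeometric upper-tail test over the miRNA universe
   (p below ``alpha``, default 0.05, uncorrected).

Only differentially expressed features are considered, and correlations are
computed on the normalized abundance layer across all samples of both
groups pooled: with three replicates per group, within-group correlation
carries no information, while cross-stage co-variation is exactly what the
ceRNA hypothesis predicts.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from scipy.stats import rankdata

from .containers import ExpressionMatrix
from .stats import hypergeom_tail

logger = logging.getLogger(__name__)

SPONGE_CLASSES = ("lncRNA", "circRNA")

#: SIF relation names per edge type
_RELATIONS = {"cerna_pair": "sponges", "miRNA_target": "targets", "coexpression": "coexpressed"}


# ---------------------------------------------------------------------------
# target map


@dataclass(frozen=True)
class TargetMap:
    """miRNA -> candidate target relations (mRNA, lncRNA or circRNA).

    Stands in for database-predicted miRNA target / sponge relations.
    ``universe_size`` (U) is the number of distinct miRNAs in the map.
    """

    targets_by_mirna: Mapping[str, frozenset[str]]

    def __post_init__(self) -> None:
        for mirna, targets in self.targets_by_mirna.items():
            if mirna in targets:
                raise ValueError(f"self-target for {mirna}")
            if any(t in self.targets_by_mirna for t in targets):
                bad = sorted(t for t in targets if t in self.targets_by_mirna)
                raise ValueError(f"miRNAs appear as targets: {bad[:5]}")
        if not self.targets_by_mirna:
            raise ValueError("target map must contain at least one miRNA")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "TargetMap":
        by_mirna: dict[str, set[str]] = {}
        for mirna, target in pairs:
            by_mirna.setdefault(mirna, set()).add(target)
        return cls({m: frozenset(t) for m, t in by_mirna.items()})

    @property
    def universe_size(self) -> int:
        return len(self.targets_by_mirna)

    @property
    def mirnas(self) -> list[str]:
        return sorted(self.targets_by_mirna)

    def targets_of(self, mirna: str) -> frozenset[str]:
        return self.targets_by_mirna.get(mirna, frozenset())

    def __contains__(self, pair: tuple[str, str]) -> bool:
        mirna, target = pair
        return target in self.targets_by_mirna.get(mirna, frozenset())

    def pairs(self) -> list[tuple[str, str]]:
        """All (miRNA, target) relations in deterministic order."""
        return [
            (m, t)
            for m in sorted(self.targets_by_mirna)
            for t in sorted(self.targets_by_mirna[m])
        ]

    @property
    def n_relations(self) -> int:
        return sum(len(t) for t in self.targets_by_mirna.values())


# ---------------------------------------------------------------------------
# correlation primitives


def pearson_cc(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation; NaN when either vector is constant.

    Callers must skip NaN pairs (a constant vector has no defined
    correlation); the selection functions below count such skips.
    """
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.all(np.isfinite(xv)) and np.all(np.isfinite(yv))):
        raise ValueError("correlation inputs must be finite")
    xc = xv - xv.mean()
    yc = yv - yv.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0.0:
        return float("nan")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def spearman_cc(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation: Pearson on mid-ranks (ties averaged)."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D vectors of equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 paired observations")
    return pearson_cc(rankdata(xv), rankdata(yv))


@dataclass(frozen=True)
class CorrelationPair:
    """A retained correlation edge candidate (a, b) with its coefficient."""

    a: str
    b: str
    kind: str  # "SCC" | "PCC"
    coefficient: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.a == self.b:
            raise ValueError("self-correlation pair")
        if not abs(self.coefficient) <= 1.0:
            raise ValueError("|coefficient| must be <= 1")
        if self.n_samples < 3:
            raise ValueError("n_samples must be >= 3")


@dataclass(frozen=True)
class SpongeTestResult:
    """Shared-miRNA hypergeometric test record for one sponge-target pair.

    ``x`` shared miRNAs out of ``M`` (gene_a) and ``N`` (gene_b) regulators
    within a universe of ``U`` miRNAs; ``pvalue`` = P(shared >= x).
    """

    gene_a: str
    gene_b: str
    x: int
    M: int
    N: int
    U: int
    pvalue: float

    def __post_init__(self) -> None:
        if not (0 <= self.x <= min(self.M, self.N) and max(self.M, self.N) <= self.U):
            raise ValueError("require x <= min(M, N) and M, N <= U")
        if not 0.0 <= self.pvalue <= 1.0:
            raise ValueError("p-value out of [0, 1]")


def sponge_test(x: int, M: int, N: int, U: int) -> float:
    """P that two genes share >= x miRNA regulators by chance.

    Hypergeometric upper tail: gene_a is linked to M of the U miRNAs,
    gene_b to N; under random assignment the overlap is
    Hypergeometric(U, M, N) and p = P(overlap >= x).
    """
    return hypergeom_tail(x, U, M, N)


# ---------------------------------------------------------------------------
# pair selection


def _check_sample_alignment(expr: Mapping[str, ExpressionMatrix]) -> int:
    orders = {tuple(em.sample_ids) for em in expr.values() if em.n_features}
    if len(orders) > 1:
        raise ValueError("expression matrices disagree on sample order")
    return len(next(iter(orders))) if orders else 0


def select_mirna_pairs(
    expr: Mapping[str, ExpressionMatrix],
    target_map: TargetMap,
    de_sets: Mapping[str, set[str]],
    scc_max: float = -0.7,
) -> list[CorrelationPair]:
    """Anti-correlation filter: miRNA-target pairs from the map, both DE, SCC < scc_max.

    ``expr`` maps RNA class to its normalized matrix; all matrices must
    share one sample ordering. The comparison is strict, so a pair sitting
    exactly at the threshold is rejected.
    """
    n_samples = _check_sample_alignment(expr)
    mirna_expr = expr.get("miRNA")
    if mirna_expr is None:
        raise ValueError("miRNA expression matrix required")
    de_mirna = de_sets.get("miRNA", set())
    class_of: dict[str, str] = {}
    for cls, em in expr.items():
        for fid in em.feature_ids:
            class_of[fid] = cls

    retained: list[CorrelationPair] = []
    n_skipped = 0
    for mirna, target in target_map.pairs():
        if mirna not in de_mirna or mirna not in mirna_expr.data.index:
            continue
        cls = class_of.get(target)
        if cls is None or target not in de_sets.get(cls, set()):
            continue
        scc = spearman_cc(mirna_expr.vector(mirna), expr[cls].vector(target))
        if np.isnan(scc):
            n_skipped += 1
            continue
        if scc < scc_max:
            retained.append(CorrelationPair(mirna, target, "SCC", scc, n_samples))
    if n_skipped:
        logger.info("select_mirna_pairs: skipped %d zero-variance pairs", n_skipped)
    return retained


def select_coexpr_pairs(
    expr: Mapping[str, ExpressionMatrix],
    de_sets: Mapping[str, set[str]],
    pcc_min: float = 0.9,
) -> list[CorrelationPair]:
    """Co-expression filter: DE lncRNA-mRNA and circRNA-mRNA pairs with PCC > pcc_min."""
    n_samples = _check_sample_alignment(expr)
    mrna_expr = expr.get("mRNA")
    if mrna_expr is None:
        raise ValueError("mRNA expression matrix required")
    de_mrna = sorted(de_sets.get("mRNA", set()) & set(mrna_expr.data.index))

    retained: list[CorrelationPair] = []
    n_skipped = 0
    for sponge_class in SPONGE_CLASSES:
        em = expr.get(sponge_class)
        if em is None:
            continue
        de_sponges = sorted(de_sets.get(sponge_class, set()) & set(em.data.index))
        for sponge in de_sponges:
            sv = em.vector(sponge)
            for target in de_mrna:
                pcc = pearson_cc(sv, mrna_expr.vector(target))
                if np.isnan(pcc):
                    n_skipped += 1
                    continue
                if pcc > pcc_min:
                    retained.append(CorrelationPair(sponge, target, "PCC", pcc, n_samples))
    if n_skipped:
        logger.info("select_coexpr_pairs: skipped %d zero-variance pairs", n_skipped)
    return retained


# ---------------------------------------------------------------------------
# network assembly


@dataclass
class CeRNANetwork:
    """Typed ceRNA network: nodes carry an RNA class, edges a type.

    Edge types: ``cerna_pair`` (validated sponge-target pair, with the
    Pearson coefficient and the sponge-test p-value) and ``miRNA_target``
    (a supporting miRNA to one member, with the Spearman coefficient).
    """

    graph: nx.Graph = field(default_factory=nx.Graph)
    sponge_tests: list[SpongeTestResult] = field(default_factory=list)

    def add_node(self, node_id: str, rna_class: str) -> None:
        self.graph.add_node(node_id, rna_class=rna_class)

    def add_edge(self, a: str, b: str, edge_type: str, coefficient: float,
                 pvalue: float | None = None) -> None:
        if a == b:
            raise ValueError("self-loop")
        if a not in self.graph or b not in self.graph:
            raise ValueError("edge endpoints must be added as nodes first")
        cls_a = self.graph.nodes[a]["rna_class"]
        cls_b = self.graph.nodes[b]["rna_class"]
        if edge_type == "miRNA_target":
            if (cls_a == "miRNA") == (cls_b == "miRNA"):
                raise ValueError("miRNA_target edges connect a miRNA to a non-miRNA")
        elif edge_type in ("cerna_pair", "coexpression"):
            if "miRNA" in (cls_a, cls_b):
                raise ValueError(f"{edge_type} edges connect two non-miRNAs")
        else:
            raise ValueError(f"unknown edge type {edge_type!r}")
        self.graph.add_edge(a, b, a=a, b=b, edge_type=edge_type,
                            coefficient=coefficient, pvalue=pvalue)

    # -- reporting -------------------------------------------------------

    def node_counts(self) -> dict[str, int]:
        counts = {cls: 0 for cls in ("mRNA", "lncRNA", "circRNA", "miRNA")}
        for _, data in self.graph.nodes(data=True):
            counts[data["rna_class"]] += 1
        return counts

    def pair_counts(self) -> dict[str, int]:
        counts = {
            "circRNA-miRNA": 0,
            "lncRNA-miRNA": 0,
            "miRNA-mRNA": 0,
            "cerna_pair": 0,
        }
        for _, _, data in self.graph.edges(data=True):
            if data["edge_type"] == "cerna_pair":
                counts["cerna_pair"] += 1
                continue
            if data["edge_type"] != "miRNA_target":
                continue
            partner = data["b"] if self.graph.nodes[data["a"]]["rna_class"] == "miRNA" else data["a"]
            cls = self.graph.nodes[partner]["rna_class"]
            if cls == "mRNA":
                counts["miRNA-mRNA"] += 1
            elif cls == "circRNA":
                counts["circRNA-miRNA"] += 1
            elif cls == "lncRNA":
                counts["lncRNA-miRNA"] += 1
        return counts

    def degree_of(self, node_id: str) -> int:
        return self.graph.degree[node_id]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def build_cerna_network(
    mirna_pairs: Sequence[CorrelationPair],
    coexpr_pairs: Sequence[CorrelationPair],
    target_map: TargetMap,
    alpha: float = 0.05,
    universe_size: int | None = None,
    class_of: Mapping[str, str] | None = None,
) -> CeRNANetwork:
    """Sponge-test filter + assembly: sponge-test each co-expressed pair.

    A co-expressed sponge-target pair becomes a ``cerna_pair`` edge iff its
    shared-miRNA hypergeometric p < ``alpha`` (strict), where the shared
    miRNAs are restricted to those passing the anti-correlation filter for
    BOTH members. Each shared miRNA then contributes ``miRNA_target`` edges
    to both members.

    ``universe_size`` (U) defaults to the number of distinct miRNAs in the
    target map; pass the DE-filtered count to restrict the universe.
    ``class_of`` maps feature id -> RNA class for node typing; when absent,
    miRNAs are identified from the target map and all sponges default to
    their id prefix-free "circRNA"/"lncRNA" cannot be inferred, so
    ``class_of`` is required whenever there are edges to type.
    """
    U = target_map.universe_size if universe_size is None else int(universe_size)
    if U < 1:
        raise ValueError("miRNA universe must contain at least one miRNA")

    linked: dict[str, set[str]] = {}
    scc_of: dict[tuple[str, str], float] = {}
    for pair in mirna_pairs:
        linked.setdefault(pair.b, set()).add(pair.a)
        scc_of[(pair.a, pair.b)] = pair.coefficient

    network = CeRNANetwork()

    def cls(fid: str) -> str:
        if class_of is not None and fid in class_of:
            return class_of[fid]
        raise ValueError(f"cannot determine RNA class of {fid!r}; pass class_of")

    for pair in coexpr_pairs:
        sponge, target = pair.a, pair.b
        m_sponge = linked.get(sponge, set())
        m_target = linked.get(target, set())
        shared = sorted(m_sponge & m_target)
        M, N, x = len(m_sponge), len(m_target), len(shared)
        if max(M, N) > U:
            raise ValueError(
                f"linked miRNA count ({max(M, N)}) exceeds universe U={U}"
            )
        p = sponge_test(x, M, N, U)
        network.sponge_tests.append(SpongeTestResult(sponge, target, x, M, N, U, p))
        if p < alpha:
            network.add_node(sponge, cls(sponge))
            network.add_node(target, cls(target))
            network.add_edge(sponge, target, "cerna_pair", pair.coefficient, p)
            for mirna in shared:
                network.add_node(mirna, "miRNA")
                for member in (sponge, target):
                    if not network.graph.has_edge(mirna, member):
                        network.add_edge(mirna, member, "miRNA_target",
                                         scc_of[(mirna, member)])
    return network


# ---------------------------------------------------------------------------
# export


def export_network(network: CeRNANetwork, outdir) -> dict[str, Path]:
    """Write SIF + node/edge attribute tables with deterministic row order.

    Files: ``network.sif`` (a <TAB> relation <TAB> b), ``nodes.tsv``
    (id, rna_class, degree), ``edges.tsv`` (a, relation, b, coefficient,
    pvalue). Rows are sorted lexicographically, so a fixed network exports
    byte-identically.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for _, _, data in network.graph.edges(data=True):
        rows.append((data["a"], _RELATIONS[data["edge_type"]], data["b"],
                     data["coefficient"], data["pvalue"]))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))

    sif_path = outdir / "network.sif"
    with open(sif_path, "w", encoding="utf-8") as fh:
        for a, rel, b, _, _ in rows:
            fh.write(f"{a}\t{rel}\t{b}\n")

    nodes_path = outdir / "nodes.tsv"
    with open(nodes_path, "w", encoding="utf-8") as fh:
        fh.write("id\trna_class\tdegree\n")
        for node in sorted(network.graph.nodes):
            fh.write(f"{node}\t{network.graph.nodes[node]['rna_class']}\t"
                     f"{network.graph.degree[node]}\n")

    edges_path = outdir / "edges.tsv"
    with open(edges_path, "w", encoding="utf-8") as fh:
        fh.write("a\trelation\tb\tcoefficient\tpvalue\n")
        for a, rel, b, coef, p in rows:
            p_str = "" if p is None else f"{p:.10g}"
            fh.write(f"{a}\t{rel}\t{b}\t{coef:.10g}\t{p_str}\n")

    return {"sif": sif_path, "nodes": nodes_path, "edges": edges_path}
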