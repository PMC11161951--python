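"""Synthetic whole-transcriptome bundles with planted ceRNA structure.

Emulates a two-stage (e.g. embryonic day 65 vs 85), three-replicate design
over four RNA classes: negative-binomial counts, planted differential
expression, and planted ceRNA triplets in which a sponge (circRNA or
lncRNA), a miRNA and an mRNA target share a per-sample log-normal latent
factor — positively loaded on sponge and target, negatively on the miRNA —
so that the rank/moment correlations the downstream filters assume are
actually present in the data. A truth table records everything planted so
recovery can be scored.

Decoy triplets are random (sponge, miRNA, target) triplets whose two
miRNA->gene relations are guaranteed into the target map but whose members
carry no planted effect at all; they probe the false-positive path of the
network construction.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, FeatureAnnotation, LENGTH_RANGES, RNA_CLASSES
from .cerna import TargetMap

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "generate_annotation",
    "generate_counts",
    "generate_target_map",
    "generate_term_map",
    "generate_bundle",
]

# fixed substream indices: adding a later stream never perturbs earlier draws
_STREAMS = {
    "annotation": 0,
    "plan": 1,
    "latent": 2,
    "counts:mRNA": 3,
    "counts:lncRNA": 4,
    "counts:circRNA": 5,
    "counts:miRNA": 6,
    "targets": 7,
    "terms": 8,
    "decoys": 9,
}

_ID_PREFIX = {"mRNA": "G", "lncRNA": "LNC", "circRNA": "CIRC", "miRNA": "MIR"}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design and noise parameters of the synthetic bundle.

    Defaults describe the two-timepoint, three-replicate design the
    pipeline targets: ~3,350 features across four classes, NB counts with
    variance mu + phi*mu^2 (phi = 0.1), 50 ceRNA triplets planted with a
    latent-factor loading of 0.9, and planted effects of |log2FC| = 6
    split symmetrically across the two stages. Effect sizes are chosen so
    the planted structure is detectable through every downstream filter at
    three replicates per group (see the methods note), not for realism of
    any single parameter.
    """

    n_mrna: int = 2000
    n_lncrna: int = 400
    n_circrna: int = 800
    n_mirna: int = 150
    n_replicates: int = 3
    baseline_mean: float = 200.0
    dispersion: float = 0.1
    n_de_per_class: int = 100
    de_log2fc: float = 6.0
    n_triplets: int = 50
    n_decoy_triplets: int = 500
    triplet_correlation_strength: float = 0.9
    latent_sd: float = 1.0
    intergenic_fraction: float = 0.10
    target_density: float = 0.01
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 100)
    group_names: tuple[str, str] = ("E65", "E85")
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_circrna", "n_mirna", "n_de_per_class",
                     "n_triplets", "n_decoy_triplets", "n_terms"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        if not 0.0 <= self.triplet_correlation_strength <= 1.0:
            raise ValueError("triplet_correlation_strength must lie in [0, 1]")
        if self.latent_sd < 0:
            raise ValueError("latent_sd must be >= 0")
        if not 0.0 <= self.intergenic_fraction <= 1.0:
            raise ValueError("intergenic_fraction must lie in [0, 1]")
        if not 0.0 <= self.target_density <= 1.0:
            raise ValueError("target_density must lie in [0, 1]")
        if self.baseline_mean <= 0:
            raise ValueError("baseline_mean must be > 0")
        if self.term_size_range[0] < 1 or self.term_size_range[0] > self.term_size_range[1]:
            raise ValueError("term sizes must be >= 1 with min <= max")

    @property
    def class_sizes(self) -> dict[str, int]:
        return {"mRNA": self.n_mrna, "lncRNA": self.n_lncrna,
                "circRNA": self.n_circrna, "miRNA": self.n_mirna}

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_{r + 1}" for g in self.group_names for r in range(self.n_replicates)]


@dataclass
class TruthTable:
    """What was planted: DE features with true effects, triplets, decoys."""

    de_features: dict[str, float]  # feature id -> true log2FC
    planted_triplets: list[tuple[str, str, str]]  # (sponge, miRNA, target)
    decoy_triplets: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.planted_triplets) & set(self.decoy_triplets):
            raise ValueError("planted and decoy triplets must be disjoint")

    @property
    def planted_pairs(self) -> set[tuple[str, str]]:
        """(sponge, target) pairs of the planted triplets."""
        return {(s, t) for s, _, t in self.planted_triplets}

    @property
    def decoy_pairs(self) -> set[tuple[str, str]]:
        return {(s, t) for s, _, t in self.decoy_triplets}


# ---------------------------------------------------------------------------
# annotation


def generate_annotation(config: SimulationConfig) -> FeatureAnnotation:
    """Feature ids, classes, lengths, circRNA host genes, lncRNA cis-genes.

    Lengths are uniform over the class length range; a configurable
    fraction of circRNAs is intergenic (no host gene). Host and cis genes
    are drawn from the simulated mRNA ids.
    """
    rng = _rng(config.seed, "annotation")
    records = []
    ids_by_class = {
        cls: [f"{_ID_PREFIX[cls]}{i + 1:05d}" for i in range(n)]
        for cls, n in config.class_sizes.items()
    }
    mrna_ids = ids_by_class["mRNA"]
    for cls in RNA_CLASSES:
        lo, hi = LENGTH_RANGES[cls]
        for fid in ids_by_class[cls]:
            length = int(rng.integers(lo, hi + 1))
            host = cis = None
            if cls == "circRNA" and mrna_ids:
                if rng.random() >= config.intergenic_fraction:
                    host = mrna_ids[int(rng.integers(len(mrna_ids)))]
            elif cls == "lncRNA" and mrna_ids:
                cis = mrna_ids[int(rng.integers(len(mrna_ids)))]
            records.append((fid, cls, length, host, cis))
    table = pd.DataFrame(
        records, columns=["feature_id", "rna_class", "length", "host_gene", "cis_gene"]
    ).set_index("feature_id")
    return FeatureAnnotation(table)


# ---------------------------------------------------------------------------
# counts + truth


def _plan_structure(annotation: FeatureAnnotation, config: SimulationConfig):
    """Choose planted triplets, per-class DE sets and decoy triplets."""
    rng = _rng(config.seed, "plan")
    by_class = {cls: annotation.features_of_class(cls) for cls in RNA_CLASSES}

    n_trip = config.n_triplets
    n_circ_sponges = math.ceil(n_trip / 2) if by_class["circRNA"] else 0
    n_lnc_sponges = n_trip - n_circ_sponges
    if n_circ_sponges > len(by_class["circRNA"]) or n_lnc_sponges > len(by_class["lncRNA"]):
        raise ValueError("not enough circRNA/lncRNA features for the requested triplets")
    if n_trip > len(by_class["mRNA"]) or n_trip > len(by_class["miRNA"]):
        raise ValueError("not enough mRNA/miRNA features for the requested triplets")

    circ_sponges = list(rng.choice(by_class["circRNA"], n_circ_sponges, replace=False)) if n_circ_sponges else []
    lnc_sponges = list(rng.choice(by_class["lncRNA"], n_lnc_sponges, replace=False)) if n_lnc_sponges else []
    sponges = []
    for i in range(n_trip):  # interleave so both sponge classes participate
        pool = circ_sponges if (i % 2 == 0 and circ_sponges) else lnc_sponges
        if not pool:
            pool = circ_sponges or lnc_sponges
        sponges.append(pool.pop())
    targets = list(rng.choice(by_class["mRNA"], n_trip, replace=False)) if n_trip else []
    mirnas = list(rng.choice(by_class["miRNA"], n_trip, replace=False)) if n_trip else []
    triplets = list(zip(sponges, mirnas, targets))

    # planted DE: triplet members first (sponge/target up, miRNA down),
    # then extras whose signs balance the up/down counts per class so that
    # the planted effects leave the per-class library totals unshifted
    de: dict[str, float] = {}
    for sponge, mirna, target in triplets:
        de[sponge] = config.de_log2fc
        de[target] = config.de_log2fc
        de[mirna] = -config.de_log2fc
    for cls in RNA_CLASSES:
        if not by_class[cls]:
            continue
        members = [f for f in by_class[cls] if f in de]
        if config.n_de_per_class > len(by_class[cls]):
            raise ValueError(
                f"n_de_per_class={config.n_de_per_class} exceeds {cls} class size"
            )
        n_extra = max(0, config.n_de_per_class - len(members))
        pool = [f for f in by_class[cls] if f not in de]
        extras = list(rng.choice(pool, n_extra, replace=False)) if n_extra else []
        n_up = sum(1 for f in members if de[f] > 0)
        n_down = len(members) - n_up
        total = len(members) + n_extra
        want_up = total // 2 + (1 if total % 2 and rng.random() < 0.5 else 0)
        extra_up = int(np.clip(want_up - n_up, 0, n_extra))
        for j, fid in enumerate(extras):
            sign = 1.0 if j < extra_up else -1.0
            de[fid] = sign * config.de_log2fc

    # decoys: members disjoint from every planted-DE feature
    rng_decoy = _rng(config.seed, "decoys")
    decoy_sponge_pool = [f for f in by_class["circRNA"] + by_class["lncRNA"] if f not in de]
    decoy_target_pool = [f for f in by_class["mRNA"] if f not in de]
    decoy_mirna_pool = [f for f in by_class["miRNA"] if f not in de]
    decoys: list[tuple[str, str, str]] = []
    seen_pairs: set[tuple[str, str]] = set()
    if config.n_decoy_triplets:
        if not (decoy_sponge_pool and decoy_target_pool and decoy_mirna_pool):
            raise ValueError("no null features left to form decoy triplets")
        max_pairs = len(decoy_sponge_pool) * len(decoy_target_pool)
        if config.n_decoy_triplets > max_pairs:
            raise ValueError("n_decoy_triplets exceeds the number of available null pairs")
        while len(decoys) < config.n_decoy_triplets:
            s = decoy_sponge_pool[int(rng_decoy.integers(len(decoy_sponge_pool)))]
            t = decoy_target_pool[int(rng_decoy.integers(len(decoy_target_pool)))]
            if (s, t) in seen_pairs:
                continue
            m = decoy_mirna_pool[int(rng_decoy.integers(len(decoy_mirna_pool)))]
            seen_pairs.add((s, t))
            decoys.append((s, m, t))
    return triplets, de, decoys


def generate_counts(
    annotation: FeatureAnnotation, config: SimulationConfig
) -> tuple[dict[str, ExpressionMatrix], TruthTable]:
    """NB count matrices per class plus the truth table.

    Counts follow NB(mu, phi) with variance mu + phi*mu^2 (Poisson when
    phi = 0). Group-2 means of planted-DE features are multiplied by
    2**log2fc. Each planted triplet shares a per-replicate latent factor:
    a standard-normal draw per replicate slot, standardized to zero mean
    and ``latent_sd`` within the group and repeated across both groups
    (sample-level covariation of the module, orthogonal to the stage
    effect). The NB mean is multiplied by exp(+s*z) for sponge and target
    and exp(-s*z) for the miRNA — s is the correlation strength — each
    rescaled to unit mean so the planted group-mean ratio is preserved
    exactly.
    """
    if annotation.n_features == 0:
        raise ValueError("annotation is empty")
    triplets, de, decoys = _plan_structure(annotation, config)
    truth = TruthTable(de_features=de, planted_triplets=triplets, decoy_triplets=decoys)

    n_rep = config.n_replicates
    n_samples = 2 * n_rep
    samples = config.sample_ids
    s = config.triplet_correlation_strength

    # latent factors, one standardized per-replicate vector per triplet,
    # repeated across the two groups (paired: cancels in the group means)
    rng_latent = _rng(config.seed, "latent")
    latent = {}
    for sponge, mirna, target in triplets:
        h = rng_latent.standard_normal(n_rep)
        spread = h.std()
        if spread == 0.0:
            spread = 1.0
        h = (h - h.mean()) / spread * config.latent_sd
        z = np.tile(h, 2)
        mult_pos = np.exp(s * z)
        mult_pos /= mult_pos.mean()
        mult_neg = np.exp(-s * z)
        mult_neg /= mult_neg.mean()
        latent[sponge] = mult_pos
        latent[target] = mult_pos
        latent[mirna] = mult_neg

    matrices: dict[str, ExpressionMatrix] = {}
    for cls in RNA_CLASSES:
        ids = annotation.features_of_class(cls)
        rng = _rng(config.seed, f"counts:{cls}")
        if not ids:
            matrices[cls] = ExpressionMatrix(
                pd.DataFrame(np.zeros((0, n_samples)), columns=samples), cls, "count"
            )
            continue
        mu = np.full((len(ids), n_samples), config.baseline_mean)
        for i, fid in enumerate(ids):
            if fid in de:
                # symmetric split: group means mu*2^(-lfc/2) and mu*2^(+lfc/2)
                # keep the log2 ratio at lfc without shifting the library total
                mu[i, :n_rep] *= 2.0 ** (-0.5 * de[fid])
                mu[i, n_rep:] *= 2.0 ** (0.5 * de[fid])
            if fid in latent:
                mu[i, :] *= latent[fid]
        if config.dispersion > 0:
            r = 1.0 / config.dispersion
            counts = rng.negative_binomial(r, r / (r + mu))
        else:
            counts = rng.poisson(mu)
        matrices[cls] = ExpressionMatrix(
            pd.DataFrame(counts, index=ids, columns=samples), cls, "count"
        )
    return matrices, truth


# ---------------------------------------------------------------------------
# target map


def generate_target_map(
    annotation: FeatureAnnotation, truth: TruthTable, config: SimulationConfig
) -> TargetMap:
    """Planted + decoy relations, plus Bernoulli background relations.

    Every planted triplet contributes its (miRNA -> sponge) and
    (miRNA -> target) relations; decoy triplets likewise. Background
    relations are added independently at ``config.target_density`` over
    all miRNA x non-miRNA combinations. miRNAs never appear as targets.
    """
    mirnas = annotation.features_of_class("miRNA")
    if not mirnas:
        raise ValueError("cannot build a target map without miRNAs")
    candidates = [f for cls in ("mRNA", "lncRNA", "circRNA")
                  for f in annotation.features_of_class(cls)]
    pairs: set[tuple[str, str]] = set()
    for sponge, mirna, target in truth.planted_triplets + truth.decoy_triplets:
        pairs.add((mirna, sponge))
        pairs.add((mirna, target))
    if config.target_density > 0 and candidates:
        rng = _rng(config.seed, "targets")
        hits = rng.random((len(mirnas), len(candidates))) < config.target_density
        for i, j in zip(*np.nonzero(hits)):
            pairs.add((mirnas[i], candidates[j]))
    # guarantee every miRNA appears so the universe size is well-defined
    by_mirna: dict[str, set[str]] = {m: set() for m in mirnas}
    for m, t in pairs:
        by_mirna[m].add(t)
    return TargetMap({m: frozenset(t) for m, t in by_mirna.items() if t} or
                     {mirnas[0]: frozenset()})


# ---------------------------------------------------------------------------
# term map


def generate_term_map(
    annotation: FeatureAnnotation,
    config: SimulationConfig,
    truth: TruthTable | None = None,
) -> dict[str, tuple[str, list[str]]]:
    """Random gene-set (GMT-style) terms over the mRNA universe.

    Returns term id -> (description, member genes). When a truth table is
    supplied, one extra term ``TERM_SEEDED`` containing exactly the planted
    DE mRNAs is added so downstream enrichment has a detectable signal.
    """
    genes = annotation.features_of_class("mRNA")
    lo, hi = config.term_size_range
    if lo < 1:
        raise ValueError("term size must be >= 1")
    if hi > len(genes):
        raise ValueError("term size range exceeds the mRNA universe")
    rng = _rng(config.seed, "terms")
    terms: dict[str, tuple[str, list[str]]] = {}
    for k in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = sorted(rng.choice(genes, size, replace=False).tolist())
        terms[f"TERM{k + 1:04d}"] = (f"synthetic term {k + 1}", members)
    if truth is not None:
        de_mrna = sorted(f for f in truth.de_features if f in set(genes))
        if de_mrna:
            terms["TERM_SEEDED"] = ("planted DE gene set", de_mrna)
    return terms


# ---------------------------------------------------------------------------
# one-call bundle


def generate_bundle(config: SimulationConfig):
    """Generate annotation, counts, truth, target map and term map at once."""
    annotation = generate_annotation(config)
    counts, truth = generate_counts(annotation, config)
    target_map = generate_target_map(annotation, truth, config)
    terms = generate_term_map(annotation, config, truth)
    return {
        "annotation": annotation,
        "counts": counts,
        "truth": truth,
        "target_map": target_map,
        "terms": terms,
        "config": config,
    }
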