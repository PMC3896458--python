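"""Synthetic microarray study generator with known planted truth.

Emulates a small two-group (5 case vs 5 control) expression study under the
random-variance-model assumption: gene precisions 1/sigma^2 ~ Gamma(a, b),
log2 intensities Normal around a per-gene baseline, a chosen subset of genes
shifted by +/- log2_effect in the case group (signs split evenly), gene sets
of which some are enriched in the planted DE genes, and a directed
relation-typed interaction network in which designated hub genes attract a
fixed multiple of the baseline attachment probability.

Everything is driven by one integer seed; identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import InvalidConfigError
from .expression import ExpressionMatrix
from .enrichment import GeneSetCollection
from .networks import RELATION_CODES, UNDIRECTED_RELATIONS, InteractionEdgeList

BASELINE_MEAN = 7.0     # log2 units, centre of microarray dynamic range
BASELINE_SD = 1.5
PLANT_FRACTION = 0.6    # fraction of a planted term's members drawn from DE genes


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic generator.

    ``prior_shape_a``/``prior_scale_b`` parameterize the Gamma prior on gene
    precisions (the RVM assumption); ``log2_effect`` is the mean log2 shift
    of each planted DE gene (sign alternating up/down); ``hub_multiplier``
    scales a hub gene's attachment probability in the interaction network.
    """

    n_genes: int = 2000
    n_case: int = 5
    n_control: int = 5
    prior_shape_a: float = 2.0
    prior_scale_b: float = 1.0
    n_de: int = 100
    log2_effect: float = 2.0
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 40)
    n_planted_terms: int = 10
    n_edges: int = 600
    hub_genes: tuple[str, ...] = ()
    hub_multiplier: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "n_genes": self.n_genes, "n_case": self.n_case, "n_control": self.n_control,
            "prior_shape_a": self.prior_shape_a, "prior_scale_b": self.prior_scale_b,
            "hub_multiplier": self.hub_multiplier,
        }
        for name, value in positive.items():
            if value <= 0:
                raise InvalidConfigError(f"{name} must be positive, got {value}")
        for name, value in {"n_de": self.n_de, "n_terms": self.n_terms,
                            "n_planted_terms": self.n_planted_terms, "n_edges": self.n_edges}.items():
            if value < 0:
                raise InvalidConfigError(f"{name} must be non-negative, got {value}")
        if self.n_de > self.n_genes:
            raise InvalidConfigError(f"n_de={self.n_de} exceeds n_genes={self.n_genes}")
        if self.n_planted_terms > self.n_terms:
            raise InvalidConfigError("n_planted_terms exceeds n_terms")
        lo, hi = self.term_size_range
        if not (0 < lo <= hi):
            raise InvalidConfigError(f"bad term_size_range {self.term_size_range}")
        if hi > self.n_genes:
            raise InvalidConfigError("term_size_range max exceeds n_genes")
        if self.log2_effect < 0:
            raise InvalidConfigError("log2_effect must be non-negative")


@dataclass
class SimTruth:
    """Planted ground truth: DE genes (with shift sign), enriched terms
    (with direction), hub genes."""

    de_signs: dict[str, int] = field(default_factory=dict)
    enriched_term_directions: dict[str, str] = field(default_factory=dict)
    hub_genes: set[str] = field(default_factory=set)

    @property
    def de_genes(self) -> set[str]:
        return set(self.de_signs)

    @property
    def enriched_terms(self) -> set[str]:
        return set(self.enriched_term_directions)

    def de_by_direction(self, direction: str) -> set[str]:
        sign = 1 if direction == "up" else -1
        return {g for g, s in self.de_signs.items() if s == sign}


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i + 1:0{width}d}" for i in range(n)]


def simulate_expression(config: SimConfig) -> tuple[ExpressionMatrix, SimTruth]:
    """Draw a linear-scale expression matrix under the RVM assumption.

    Per gene: precision ~ Gamma(prior_shape_a, scale=prior_scale_b), baseline
    log2 level ~ Normal(7, 1.5^2), samples Normal(baseline, sigma^2); planted
    DE genes additionally shift the case group by +/- log2_effect (half up,
    half down). Returned intensities are 2**log2 (all positive).
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_ids(config.n_genes)
    samples = [f"case_{i + 1}" for i in range(config.n_case)] + \
              [f"control_{i + 1}" for i in range(config.n_control)]
    design = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control, index=samples
    )

    precisions = rng.gamma(shape=config.prior_shape_a, scale=config.prior_scale_b,
                           size=config.n_genes)
    sigma = 1.0 / np.sqrt(precisions)
    baseline = rng.normal(BASELINE_MEAN, BASELINE_SD, size=config.n_genes)
    log2x = baseline[:, None] + rng.normal(size=(config.n_genes, len(samples))) * sigma[:, None]

    de_idx = rng.choice(config.n_genes, size=config.n_de, replace=False)
    signs = np.ones(config.n_de, dtype=int)
    signs[config.n_de // 2:] = -1  # even up/down split
    log2x[de_idx, : config.n_case] += signs[:, None] * config.log2_effect

    matrix = ExpressionMatrix(
        intensities=pd.DataFrame(2.0 ** log2x, index=genes, columns=samples),
        design=design,
    )
    truth = SimTruth(de_signs={genes[i]: int(s) for i, s in zip(de_idx, signs)})
    return matrix, truth


def simulate_annotation(genes, config: SimConfig,
                        de_truth: SimTruth | None = None) -> tuple[GeneSetCollection, SimTruth]:
    """Generate gene sets, planting n_planted_terms enriched in the DE genes.

    Planted terms draw 60% of their members from one direction of
    ``de_truth`` (alternating up/down across planted terms) and the rest from
    non-DE genes; remaining terms sample uniformly. Categories alternate
    GO / pathway. Without ``de_truth`` (or with n_planted_terms = 0) nothing
    is planted.
    """
    genes = list(genes)
    if not genes:
        raise InvalidConfigError("gene list is empty")
    lo, hi = config.term_size_range
    if hi > len(genes):
        raise InvalidConfigError("term_size_range max exceeds the gene universe")
    rng = np.random.default_rng(config.seed + 1)
    truth = de_truth if de_truth is not None else SimTruth()
    n_planted = config.n_planted_terms if truth.de_signs else 0

    gene_arr = np.array(genes)
    non_de = np.array(sorted(set(genes) - truth.de_genes))
    terms: dict[str, tuple[str, str, frozenset[str]]] = {}
    width = max(3, len(str(config.n_terms)))
    for i in range(config.n_terms):
        tid = f"T{i + 1:0{width}d}"
        category = "GO" if i % 2 == 0 else "pathway"
        size = int(rng.integers(lo, hi + 1))
        if i < n_planted:
            direction = "up" if i % 2 == 0 else "down"
            pool = np.array(sorted(truth.de_by_direction(direction)))
            k = min(int(np.ceil(PLANT_FRACTION * size)), len(pool))
            members = set(rng.choice(pool, size=k, replace=False))
            filler = non_de if len(non_de) >= size - k else gene_arr
            remaining = np.array(sorted(set(filler) - members))
            members |= set(rng.choice(remaining, size=size - k, replace=False))
            truth.enriched_term_directions[tid] = direction
        else:
            members = set(rng.choice(gene_arr, size=size, replace=False))
        terms[tid] = (f"synthetic term {tid}", category, frozenset(members))
    return GeneSetCollection(terms=terms, universe=frozenset(genes)), truth


def simulate_interaction_network(genes, config: SimConfig) -> InteractionEdgeList:
    """Directed relation-typed edges with hub-biased endpoint sampling.

    Each endpoint is drawn with probability proportional to 1, or
    ``hub_multiplier`` for hub genes; relation codes are uniform over the
    eight KEGG-style legend codes; binding ('b') edges are undirected.
    Self-loops are rejected and duplicate (source, target, relation)
    triples resampled.
    """
    genes = list(genes)
    unknown = set(config.hub_genes) - set(genes)
    if unknown:
        raise InvalidConfigError(f"hub genes outside the universe: {sorted(unknown)}")
    if config.n_edges and len(genes) < 2:
        raise InvalidConfigError("need at least 2 genes to draw edges")
    rng = np.random.default_rng(config.seed + 2)
    weights = np.array([config.hub_multiplier if g in set(config.hub_genes) else 1.0
                        for g in genes])
    prob = weights / weights.sum()

    edges: list[tuple[str, str, str, bool]] = []
    seen: set[tuple[str, str, str]] = set()
    max_draws = 50 * max(config.n_edges, 1)
    draws = 0
    while len(edges) < config.n_edges and draws < max_draws:
        draws += 1
        src, tgt = rng.choice(len(genes), size=2, p=prob)
        if src == tgt:
            continue
        rel = RELATION_CODES[rng.integers(len(RELATION_CODES))]
        key = (genes[src], genes[tgt], rel)
        if key in seen:
            continue
        seen.add(key)
        edges.append((genes[src], genes[tgt], rel, rel not in UNDIRECTED_RELATIONS))
    if len(edges) < config.n_edges:
        raise InvalidConfigError(
            f"could not place {config.n_edges} unique edges on {len(genes)} genes"
        )
    return InteractionEdgeList(edges=edges)


@dataclass
class SyntheticBundle:
    """One complete synthetic study: inputs for every pipeline stage plus truth."""

    matrix: ExpressionMatrix
    collection: GeneSetCollection
    edges: InteractionEdgeList
    term_relations: list[tuple[str, str]]
    truth: SimTruth


def simulate_term_relations(term_ids, config: SimConfig, n_relations: int | None = None
                            ) -> list[tuple[str, str]]:
    """Random distinct term pairs standing in for curated term-term links."""
    term_ids = list(term_ids)
    if n_relations is None:
        n_relations = 2 * len(term_ids)
    if len(term_ids) < 2:
        return []
    rng = np.random.default_rng(config.seed + 3)
    pairs: set[tuple[str, str]] = set()
    max_pairs = len(term_ids) * (len(term_ids) - 1) // 2
    while len(pairs) < min(n_relations, max_pairs):
        i, j = rng.choice(len(term_ids), size=2, replace=False)
        pairs.add((term_ids[min(i, j)], term_ids[max(i, j)]))
    return sorted(pairs)


def simulate_bundle(config: SimConfig, n_network_background: int = 100) -> SyntheticBundle:
    """Generate a coherent study: expression, annotation, interaction network.

    The interaction network is drawn over the planted DE genes plus a random
    background sample — mirroring a pathway-derived interaction source, which
    concentrates edges on genes of interest. If no hub is configured, the
    first planted DE gene (lexicographic) becomes the hub.
    """
    matrix, truth = simulate_expression(config)
    collection, truth = simulate_annotation(matrix.gene_ids, config, de_truth=truth)
    term_relations = simulate_term_relations(sorted(collection.terms), config)

    rng = np.random.default_rng(config.seed + 4)
    background = sorted(set(matrix.gene_ids) - truth.de_genes)
    n_bg = min(n_network_background, len(background))
    net_genes = sorted(truth.de_genes) + [
        background[i] for i in sorted(rng.choice(len(background), size=n_bg, replace=False))
    ]
    net_config = config
    if not config.hub_genes and truth.de_genes:
        net_config = replace(config, hub_genes=(min(truth.de_genes),))
    truth.hub_genes = set(net_config.hub_genes)
    edges = simulate_interaction_network(net_genes, net_config)
    return SyntheticBundle(matrix=matrix, collection=collection, edges=edges,
                          term_relations=term_relations, truth=truth)
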