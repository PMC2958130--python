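"""Seeded generators for synthetic cohorts, interaction graphs and gene sets.

The cohort generator emulates paired two-channel expression data: per-gene
log-intensity baselines, intensity-dependent (decreasing) noise, a
configurable fraction of truly responsive genes, and per-donor response
heterogeneity (each responsive gene responds in a given donor with
probability ``response_prob``).  The graph generator clusters responsive
genes into densely wired modules bridged by linker genes, with
non-responsive genes attached sparsely.  All generators are deterministic
given the seed.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np

from .io_formats import DEFAULT_SEED, IntensityPair
from .netstruct import KnowledgeGraph

logger = logging.getLogger("evoccur.synthdata")

__all__ = [
    "CohortSpec",
    "SyntheticTruth",
    "generate_cohort",
    "generate_graph",
    "generate_genesets",
    "heterogeneity_scenario",
]


@dataclass
class CohortSpec:
    """Parameters of the synthetic paired-intensity cohort.

    ``effect_size`` is expressed in multiples of the local spread of the
    paired log-difference (so an effect of 3 puts a responding gene's
    expected standardized deviation near 3).  ``noise_floor``/``noise_amp``/
    ``noise_scale`` parameterize the decreasing per-channel noise
    ``sigma(b) = floor + amp * exp(-(b - b_ref) / scale)`` with
    ``b_ref = baseline_mean - 2 * baseline_sd``.
    """

    n_genes: int = 2000
    n_donors: int = 6
    frac_de: float = 0.10
    response_prob: float = 1.0
    effect_size: float = 3.0
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    noise_floor: float = 0.15
    noise_amp: float = 0.6
    noise_scale: float = 1.5
    replicate_probes_per_gene: int = 1
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if not (0.0 < self.frac_de < 1.0):
            raise ValueError(f"frac_de must be in (0,1), got {self.frac_de}")
        if not (0.0 < self.response_prob <= 1.0):
            raise ValueError(f"response_prob must be in (0,1], got {self.response_prob}")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.n_genes < 20 or self.n_donors < 2:
            raise ValueError("infeasible cohort spec: too few genes or donors")
        if self.replicate_probes_per_gene < 1:
            raise ValueError("replicate_probes_per_gene must be >= 1")

    def sigma(self, b: np.ndarray) -> np.ndarray:
        b_ref = self.baseline_mean - 2.0 * self.baseline_sd
        return self.noise_floor + self.noise_amp * np.exp(-(np.asarray(b) - b_ref) / self.noise_scale)


@dataclass
class SyntheticTruth:
    """Ground-truth labels written alongside generated data."""

    gene_ids: list[str]
    de_genes: list[str]
    direction: dict[str, int]              # +1 / -1 for responsive genes
    responded: dict[str, dict[str, bool]]  # gene -> donor -> responded
    module_id: dict[str, int] = field(default_factory=dict)
    noise_model: str = ""

    def to_json(self, path: str | Path) -> None:
        data = {
            "gene_ids": self.gene_ids,
            "de_genes": self.de_genes,
            "direction": self.direction,
            "responded": self.responded,
            "module_id": self.module_id,
            "noise_model": self.noise_model,
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(data, fh, indent=1)
            fh.write("\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path, encoding="utf-8") as fh:
            data = json.load(fh)
        return cls(
            gene_ids=data["gene_ids"],
            de_genes=data["de_genes"],
            direction={k: int(v) for k, v in data["direction"].items()},
            responded={g: {d: bool(v) for d, v in dd.items()} for g, dd in data["responded"].items()},
            module_id={k: int(v) for k, v in data["module_id"].items()},
            noise_model=data.get("noise_model", ""),
        )


def generate_cohort(spec: CohortSpec) -> tuple[dict[str, list[IntensityPair]], SyntheticTruth]:
    """Per-donor intensity tables plus ground truth.

    ref = exp(b + eps), test = exp(b + responded*direction*effect*sqrt(2)*
    sigma(b) + eps'), eps ~ N(0, sigma(b)); sqrt(2)*sigma(b) is the local
    spread of the paired log-difference.  Replicate probes share the gene
    signal with independent noise.
    """
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_genes - 1))
    gene_ids = [f"G{i:0{width}d}" for i in range(spec.n_genes)]
    n_de = int(round(spec.frac_de * spec.n_genes))
    de_idx = rng.choice(spec.n_genes, size=n_de, replace=False)
    de_mask = np.zeros(spec.n_genes, dtype=bool)
    de_mask[de_idx] = True
    direction = np.where(rng.random(spec.n_genes) < 0.5, 1, -1)
    direction[~de_mask] = 0

    b = rng.normal(spec.baseline_mean, spec.baseline_sd, spec.n_genes)
    sig = spec.sigma(b)
    diff_spread = math.sqrt(2.0) * sig  # spread of eps' - eps

    donors = [f"donor{d + 1}" for d in range(spec.n_donors)]
    responded = rng.random((spec.n_genes, spec.n_donors)) < spec.response_prob
    responded &= de_mask[:, None]

    tables: dict[str, list[IntensityPair]] = {}
    for j, donor in enumerate(donors):
        shift = responded[:, j] * direction * spec.effect_size * diff_spread
        pairs: list[IntensityPair] = []
        for _rep in range(spec.replicate_probes_per_gene):
            eps_ref = rng.normal(0.0, sig)
            eps_test = rng.normal(0.0, sig)
            ref = np.exp(b + eps_ref)
            test = np.exp(b + shift + eps_test)
            pairs.extend(
                IntensityPair(g, donor, float(r), float(t))
                for g, r, t in zip(gene_ids, ref, test)
            )
        tables[donor] = pairs

    truth = SyntheticTruth(
        gene_ids=gene_ids,
        de_genes=[gene_ids[i] for i in np.flatnonzero(de_mask)],
        direction={gene_ids[i]: int(direction[i]) for i in np.flatnonzero(de_mask)},
        responded={
            gene_ids[i]: {donors[j]: bool(responded[i, j]) for j in range(spec.n_donors)}
            for i in np.flatnonzero(de_mask)
        },
        noise_model=(
            f"sigma(b) = {spec.noise_floor} + {spec.noise_amp} * "
            f"exp(-(b - {spec.baseline_mean - 2 * spec.baseline_sd}) / {spec.noise_scale})"
        ),
    )
    logger.info(
        "generate_cohort genes=%d donors=%d de=%d rho=%.2f effect=%.1f seed=%d",
        spec.n_genes, spec.n_donors, n_de, spec.response_prob, spec.effect_size, spec.seed,
    )
    return tables, truth


def generate_graph(
    truth: SyntheticTruth,
    n_modules: int = 3,
    intra_p: float = 0.3,
    inter_p: float = 0.01,
    linker_genes: int = 20,
    attach_p: float = 0.3,
    module_weights: Sequence[float] | None = None,
    n_bridge_genes: int = 0,
    bridge_edges: int = 2,
    seed: int = DEFAULT_SEED,
) -> KnowledgeGraph:
    """Module-structured interaction graph over the cohort's genes.

    Responsive genes are partitioned into ``n_modules`` modules sized by
    ``module_weights`` (equal by default) and wired densely within modules
    (edge probability ``intra_p``); diffuse inter-module edges appear with
    probability ``inter_p``.  ``n_bridge_genes`` designated genes of each
    module additionally carry ``bridge_edges`` edges into the preceding
    module (chained localized bridges — the fodder for genes shared
    between networks).  ``linker_genes`` non-responsive genes bridge module
    pairs; remaining non-responsive genes are wired pairwise to each other
    with probability ``attach_p``, giving false-positive genes an edge (so
    they are network-eligible) without creating paths into the modules.
    Module assignments are recorded in ``truth.module_id``.
    """
    if not (0.0 <= inter_p < intra_p <= 1.0):
        raise ValueError("need intra_p > inter_p within [0,1]")
    rng = np.random.default_rng(seed)
    de = list(truth.de_genes)
    rng.shuffle(de)
    if module_weights is None:
        modules = [list(chunk) for chunk in np.array_split(de, n_modules)]
    else:
        if len(module_weights) != n_modules or any(w <= 0 for w in module_weights):
            raise ValueError("module_weights must give a positive weight per module")
        w = np.asarray(module_weights, dtype=float)
        cuts = np.cumsum(np.round(w / w.sum() * len(de)).astype(int))[:-1]
        modules = [list(chunk) for chunk in np.split(np.asarray(de), cuts)]
    truth.module_id.update({g: m for m, genes in enumerate(modules) for g in genes})

    g = nx.Graph()
    g.add_nodes_from(truth.gene_ids)
    for genes in modules:
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                if rng.random() < intra_p:
                    g.add_edge(genes[i], genes[j], interaction="direct")
    if inter_p > 0:
        for mi in range(n_modules):
            for mj in range(mi + 1, n_modules):
                for a in modules[mi]:
                    for b_ in modules[mj]:
                        if rng.random() < inter_p:
                            g.add_edge(a, b_, interaction="indirect")
    if n_bridge_genes > 0:
        for j in range(1, n_modules):
            picks = rng.choice(
                len(modules[j]), size=min(n_bridge_genes, len(modules[j])), replace=False
            )
            for pi in picks:
                bridge = modules[j][pi]
                targets = rng.choice(
                    len(modules[j - 1]),
                    size=min(bridge_edges, len(modules[j - 1])),
                    replace=False,
                )
                for t in targets:
                    g.add_edge(bridge, modules[j - 1][t], interaction="indirect")

    non_de = [x for x in truth.gene_ids if x not in set(truth.de_genes)]
    rng.shuffle(non_de)
    linkers, rest = non_de[:linker_genes], non_de[linker_genes:]
    for linker in linkers:
        picked = rng.choice(n_modules, size=min(2, n_modules), replace=False)
        for m in picked:
            if modules[m]:
                targets = rng.choice(len(modules[m]), size=min(2, len(modules[m])), replace=False)
                for t in targets:
                    g.add_edge(linker, modules[m][t], interaction="direct")
    for a, b_ in zip(rest[0::2], rest[1::2]):
        if rng.random() < attach_p:
            g.add_edge(a, b_, interaction="direct")

    logger.info(
        "generate_graph modules=%d nodes=%d edges=%d",
        n_modules, g.number_of_nodes(), g.number_of_edges(),
    )
    return KnowledgeGraph(g, background_size=len(truth.gene_ids))


def heterogeneity_scenario(
    seed: int = DEFAULT_SEED, response_prob: float = 0.67
) -> tuple[CohortSpec, dict[str, list[IntensityPair]], SyntheticTruth, KnowledgeGraph]:
    """Reference donor-heterogeneity scenario for end-to-end runs.

    A 6-donor cohort whose responsive genes respond in each donor with
    probability ``response_prob`` and cluster into size-graded interaction
    modules chained by a few bridge genes, plus pairwise-wired background
    genes.  With ``response_prob`` near 4/6 the network structuring peak
    sits at occurrence >= 4/6.
    """
    spec = CohortSpec(
        n_genes=2500,
        n_donors=6,
        frac_de=0.064,
        response_prob=response_prob,
        effect_size=3.5,
        seed=seed,
    )
    tables, truth = generate_cohort(spec)
    graph = generate_graph(
        truth,
        n_modules=6,
        intra_p=0.3,
        inter_p=0.0,
        linker_genes=0,
        attach_p=1.0,
        module_weights=(34, 28, 26, 24, 22, 20),
        n_bridge_genes=2,
        bridge_edges=2,
        seed=seed,
    )
    return spec, tables, truth, graph


def generate_genesets(
    truth: SyntheticTruth,
    n_sets: int = 10,
    hit_fraction: float = 0.5,
    set_size: int = 40,
    seed: int = DEFAULT_SEED,
) -> tuple[dict[str, frozenset[str]], set[str]]:
    """Named gene sets, half enriched in responsive genes at ``hit_fraction``.

    Returns (sets, names of the enriched sets).
    """
    if not (0.0 < hit_fraction <= 1.0):
        raise ValueError(f"hit_fraction must be in (0,1], got {hit_fraction}")
    rng = np.random.default_rng(seed)
    de = list(truth.de_genes)
    non_de = [x for x in truth.gene_ids if x not in set(de)]
    sets: dict[str, frozenset[str]] = {}
    enriched: set[str] = set()
    n_enriched = n_sets // 2
    for i in range(n_sets):
        if i < n_enriched:
            n_hit = min(int(round(hit_fraction * set_size)), len(de))
            hits = rng.choice(len(de), size=n_hit, replace=False)
            fill = rng.choice(len(non_de), size=set_size - n_hit, replace=False)
            members = {de[h] for h in hits} | {non_de[f] for f in fill}
            name = f"SET_ENR_{i:02d}"
            enriched.add(name)
        else:
            pool = truth.gene_ids
            pick = rng.choice(len(pool), size=min(set_size, len(pool)), replace=False)
            members = {pool[p] for p in pick}
            name = f"SET_RND_{i:02d}"
        sets[name] = frozenset(members)
    return sets, enriched
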