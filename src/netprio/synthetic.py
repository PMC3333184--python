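"""Synthetic benchmark generator: planted disease modules in a random network.

Network-based prioritization rests on the working hypothesis that the
causative genes of one disease sit close together in a biological
network.  The generator makes that hypothesis literally true in a
controllable way: a planted-partition graph in which genes of the same
module connect with probability ``p_within`` and all other pairs with
``p_between``, each module being emitted as one disease family.  A
companion position table scatters genes across chromosomes, so a
linkage window around a disease gene is filled mostly with unrelated
background genes — the situation a real linkage interval presents.

Everything is a pure function of the spec, including its seed; the
same spec always yields byte-identical artifacts.
"""

from __future__ import annotations

import dataclasses

import networkx as nx
import numpy as np

from .network_io import DiseaseFamilyTable, GeneNetwork, GenePositionTable

__all__ = [
    "SyntheticSpec",
    "generate_planted_network",
    "generate_positions",
    "benchmark_fixture",
    "PROFILES",
]

_WEIGHT_MODELS = ("unit", "uniform", "beta")


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a planted-module benchmark network.

    ``weight_model`` is ``("unit",)`` for an unweighted network,
    ``("uniform", lo, hi)`` or ``("beta", a, b)`` for confidence-style
    weights in (0, 1].  ``holdout_fraction`` removes that fraction of
    each module's genes from its disease family (they stay in the
    network as unlabeled module members); at least two labeled members
    always remain.
    """

    n_modules: int
    module_size: int
    n_background: int
    p_within: float
    p_between: float
    weight_model: tuple = ("unit",)
    rng_seed: int = 0
    holdout_fraction: float = 0.0

    def __post_init__(self):
        if self.n_modules < 1 or self.module_size < 2 or self.n_background < 0:
            raise ValueError("need n_modules >= 1, module_size >= 2, n_background >= 0")
        if not (0.0 <= self.p_between <= self.p_within <= 1.0):
            raise ValueError("need 0 <= p_between <= p_within <= 1")
        if not (0.0 <= self.holdout_fraction < 1.0):
            raise ValueError("holdout_fraction must be in [0, 1)")
        model = self.weight_model[0]
        if model not in _WEIGHT_MODELS:
            raise ValueError(f"weight_model must be one of {_WEIGHT_MODELS}")
        if model == "uniform":
            lo, hi = self.weight_model[1], self.weight_model[2]
            if not (0.0 < lo <= hi <= 1.0):
                raise ValueError("uniform weights need 0 < lo <= hi <= 1")
        if model == "beta":
            a, b = self.weight_model[1], self.weight_model[2]
            if a <= 0 or b <= 0:
                raise ValueError("beta weights need positive shape parameters")

    @property
    def n_nodes(self) -> int:
        return self.n_modules * self.module_size + self.n_background

    @property
    def weighted(self) -> bool:
        return self.weight_model[0] != "unit"


def _node_names(spec: SyntheticSpec) -> tuple[list[str], np.ndarray]:
    names = [
        f"M{m + 1:02d}G{g + 1:02d}"
        for m in range(spec.n_modules)
        for g in range(spec.module_size)
    ]
    names += [f"BG{i + 1:05d}" for i in range(spec.n_background)]
    module_of = np.full(spec.n_nodes, -1)
    module_of[: spec.n_modules * spec.module_size] = np.repeat(
        np.arange(spec.n_modules), spec.module_size
    )
    return names, module_of


def generate_planted_network(spec: SyntheticSpec) -> tuple[GeneNetwork, DiseaseFamilyTable]:
    """Draw the planted-partition network and its disease-family table.

    Edges are drawn first and weights second, so two specs differing
    only in ``weight_model`` share an identical topology.
    """
    rng = np.random.default_rng(spec.rng_seed)
    names, module_of = _node_names(spec)
    n = spec.n_nodes

    edge_idx: list[tuple[int, int]] = []
    for i in range(n - 1):
        js = np.arange(i + 1, n)
        p = np.where(
            (module_of[i] >= 0) & (module_of[js] == module_of[i]),
            spec.p_within,
            spec.p_between,
        )
        hits = js[rng.random(js.size) < p]
        edge_idx.extend((i, int(j)) for j in hits)
    if not edge_idx:
        raise ValueError("spec yields an empty network (no edges drawn)")

    model = spec.weight_model[0]
    if model == "unit":
        weights = np.ones(len(edge_idx))
    elif model == "uniform":
        weights = rng.uniform(spec.weight_model[1], spec.weight_model[2], len(edge_idx))
    else:  # beta
        weights = rng.beta(spec.weight_model[1], spec.weight_model[2], len(edge_idx))

    graph = nx.Graph()
    graph.add_nodes_from(names)
    for (i, j), w in zip(edge_idx, weights):
        graph.add_edge(names[i], names[j], weight=float(w))
    network = GeneNetwork(graph, weighted=spec.weighted)

    families: dict[str, frozenset] = {}
    for m in range(spec.n_modules):
        members = sorted(names[m * spec.module_size : (m + 1) * spec.module_size])
        n_hold = min(int(round(spec.holdout_fraction * len(members))), len(members) - 2)
        if n_hold > 0:
            held = set(rng.choice(members, size=n_hold, replace=False))
            members = [g for g in members if g not in held]
        families[f"F{m + 1:02d}"] = frozenset(members)
    return network, DiseaseFamilyTable(families)


def generate_positions(
    network: GeneNetwork, n_chromosomes: int, rng_seed: int
) -> GenePositionTable:
    """Scatter genes over chromosomes: shuffled, dealt round-robin, increasing starts."""
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    rng = np.random.default_rng(rng_seed)
    genes = list(network.nodes)
    order = rng.permutation(len(genes))
    positions = {}
    for slot, gi in enumerate(order):
        chrom = f"chr{(slot % n_chromosomes) + 1}"
        start = (slot // n_chromosomes + 1) * 1000
        positions[genes[gi]] = (chrom, start)
    return GenePositionTable(positions)


#: profile -> (spec, n_chromosomes, position seed)
PROFILES: dict[str, tuple[SyntheticSpec, int, int]] = {
    "tiny": (SyntheticSpec(2, 5, 50, 0.9, 0.02, ("unit",), rng_seed=7), 2, 107),
    "default": (SyntheticSpec(8, 15, 1500, 0.3, 0.005, ("unit",), rng_seed=42), 8, 142),
    "weighted": (SyntheticSpec(8, 15, 1500, 0.3, 0.005, ("beta", 2.0, 2.0), rng_seed=42), 8, 142),
}


def benchmark_fixture(
    profile: str,
) -> tuple[GeneNetwork, DiseaseFamilyTable, GenePositionTable]:
    """Canned benchmark instances with fixed seeds.

    ``tiny`` (2 modules x 5 genes, 50 background) for fast unit tests;
    ``default`` (8 x 15 modules, 1500 background, p_within 0.3,
    p_between 0.005, unit weights) for the planted-module benchmark;
    ``weighted`` shares the default topology with beta(2, 2) weights to
    exercise the confidence-weighted path.
    """
    if profile not in PROFILES:
        raise ValueError(f"unknown profile {profile!r}; available: {sorted(PROFILES)}")
    spec, n_chrom, pos_seed = PROFILES[profile]
    network, families = generate_planted_network(spec)
    positions = generate_positions(network, n_chrom, pos_seed)
    return network, families, positions
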