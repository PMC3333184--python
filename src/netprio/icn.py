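"""Interconnectedness (ICN) scoring of gene pairs and candidate ranking.

The ICN score measures the closeness of two genes in a network by
combining their direct edge weight with the evidence carried by their
shared interaction partners ("connectors"):

    ICN_ij = w_ij + ( sum_{u in N_i ∩ N_j} w_iu * w_uj ) / E_ij

where N_g is the neighbor set of gene g and E_ij = k_i * k_j / sum_g k_g
is the expected number of connectors for a pair with strengths k_i and
k_j (k_i being the sum of incident edge weights, i.e. the degree in an
unweighted network).  Normalizing by E_ij stops hub genes from
accumulating connector credit merely by having many neighbors.  The
score is parameter-free: nothing in it is trained on the network.

Candidate genes are scored against a seed set S_d (the known genes of a
disease family) by summing their ICN to every seed,

    Score_i = sum_{j in S_d} ICN_ij,

and ranked in descending score order with average ranks for ties.

The connector aggregation is pluggable via ``formula``; ``"product"``
(the default above) multiplies the two connector-edge weights,
``"average"`` averages them.  Both coincide on unweighted networks.
"""

from __future__ import annotations

from collections.abc import Iterable
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.stats

from .network_io import GeneNetwork

__all__ = ["RankedList", "strength", "icn_score", "candidate_scores", "assign_ranks", "FORMULAS"]


def _product_form(w_ij, connector_pairs, k_i, k_j, total_strength):
    conn = sum(w_iu * w_uj for w_iu, w_uj in connector_pairs)
    if conn == 0.0:
        return w_ij
    return w_ij + conn * total_strength / (k_i * k_j)


def _average_form(w_ij, connector_pairs, k_i, k_j, total_strength):
    conn = sum(0.5 * (w_iu + w_uj) for w_iu, w_uj in connector_pairs)
    if conn == 0.0:
        return w_ij
    return w_ij + conn * total_strength / (k_i * k_j)


#: name -> f(w_ij, [(w_iu, w_uj), ...], k_i, k_j, sum_g k_g)
FORMULAS = {"product": _product_form, "average": _average_form}


class RankedList:
    """Candidate genes with scores and ranks for one (method, seed set) pair.

    Entries are held in rank order (best first); tied scores share the
    average of the ranks they span, so a higher score never maps to a
    numerically larger rank.
    """

    def __init__(self, genes, scores, ranks, method: str = "", seeds: frozenset = frozenset()):
        self.genes: tuple[str, ...] = tuple(genes)
        self.scores = np.asarray(scores, dtype=float)
        self.ranks = np.asarray(ranks, dtype=float)
        if not (len(self.genes) == len(self.scores) == len(self.ranks)):
            raise ValueError("genes, scores and ranks must have equal length")
        self.method = method
        self.seeds = frozenset(seeds)
        self._rank_map = dict(zip(self.genes, self.ranks))
        self._score_map = dict(zip(self.genes, self.scores))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(zip(self.genes, self.scores, self.ranks))

    @property
    def candidate_set(self) -> frozenset:
        return frozenset(self.genes)

    def rank_of(self, gene: str) -> float:
        return float(self._rank_map[gene])

    def score_of(self, gene: str) -> float:
        return float(self._score_map[gene])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": self.genes, "score": self.scores, "rank": self.ranks})

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def read_tsv(cls, path: str | Path, method: str = "") -> "RankedList":
        df = pd.read_csv(path, sep="\t")
        return cls(df["gene_id"].astype(str), df["score"], df["rank"], method=method)


def strength(network: GeneNetwork, gene: str) -> float:
    """k_i: sum of the weights of ``gene``'s incident edges."""
    return network.strength(gene)


def icn_score(network: GeneNetwork, i: str, j: str, formula: str = "product") -> float:
    """ICN between two distinct genes of the network.

    The score of a gene with itself is undefined and raises rather than
    returning a convention value.
    """
    if i == j:
        raise ValueError("ICN of a gene with itself is undefined")
    fn = FORMULAS[formula]
    ni = network.neighbors(i)  # raises KeyError for unknown genes
    nj = network.neighbors(j)
    w_ij = ni.get(j, 0.0)
    common = sorted(set(ni) & set(nj))
    pairs = [(ni[u], nj[u]) for u in common]
    return float(
        fn(w_ij, pairs, network.strength(i), network.strength(j), network.total_strength)
    )


def assign_ranks(
    scores: Iterable[tuple[str, float]], method: str = "", seeds: frozenset = frozenset()
) -> RankedList:
    """Rank (gene, score) pairs descending by score with average-tie ranks.

    Two genes tied for positions 1-2 both receive rank 1.5; with ties
    the best rank is therefore not necessarily 1.  NaN scores are
    rejected (a NaN cannot be ordered).
    """
    items = list(scores)
    if not items:
        raise ValueError("cannot rank an empty score list")
    genes = [g for g, _ in items]
    vals = np.asarray([s for _, s in items], dtype=float)
    if np.isnan(vals).any():
        raise ValueError("NaN score cannot be ranked")
    ranks = scipy.stats.rankdata(-vals, method="average")
    order = np.argsort(ranks, kind="stable")
    return RankedList(
        genes=[genes[o] for o in order],
        scores=vals[order],
        ranks=ranks[order],
        method=method,
        seeds=seeds,
    )


def candidate_scores(
    network: GeneNetwork,
    seeds: Iterable[str],
    candidates: Iterable[str],
    formula: str = "product",
) -> RankedList:
    """Score and rank candidates against a seed set (Score_i = sum over seeds of ICN).

    A candidate that is itself a seed is scored against the *other*
    seeds only (its undefined self-score contributes nothing).  For the
    default formula the computation is vectorized with sparse matrix
    products; other formulas fall back to pairwise evaluation.
    """
    seed_list = sorted(set(seeds))
    cand_list = list(dict.fromkeys(candidates))
    if not seed_list:
        raise ValueError("empty seed set")
    if not cand_list:
        raise ValueError("empty candidate set")
    for g in seed_list + cand_list:
        if g not in network:
            raise KeyError(f"unknown gene {g!r}")

    if formula == "product":
        scores = _vectorized_product_scores(network, seed_list, cand_list)
    else:
        scores = np.array(
            [
                sum(icn_score(network, c, s, formula=formula) for s in seed_list if s != c)
                for c in cand_list
            ]
        )
    return assign_ranks(
        zip(cand_list, scores), method="icn", seeds=frozenset(seed_list)
    )


def _vectorized_product_scores(
    network: GeneNetwork, seed_list: list[str], cand_list: list[str]
) -> np.ndarray:
    A = network.adjacency_matrix
    k = network.strengths
    total = network.total_strength
    idx_s = np.array([network.node_index[s] for s in seed_list])
    idx_c = np.array([network.node_index[c] for c in cand_list])
    a_cols = A[:, idx_s]
    direct = A[idx_c][:, idx_s].toarray()
    conn = (A[idx_c] @ a_cols).toarray()
    denom = np.outer(k[idx_c], k[idx_s])
    with np.errstate(divide="ignore", invalid="ignore"):
        factor = np.where(denom > 0, total / np.where(denom > 0, denom, 1.0), 0.0)
    icn = direct + conn * factor
    # a candidate that is also a seed: zero out its (undefined) self term
    seed_col = {si: col for col, si in enumerate(idx_s)}
    for row, ci in enumerate(idx_c):
        col = seed_col.get(ci)
        if col is not None:
            icn[row, col] = 0.0
    return icn.sum(axis=1)
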