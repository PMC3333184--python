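"""Rank-product combination of prioritization results.

Each method contributes a rank R_ij for candidate gene i; the combined
score is the product over methods,

    CS_i = prod_j R_ij,

and candidates are re-ranked ascending in CS (the lower the combined
score, the higher the priority).  Multiplying ranks rather than scores
keeps the combination scale-free across methods whose raw scores are
not comparable.  Fractional ranks produced by tie-averaging multiply
as-is.
"""

from __future__ import annotations

from collections.abc import Sequence
from pathlib import Path

import numpy as np
import pandas as pd

from .icn import RankedList, assign_ranks

__all__ = ["CombinedRanking", "combine_rankings", "COMBINATION_PRESETS"]

#: preset label -> method labels entering the product
COMBINATION_PRESETS: dict[str, tuple[str, ...]] = {
    "icn-rw": ("icn", "rw"),
    "icn-pr": ("icn", "prince"),
    "rw-pr": ("rw", "prince"),
    "icn-rw-pr": ("icn", "rw", "prince"),
}


class CombinedRanking:
    """Candidates with combined scores CS and final (ascending-CS) ranks."""

    def __init__(self, genes, combined_scores, ranks, methods: tuple[str, ...]):
        self.genes: tuple[str, ...] = tuple(genes)
        self.combined_scores = np.asarray(combined_scores, dtype=float)
        self.ranks = np.asarray(ranks, dtype=float)
        self.methods = tuple(methods)
        self._rank_map = dict(zip(self.genes, self.ranks))
        self._score_map = dict(zip(self.genes, self.combined_scores))

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(zip(self.genes, self.combined_scores, self.ranks))

    @property
    def candidate_set(self) -> frozenset:
        return frozenset(self.genes)

    def rank_of(self, gene: str) -> float:
        return float(self._rank_map[gene])

    def score_of(self, gene: str) -> float:
        return float(self._score_map[gene])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene_id": self.genes, "combined_score": self.combined_scores, "rank": self.ranks}
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def combine_rankings(
    rankings: Sequence[RankedList], allow_single: bool = False
) -> CombinedRanking:
    """Combine per-method rankings over an identical candidate set by rank product.

    The result is invariant to the order in which method rankings are
    supplied.  Tied combined scores receive average final ranks.
    """
    if not rankings:
        raise ValueError("no rankings to combine")
    if len(rankings) < 2 and not allow_single:
        raise ValueError("need at least 2 rankings to combine")
    base = rankings[0].candidate_set
    for r in rankings[1:]:
        if r.candidate_set != base:
            diff = sorted(base.symmetric_difference(r.candidate_set))
            raise ValueError(f"candidate sets differ; symmetric difference: {diff}")
    genes = sorted(base)
    cs = np.prod([[r.rank_of(g) for g in genes] for r in rankings], axis=0)
    # descending order of -CS == ascending order of CS
    ranked = assign_ranks(zip(genes, -cs))
    return CombinedRanking(
        genes=ranked.genes,
        combined_scores=-ranked.scores,
        ranks=ranked.ranks,
        methods=tuple(r.method for r in rankings),
    )
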