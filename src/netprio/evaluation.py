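"""Leave-one-out benchmark harness, success-rate bookkeeping and topology analysis.

For every disease-gene association (family, gene), one trial removes
that association, seeds the methods with the remaining family members,
and asks each method to re-find the held-out gene within a candidate
set.  Two scenarios define the candidate set:

``linkage``
    the held-out gene plus a fixed number of genomically flanking genes
    (default 100) on the same chromosome — mimicking a linkage interval;
``genome_scan``
    every network gene except the other members of the held-out gene's
    family.

A trial succeeds at cutoff k if the held-out gene's rank is <= k; with
average-tie ranks a gene tied across the boundary (rank k + 0.5) counts
as a failure.  The success rate at k is the fraction of successful
trials.
"""

from __future__ import annotations

import dataclasses
import math
from collections.abc import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd
import scipy.stats

from .combine import COMBINATION_PRESETS, combine_rankings
from .icn import RankedList, candidate_scores
from .network_io import DiseaseFamilyTable, GeneNetwork, GenePositionTable
from .propagation import (
    ConvergenceError,
    PropagationConfig,
    prince_propagate,
    propagation_ranked_list,
    random_walk,
)

__all__ = [
    "TrialResult",
    "SkippedTrial",
    "EvaluationSummary",
    "OverlapTable",
    "RescueReport",
    "TopologyReport",
    "linkage_candidate_set",
    "genome_scan_candidate_set",
    "run_leave_one_out",
    "success_overlap",
    "rescued_cases",
    "unique_case_topology",
]

BASE_METHODS = ("icn", "rw", "prince")
SCENARIOS = ("linkage", "genome_scan")


@dataclasses.dataclass(frozen=True)
class TrialResult:
    """Outcome of one leave-one-out trial across all methods."""

    family_id: str
    gene: str
    n_candidates: int
    ranks: dict[str, float]  # method/preset -> rank of the held-out gene (NaN = failed)
    warning: str | None = None


@dataclasses.dataclass(frozen=True)
class SkippedTrial:
    family_id: str
    gene: str
    reason: str


def linkage_candidate_set(
    test_gene: str,
    positions: GenePositionTable,
    network: GeneNetwork,
    flank_total: int = 100,
) -> tuple[tuple[str, ...], str | None]:
    """Candidate window for the simulated-linkage scenario.

    Returns the ``flank_total`` network-present genes nearest the test
    gene on its chromosome (half on each side where possible, borrowing
    from the other side at chromosome ends) plus the test gene itself.
    If the chromosome holds fewer positioned network genes, the whole
    chromosome is returned together with a warning string.
    """
    if flank_total % 2 != 0:
        raise ValueError("flank_total must be even")
    if test_gene not in positions:
        raise LookupError(f"test gene {test_gene!r} has no position")
    chrom = positions.chromosome(test_gene)
    ordered = [g for g in positions.ordered_genes(chrom) if g in network]
    if test_gene not in ordered:
        raise LookupError(f"test gene {test_gene!r} not in network")
    idx = ordered.index(test_gene)
    half = flank_total // 2
    lo, hi = idx - half, idx + half
    n = len(ordered)
    if lo < 0:
        hi += -lo
        lo = 0
    if hi > n - 1:
        lo -= hi - (n - 1)
        hi = n - 1
        lo = max(lo, 0)
    candidates = tuple(ordered[lo : hi + 1])
    warning = None
    if len(candidates) < flank_total + 1:
        warning = (
            f"only {len(candidates) - 1} flanking genes available on {chrom} "
            f"(wanted {flank_total})"
        )
    return candidates, warning


def genome_scan_candidate_set(
    test_gene: str, family: Iterable[str], network: GeneNetwork
) -> tuple[str, ...]:
    """All network genes except the other members of the test gene's family."""
    excluded = set(family) - {test_gene}
    return tuple(g for g in network.nodes if g not in excluded)


def _score_trial(
    method: str,
    network: GeneNetwork,
    seeds: frozenset,
    candidates: Sequence[str],
    config: PropagationConfig,
    formula: str,
) -> RankedList:
    if method == "icn":
        return candidate_scores(network, seeds, candidates, formula=formula)
    if method == "rw":
        return propagation_ranked_list(random_walk(network, seeds, config), candidates)
    if method == "prince":
        return propagation_ranked_list(prince_propagate(network, seeds, config), candidates)
    raise ValueError(f"unknown method {method!r}; expected one of {BASE_METHODS}")


class EvaluationSummary:
    """Per-trial ranks plus success-rate aggregation over a rank-cutoff grid."""

    def __init__(
        self,
        scenario: str,
        base_methods: tuple[str, ...],
        combo_methods: tuple[str, ...],
        k_values: tuple[int, ...],
        trials: list[TrialResult],
        skipped: list[SkippedTrial],
    ):
        self.scenario = scenario
        self.base_methods = tuple(base_methods)
        self.combo_methods = tuple(combo_methods)
        self.k_values = tuple(sorted(k_values))
        self.trials = list(trials)
        self.skipped = list(skipped)

    @property
    def methods(self) -> tuple[str, ...]:
        return self.base_methods + self.combo_methods

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @staticmethod
    def trial_success(trial: TrialResult, method: str, k: int) -> bool:
        rank = trial.ranks.get(method, math.nan)
        return (not math.isnan(rank)) and rank <= k

    def success_count(self, method: str, k: int) -> int:
        return sum(self.trial_success(t, method, k) for t in self.trials)

    def success_rate(self, method: str, k: int) -> float:
        if not self.trials:
            raise ValueError("no trials recorded")
        return self.success_count(method, k) / self.n_trials

    def success_set(self, method: str, k: int = 1) -> frozenset:
        return frozenset(
            (t.family_id, t.gene) for t in self.trials if self.trial_success(t, method, k)
        )

    def success_table(self) -> pd.DataFrame:
        rows = [
            {"method": m, **{f"k={k}": self.success_rate(m, k) for k in self.k_values}}
            for m in self.methods
        ]
        return pd.DataFrame(rows).set_index("method")

    def trials_frame(self) -> pd.DataFrame:
        """Long-form table: one row per trial x method."""
        rows = []
        for t in self.trials:
            for m in self.methods:
                rank = t.ranks.get(m, math.nan)
                rows.append(
                    {
                        "family_id": t.family_id,
                        "gene": t.gene,
                        "method": m,
                        "n_candidates": t.n_candidates,
                        "rank": rank,
                        **{f"success_at_{k}": self.trial_success(t, m, k) for k in self.k_values},
                        "warning": t.warning or "",
                    }
                )
        return pd.DataFrame(rows)


def run_leave_one_out(
    network: GeneNetwork,
    families: DiseaseFamilyTable,
    methods: Sequence[str] = BASE_METHODS,
    scenario: str = "linkage",
    positions: GenePositionTable | None = None,
    k_values: Sequence[int] = (1, 5, 10),
    combine_presets: Sequence[str] = ("icn-rw", "icn-pr", "rw-pr", "icn-rw-pr"),
    config: PropagationConfig | None = None,
    formula: str = "product",
    flank_total: int = 100,
) -> EvaluationSummary:
    """Run the full leave-one-out benchmark: one trial per disease-gene association.

    Every method (and every combination preset derived from the same
    per-method rankings) is scored on the identical candidate set of
    each trial.  A method that fails to converge in a trial is recorded
    with rank NaN, which counts as unsuccessful at every cutoff.
    """
    if scenario not in SCENARIOS:
        raise ValueError(f"scenario must be one of {SCENARIOS}")
    if scenario == "linkage" and positions is None:
        raise ValueError("linkage scenario requires a gene-position table")
    methods = tuple(methods)
    for m in methods:
        if m not in BASE_METHODS:
            raise ValueError(f"unknown method {m!r}")
    combine_presets = tuple(combine_presets)
    for preset in combine_presets:
        needed = COMBINATION_PRESETS.get(preset)
        if needed is None:
            raise ValueError(f"unknown combination preset {preset!r}")
        if not set(needed) <= set(methods):
            raise ValueError(f"preset {preset!r} needs methods {needed}")
    config = config or PropagationConfig()

    trials: list[TrialResult] = []
    skipped: list[SkippedTrial] = []
    for fid in families:
        family = families[fid]
        for gene in sorted(family):
            seeds = frozenset(family - {gene})
            warning = None
            if scenario == "linkage":
                if gene not in positions:
                    skipped.append(SkippedTrial(fid, gene, "no position for test gene"))
                    continue
                candidates, warning = linkage_candidate_set(
                    gene, positions, network, flank_total=flank_total
                )
            else:
                candidates = genome_scan_candidate_set(gene, family, network)
            per_method: dict[str, RankedList | None] = {}
            for m in methods:
                try:
                    per_method[m] = _score_trial(m, network, seeds, candidates, config, formula)
                except ConvergenceError:
                    per_method[m] = None
            ranks = {
                m: (r.rank_of(gene) if r is not None else math.nan)
                for m, r in per_method.items()
            }
            for preset in combine_presets:
                members = COMBINATION_PRESETS[preset]
                if any(per_method[m] is None for m in members):
                    ranks[preset] = math.nan
                else:
                    combined = combine_rankings([per_method[m] for m in members])
                    ranks[preset] = combined.rank_of(gene)
            trials.append(TrialResult(fid, gene, len(candidates), ranks, warning))
    return EvaluationSummary(
        scenario=scenario,
        base_methods=methods,
        combo_methods=combine_presets,
        k_values=tuple(k_values),
        trials=trials,
        skipped=skipped,
    )


@dataclasses.dataclass(frozen=True)
class OverlapTable:
    """Counts of trials succeeded by each exact subset of methods, plus the union."""

    methods: tuple[str, ...]
    exact_counts: dict[tuple[str, ...], int]  # sorted method subset -> # trials
    union: int
    n_trials: int

    def count(self, *methods: str) -> int:
        return self.exact_counts.get(tuple(sorted(methods)), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"methods": "+".join(subset), "n_trials": n}
            for subset, n in sorted(self.exact_counts.items())
        ]
        rows.append({"methods": "any", "n_trials": self.union})
        return pd.DataFrame(rows)


def success_overlap(
    summary: EvaluationSummary, k: int = 1, methods: Sequence[str] | None = None
) -> OverlapTable:
    """Venn-style breakdown of top-k successes among (base) methods."""
    methods = tuple(methods) if methods is not None else summary.base_methods
    if len(methods) < 2:
        raise ValueError("overlap needs at least 2 methods")
    exact: dict[tuple[str, ...], int] = {}
    union = 0
    for t in summary.trials:
        subset = tuple(sorted(m for m in methods if summary.trial_success(t, m, k)))
        if subset:
            union += 1
            exact[subset] = exact.get(subset, 0) + 1
    return OverlapTable(methods=methods, exact_counts=exact, union=union, n_trials=summary.n_trials)


@dataclasses.dataclass(frozen=True)
class RescueReport:
    """Trials failed at k=1 by every single method but succeeded by a combination."""

    n_failed_by_all: int
    rescued: dict[str, int]  # preset -> # rescued trials

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"preset": p, "n_rescued": n} for p, n in sorted(self.rescued.items())]
        )


def rescued_cases(summary: EvaluationSummary, k: int = 1) -> RescueReport:
    failed = [
        t
        for t in summary.trials
        if not any(summary.trial_success(t, m, k) for m in summary.base_methods)
    ]
    rescued = {
        preset: sum(summary.trial_success(t, preset, k) for t in failed)
        for preset in summary.combo_methods
    }
    return RescueReport(n_failed_by_all=len(failed), rescued=rescued)


@dataclasses.dataclass(frozen=True)
class TopologyReport:
    """Topological profile of method-unique successes and their group comparisons."""

    cases: pd.DataFrame  # method, family_id, gene, degree, mean_distance, n_unreachable
    tests: pd.DataFrame  # metric, method_a, method_b, statistic, pvalue, n_a, n_b
    notices: tuple[str, ...]


def unique_case_topology(
    summary: EvaluationSummary,
    network: GeneNetwork,
    families: DiseaseFamilyTable,
    k: int = 1,
) -> TopologyReport:
    """Characterize genes found at top-k by exactly one method.

    For every method-unique held-out gene, reports its degree and its
    mean unweighted shortest-path hop distance to the other members of
    its family (unreachable members excluded from the mean and counted).
    Method pairs are compared per metric with a two-sided Mann-Whitney
    rank-sum test; comparisons involving an empty group are skipped.
    """
    if len(summary.base_methods) < 2:
        raise ValueError("topology analysis needs at least 2 methods")
    succ = {m: summary.success_set(m, k) for m in summary.base_methods}
    unique: dict[str, set] = {}
    for m in summary.base_methods:
        others = set().union(*(succ[o] for o in summary.base_methods if o != m))
        unique[m] = set(succ[m]) - others

    rows = []
    for m in summary.base_methods:
        for fid, gene in sorted(unique[m]):
            dists = nx.single_source_shortest_path_length(network.graph, gene)
            others = sorted(families[fid] - {gene})
            reachable = [dists[o] for o in others if o in dists]
            rows.append(
                {
                    "method": m,
                    "family_id": fid,
                    "gene": gene,
                    "degree": network.degree(gene),
                    "mean_distance": float(np.mean(reachable)) if reachable else math.nan,
                    "n_unreachable": len(others) - len(reachable),
                }
            )
    cases = pd.DataFrame(
        rows, columns=["method", "family_id", "gene", "degree", "mean_distance", "n_unreachable"]
    )

    notices: list[str] = []
    test_rows = []
    for metric in ("degree", "mean_distance"):
        for i, ma in enumerate(summary.base_methods):
            for mb in summary.base_methods[i + 1 :]:
                xa = cases.loc[cases["method"] == ma, metric].dropna().to_numpy()
                xb = cases.loc[cases["method"] == mb, metric].dropna().to_numpy()
                if len(xa) == 0 or len(xb) == 0:
                    notices.append(
                        f"skipped {metric} comparison {ma} vs {mb}: empty group"
                    )
                    continue
                stat = scipy.stats.mannwhitneyu(xa, xb, alternative="two-sided")
                test_rows.append(
                    {
                        "metric": metric,
                        "method_a": ma,
                        "method_b": mb,
                        "statistic": float(stat.statistic),
                        "pvalue": float(stat.pvalue),
                        "n_a": len(xa),
                        "n_b": len(xb),
                    }
                )
    tests = pd.DataFrame(
        test_rows,
        columns=["metric", "method_a", "method_b", "statistic", "pvalue", "n_a", "n_b"],
    )
    return TopologyReport(cases=cases, tests=tests, notices=tuple(notices))
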