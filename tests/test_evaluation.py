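"""Leave-one-out harness: candidate windows, trial bookkeeping, topology analysis."""

import math

import numpy as np
import pytest

from netprio.evaluation import (
    genome_scan_candidate_set,
    linkage_candidate_set,
    rescued_cases,
    run_leave_one_out,
    success_overlap,
    unique_case_topology,
)
from netprio.network_io import DiseaseFamilyTable, GeneNetwork, GenePositionTable
from netprio.synthetic import benchmark_fixture
from conftest import make_network


def chain_network(genes):
    return make_network(list(zip(genes, genes[1:])))


def uniform_positions(genes, chrom="chr1"):
    return GenePositionTable({g: (chrom, 10 * i) for i, g in enumerate(genes)})


class TestLinkageWindow:
    def test_balanced_window_in_the_middle(self):
        genes = [f"g{i:03d}" for i in range(201)]
        net = chain_network(genes)
        pos = uniform_positions(genes)
        cands, warning = linkage_candidate_set("g100", pos, net, flank_total=100)
        assert warning is None
        assert cands == tuple(genes[50:151])
        assert len(cands) == 101

    def test_end_borrowing_at_chromosome_start(self):
        genes = [f"g{i:03d}" for i in range(201)]
        net = chain_network(genes)
        pos = uniform_positions(genes)
        cands, warning = linkage_candidate_set("g000", pos, net, flank_total=100)
        assert warning is None
        assert cands == tuple(genes[:101])

    def test_short_chromosome_yields_warning(self):
        genes = [f"g{i:02d}" for i in range(80)]
        net = chain_network(genes)
        pos = uniform_positions(genes)
        cands, warning = linkage_candidate_set("g40", pos, net, flank_total=100)
        assert len(cands) == 80
        assert "79 flanking" in warning

    def test_only_network_genes_are_candidates(self):
        genes = [f"g{i}" for i in range(10)]
        net = chain_network(genes[:5])  # g5..g9 positioned but not in network
        pos = uniform_positions(genes)
        cands, _ = linkage_candidate_set("g2", pos, net, flank_total=4)
        assert set(cands) <= set(net.nodes)

    def test_unpositioned_gene_raises_lookup(self):
        net = chain_network(["a", "b", "c"])
        pos = uniform_positions(["a", "b"])
        with pytest.raises(LookupError):
            linkage_candidate_set("c", pos, net)

    def test_odd_flank_total_rejected(self):
        net = chain_network(["a", "b", "c"])
        with pytest.raises(ValueError):
            linkage_candidate_set("a", uniform_positions(["a", "b", "c"]), net, flank_total=5)


class TestGenomeScan:
    def test_excludes_other_family_members_only(self):
        genes = [f"g{i}" for i in range(10)]
        net = chain_network(genes)
        cands = genome_scan_candidate_set("g0", {"g0", "g1", "g2"}, net)
        assert "g0" in cands and "g1" not in cands and "g2" not in cands
        assert len(cands) == 8

    def test_two_member_family(self):
        net = chain_network(["a", "b", "c"])
        assert len(genome_scan_candidate_set("a", {"a", "b"}, net)) == 2

    def test_family_covering_network_degenerates(self):
        net = chain_network(["a", "b", "c"])
        assert genome_scan_candidate_set("a", {"a", "b", "c"}, net) == ("a",)


@pytest.fixture(scope="module")
def tiny_summary():
    net, fams, pos = benchmark_fixture("tiny")
    return net, fams, run_leave_one_out(net, fams, scenario="genome_scan")


class TestHarness:
    def test_one_trial_per_association(self, tiny_summary):
        net, fams, summary = tiny_summary
        assert summary.n_trials == fams.total_associations
        assert len({(t.family_id, t.gene) for t in summary.trials}) == summary.n_trials

    def test_success_rate_monotone_in_k(self, tiny_summary):
        _, _, summary = tiny_summary
        for m in summary.methods:
            rates = [summary.success_rate(m, k) for k in summary.k_values]
            assert all(0.0 <= r <= 1.0 for r in rates)
            assert rates == sorted(rates)

    def test_candidate_sets_exclude_other_family_members(self, tiny_summary):
        net, fams, summary = tiny_summary
        for t in summary.trials:
            n_family_others = len(fams[t.family_id]) - 1
            assert t.n_candidates == net.number_of_nodes - n_family_others

    def test_overlap_union_and_bounds(self, tiny_summary):
        _, _, summary = tiny_summary
        table = success_overlap(summary)
        per_method = {m: summary.success_count(m, 1) for m in summary.base_methods}
        assert table.union >= max(per_method.values())
        assert sum(table.exact_counts.values()) == table.union
        # exact-subset counts must re-aggregate to per-method totals
        for m, total in per_method.items():
            agg = sum(n for subset, n in table.exact_counts.items() if m in subset)
            assert agg == total

    def test_rescue_counts_consistent_with_trials(self, tiny_summary):
        _, _, summary = tiny_summary
        rep = rescued_cases(summary)
        hand_failed = [
            t
            for t in summary.trials
            if all(
                math.isnan(t.ranks[m]) or t.ranks[m] > 1 for m in summary.base_methods
            )
        ]
        assert rep.n_failed_by_all == len(hand_failed)
        for preset, n in rep.rescued.items():
            assert n == sum(1 for t in hand_failed if t.ranks[preset] <= 1)

    def test_rerun_is_byte_identical(self):
        net, fams, pos = benchmark_fixture("tiny")
        s1 = run_leave_one_out(net, fams, scenario="linkage", positions=pos)
        s2 = run_leave_one_out(net, fams, scenario="linkage", positions=pos)
        assert s1.trials_frame().to_csv(sep="\t") == s2.trials_frame().to_csv(sep="\t")
        assert s1.success_table().to_csv(sep="\t") == s2.success_table().to_csv(sep="\t")

    def test_linkage_on_short_chromosomes_records_warnings(self):
        net, fams, pos = benchmark_fixture("tiny")
        summary = run_leave_one_out(net, fams, scenario="linkage", positions=pos)
        # tiny chromosomes hold 30 genes, far fewer than the 100-gene window
        assert all(t.warning for t in summary.trials)
        assert summary.n_trials == fams.total_associations

    def test_linkage_requires_positions(self, tiny_summary):
        net, fams, _ = tiny_summary
        with pytest.raises(ValueError, match="position"):
            run_leave_one_out(net, fams, scenario="linkage")

    def test_preset_needs_its_methods(self, tiny_summary):
        net, fams, _ = tiny_summary
        with pytest.raises(ValueError, match="preset"):
            run_leave_one_out(
                net, fams, methods=("icn", "rw"), scenario="genome_scan",
                combine_presets=("icn-pr",),
            )


class TestTopology:
    def test_identical_success_sets_leave_unique_groups_empty(self):
        net, fams, _ = benchmark_fixture("tiny")
        summary = run_leave_one_out(
            net, fams, methods=("rw", "prince"), scenario="genome_scan",
            combine_presets=("rw-pr",),
        )
        # build a degenerate summary by duplicating one method's ranks
        for t in summary.trials:
            t.ranks["prince"] = t.ranks["rw"]
        report = unique_case_topology(summary, net, fams)
        assert report.cases.empty
        assert any("empty group" in n for n in report.notices)

    def test_degree_and_distance_values(self):
        # path a-b-c-d plus star hub h with 5 spokes
        net = make_network(
            [("a", "b"), ("b", "c"), ("c", "d")]
            + [("h", f"s{i}") for i in range(5)]
        )
        fams = DiseaseFamilyTable({"F": {"a", "d"}, "G": {"h", "s0"}})
        summary = run_leave_one_out(
            net, fams, methods=("icn", "rw"), scenario="genome_scan",
            combine_presets=(), k_values=(1,),
        )
        # force known unique sets: icn alone finds (F, a); rw alone finds (G, h)
        for t in summary.trials:
            t.ranks["icn"] = 1.0 if (t.family_id, t.gene) == ("F", "a") else 99.0
            t.ranks["rw"] = 1.0 if (t.family_id, t.gene) == ("G", "h") else 99.0
        report = unique_case_topology(summary, net, fams)
        cases = report.cases.set_index("gene")
        assert cases.loc["a", "degree"] == 1
        assert cases.loc["a", "mean_distance"] == 3.0  # a-b-c-d
        assert cases.loc["h", "degree"] == 5
        assert cases.loc["h", "mean_distance"] == 1.0
        assert not report.tests.empty

    def test_unreachable_family_members_counted_not_averaged(self):
        net = make_network([("a", "b"), ("x", "y")])
        fams = DiseaseFamilyTable({"F": {"a", "b", "x"}})
        summary = run_leave_one_out(
            net, fams, methods=("icn", "rw"), scenario="genome_scan",
            combine_presets=(), k_values=(1,),
        )
        for t in summary.trials:
            t.ranks["icn"] = 1.0 if t.gene == "a" else 99.0
            t.ranks["rw"] = 99.0
        report = unique_case_topology(summary, net, fams)
        row = report.cases.set_index("gene").loc["a"]
        assert row["mean_distance"] == 1.0  # only b reachable
        assert row["n_unreachable"] == 1
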