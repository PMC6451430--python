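"""Contribution signs, the >70% aggregation rule, and the network export."""

import itertools

import pytest

from panethnet import (
    ConsistencyError,
    DifferentialProtein,
    NoEvidenceError,
    ProcessEffect,
    TargetEvidence,
    aggregate_trend,
    build_network,
    classify_all_processes,
    contribution_sign,
)
from panethnet.trends import write_sif


class TestContributionSign:
    @pytest.mark.parametrize("direction,effect,expected", [
        ("up", "activation", "stimulatory"),
        ("down", "inhibition", "stimulatory"),
        ("up", "inhibition", "inhibitory"),   # abundant inhibitor pushes down
        ("down", "activation", "inhibitory"),  # depleted activator pushes down
    ])
    def test_sign_product_semantics(self, direction, effect, expected):
        assert contribution_sign(direction, effect) == expected


def recount_oracle(contributions, threshold=0.70):
    """Independent recount of the trichotomy rule."""
    stim = contributions.count("stimulatory")
    inhib = contributions.count("inhibitory")
    total = stim + inhib
    if stim / total > threshold:
        return "upregulated"
    if inhib / total > threshold:
        return "downregulated"
    return "dual"


class TestAggregateTrend:
    def test_apoptosis_example_19_of_25_inhibitory_is_downregulated(self):
        res = aggregate_trend(["inhibitory"] * 19 + ["stimulatory"] * 6)
        assert res.classification == "downregulated"
        assert res.n_inhibitory == 19 and res.n_stimulatory == 6
        assert 1 - res.fraction_stimulatory == pytest.approx(0.76)

    def test_dna_repair_example_5_of_7_stimulatory_is_upregulated(self):
        res = aggregate_trend(["stimulatory"] * 5 + ["inhibitory"] * 2)
        assert res.classification == "upregulated"
        assert res.fraction_stimulatory == pytest.approx(5 / 7)

    def test_exactly_seventy_percent_is_dual(self):
        res = aggregate_trend(["stimulatory"] * 7 + ["inhibitory"] * 3)
        assert res.fraction_stimulatory == pytest.approx(0.70)
        assert res.classification == "dual"

    def test_empty_contributions_is_no_evidence_error(self):
        with pytest.raises(NoEvidenceError):
            aggregate_trend([])

    def test_exhaustive_recount_oracle_up_to_length_12(self):
        """Every contribution list of length <= 12 agrees with the oracle."""
        for length in range(1, 13):
            for combo in itertools.product(("stimulatory", "inhibitory"),
                                           repeat=length):
                contribs = list(combo)
                assert aggregate_trend(contribs).classification == \
                    recount_oracle(contribs)

    def test_flipping_every_contribution_swaps_up_down_fixes_dual(self):
        flip = {"stimulatory": "inhibitory", "inhibitory": "stimulatory"}
        swap = {"upregulated": "downregulated",
                "downregulated": "upregulated", "dual": "dual"}
        for length in range(1, 11):
            for combo in itertools.product(("stimulatory", "inhibitory"),
                                           repeat=length):
                direct = aggregate_trend(list(combo)).classification
                flipped = aggregate_trend(
                    [flip[c] for c in combo]).classification
                assert flipped == swap[direct]


class TestClassifyAllProcesses:
    def test_single_protein_single_process_is_upregulated(self):
        effects = [ProcessEffect("P1", "GO:1", "exocytosis", "activation")]
        results, unannotated = classify_all_processes({"P1": "up"}, effects)
        assert len(results) == 1
        assert results[0].classification == "upregulated"  # 1/1 > 0.7
        assert unannotated == []

    def test_opposing_pair_is_dual(self):
        effects = [ProcessEffect("P1", "GO:1", "x", "activation"),
                   ProcessEffect("P2", "GO:1", "x", "activation")]
        results, _ = classify_all_processes({"P1": "up", "P2": "down"},
                                            effects)
        assert results[0].classification == "dual"  # 1 stim, 1 inhib

    def test_out_of_context_rows_and_unknown_proteins_ignored(self):
        effects = [
            ProcessEffect("P1", "GO:1", "x", "activation"),
            ProcessEffect("P1", "GO:2", "y", "activation", in_context=False),
            ProcessEffect("P9", "GO:3", "z", "inhibition"),
        ]
        results, unannotated = classify_all_processes({"P1": "up",
                                                       "P2": "up"}, effects)
        assert [r.process_id for r in results] == ["GO:1"]
        assert unannotated == ["P2"]

    def test_planted_process_majorities_recovered(self, default_bundle):
        """Generator's per-process classifications come back exactly."""
        truth = default_bundle.truth
        directions = {h: info["direction"]
                      for h, info in truth.human_differential.items()
                      if h in truth.targeted}
        results, _ = classify_all_processes(directions,
                                            default_bundle.effects)
        assert {r.process_id: r.classification for r in results} == \
            {pid: info["classification"]
             for pid, info in truth.process_truth.items()}
        for r in results:
            info = truth.process_truth[r.process_id]
            assert (r.n_stimulatory, r.n_inhibitory) == \
                (info["n_stimulatory"], info["n_inhibitory"])


class TestBuildNetwork:
    def test_minimal_chain_has_three_nodes_two_edges(self, tmp_path):
        ev = [TargetEvidence("P1", "LC3", "experimental", "")]
        eff = [ProcessEffect("P1", "GO:1", "exocytosis", "inhibition")]
        g = build_network(ev, eff, {"P1": "up"}, [])
        assert g.number_of_nodes() == 3 and g.number_of_edges() == 2
        assert g.edges["LC3", "P1"]["relation"] == "targets"
        assert g.edges["P1", "GO:1"]["relation"] == "inhibits"
        write_sif(g, tmp_path / "n.sif")
        assert (tmp_path / "n.sif").read_text() == \
            "LC3\ttargets\tP1\nP1\tinhibits\tGO:1\n"

    def test_protein_targeted_by_two_receptors_has_in_degree_two(self):
        ev = [TargetEvidence("P1", "LC3", "experimental", ""),
              TargetEvidence("P1", "p62", "p62_motif", "3:DDWAAL")]
        g = build_network(ev, [], {"P1": "up"}, [])
        assert g.in_degree("P1") == 2

    def test_dangling_effect_reference_is_consistency_error(self):
        eff = [ProcessEffect("GHOST", "GO:1", "x", "activation")]
        with pytest.raises(ConsistencyError, match="GHOST"):
            build_network([], eff, {"P1": "up"}, [])

    def test_graph_is_tripartite_with_counting_oracle(self, default_bundle):
        """Full synthetic network: node/edge counts match direct counting,
        and no receptor-process or protein-protein edges exist."""
        from panethnet import collect_evidence, MotifDefinition, XLIR_PATTERN
        from panethnet.simulate import P62_PATTERN_DEFAULT

        truth = default_bundle.truth
        directions = {h: info["direction"]
                      for h, info in truth.human_differential.items()}
        proteins = [(h, DifferentialProtein(
            info["mouse_id"], info["log2fc"], info["direction"], 0.01, 3))
            for h, info in truth.human_differential.items()]
        evidence = collect_evidence(
            proteins, default_bundle.fasta, default_bundle.interactors,
            default_bundle.lir_list,
            MotifDefinition.from_string("p62", P62_PATTERN_DEFAULT),
            MotifDefinition.from_string("xLIR", XLIR_PATTERN),
            default_bundle.domains,
            {frozenset(p) for p in default_bundle.ddi})
        effects = [e for e in default_bundle.effects if e.in_context]
        g = build_network(evidence, effects, directions, [])

        receptors = {e.receptor for e in evidence}
        targeted = {e.human_id for e in evidence}
        effect_proteins = {e.protein_id for e in effects}
        processes = {e.process_id for e in effects}
        assert g.number_of_nodes() == \
            len(receptors) + len(targeted | effect_proteins) + len(processes)
        rp_pairs = {(e.receptor, e.human_id) for e in evidence}
        pp_pairs = {(e.protein_id, e.process_id) for e in effects}
        assert g.number_of_edges() == len(rp_pairs) + len(pp_pairs)
        kinds = {n: d["kind"] for n, d in g.nodes(data=True)}
        for u, v in g.edges():
            assert (kinds[u], kinds[v]) in (("receptor", "protein"),
                                            ("protein", "process"))
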