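"""Motif scanning, DDI inference, evidence collection and Venn overlap."""

import itertools

import numpy as np
import pytest

from panethnet import (
    DifferentialProtein,
    MotifDefinition,
    LIR_CORE_PATTERN,
    SequenceAlphabetError,
    TargetEvidence,
    XLIR_PATTERN,
    collect_evidence,
    overlap_partition,
    predict_ddi_targets,
    scan_motif,
)
from panethnet.targets import AMINO_ACIDS

LIR_CORE = MotifDefinition.from_string("LIR-core", LIR_CORE_PATTERN)
XLIR = MotifDefinition.from_string("xLIR", XLIR_PATTERN)
P62 = MotifDefinition.from_string("p62", "[DE][DE][WFY]xx[LIV]")


def naive_scan(sequence, motif):
    """Independent sliding-window membership check."""
    hits = []
    m = len(motif.positions)
    for start in range(len(sequence) - m + 1):
        window = sequence[start:start + m]
        if all((not alpha) or (ch in alpha)
               for ch, alpha in zip(window, motif.positions)):
            hits.append((start + 1, window))
    return hits


class TestScanMotif:
    def test_lir_core_direct_match(self):
        assert scan_motif("AAWEELAA", LIR_CORE) == [(3, "WEEL")]

    def test_xlir_membership_hand_checked(self):
        # E,D,Y,V,V,L each verified against the positional alphabets
        assert scan_motif("EDYVVL", XLIR) == [(1, "EDYVVL")]

    def test_empty_sequence_matches_nothing(self):
        assert scan_motif("", LIR_CORE) == []

    def test_illegal_character_cites_position(self):
        with pytest.raises(SequenceAlphabetError, match="position 3"):
            scan_motif("AAZWEEL", LIR_CORE)

    def test_x_never_satisfies_restricted_positions(self):
        assert scan_motif("AAXEELAA", LIR_CORE) == []
        assert scan_motif("AAWXXLAA", LIR_CORE) == [(3, "WXXL")]  # wildcards

    def test_overlapping_matches_all_reported_ascending(self):
        hits = scan_motif("WWLLLL", LIR_CORE)
        assert hits == [(1, "WWLL"), (2, "WLLL")]

    @pytest.mark.parametrize("motif", [LIR_CORE, XLIR, P62],
                             ids=lambda m: m.name)
    def test_matches_naive_sliding_window_oracle(self, motif):
        rng = np.random.default_rng(42)
        for _ in range(200):
            seq = "".join(rng.choice(list(AMINO_ACIDS + "X"), size=60))
            assert scan_motif(seq, motif) == naive_scan(seq, motif)


class TestPredictDdiTargets:
    def test_definition_single_pair(self):
        assert predict_ddi_targets(
            ["WD40"], [("P1", "PF_X")], {frozenset(("WD40", "PF_X"))}
        ) == {"P1"}

    def test_candidate_without_domains_is_silently_excluded(self):
        assert predict_ddi_targets(["WD40"], [], {frozenset(("WD40", "A"))}) \
            == set()

    def test_matches_brute_force_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        domains = [f"D{i}" for i in range(12)]
        query = ["D0", "D1"]
        candidates = [(f"P{i}", domains[rng.integers(0, 12)])
                      for i in range(20) for _ in range(rng.integers(0, 4))]
        ddi = {frozenset((domains[rng.integers(0, 12)],
                          domains[rng.integers(0, 12)]))
               for _ in range(15)}
        expected = set()
        for pid, dom in candidates:
            for q in query:
                for pair in ddi:
                    if pair == frozenset((q, dom)):
                        expected.add(pid)
        assert predict_ddi_targets(query, candidates, ddi) == expected


def _human(i, direction="up"):
    fc = 2.0 if direction == "up" else -2.0
    return (f"H{i}", DifferentialProtein(f"M{i}", fc, direction, 0.01, 3))


class TestCollectEvidence:
    def _collect(self, proteins, **overrides):
        kwargs = dict(
            sequences={hid: "A" * 30 for hid, _ in proteins},
            interactor_lists={"p62": [], "LC3": [], "ATG16L1": []},
            lir_list=[],
            p62_motif=P62,
            lir_motif=XLIR,
            domains=[("ATG16L1", "PF00400")],
            ddi=set(),
        )
        kwargs.update(overrides)
        return collect_evidence(proteins, **kwargs)

    def test_arn_list_membership_yields_experimental_row(self):
        proteins = [_human(1)]
        ev = self._collect(proteins,
                           interactor_lists={"p62": [], "LC3": ["H1"],
                                             "ATG16L1": []})
        assert [(e.receptor, e.evidence_type) for e in ev] == \
            [("LC3", "experimental")]

    def test_protein_in_no_source_yields_no_rows(self):
        assert self._collect([_human(1)]) == []

    def test_planted_motif_and_ddi_give_two_receptors(self):
        seq = "A" * 10 + "EDYVVL" + "A" * 10
        proteins = [_human(1)]
        ev = self._collect(
            proteins,
            sequences={"H1": seq},
            domains=[("ATG16L1", "PF00400"), ("H1", "PF_X")],
            ddi={frozenset(("PF00400", "PF_X"))})
        kinds = {(e.receptor, e.evidence_type) for e in ev}
        assert ("LC3", "lir_motif") in kinds
        assert ("ATG16L1", "ddi") in kinds

    def test_protein_absent_from_fasta_skips_motifs_only(self):
        proteins = [_human(1)]
        ev = self._collect(proteins, sequences={},
                           interactor_lists={"p62": ["H1"], "LC3": [],
                                             "ATG16L1": []})
        assert [(e.receptor, e.evidence_type) for e in ev] == \
            [("p62", "experimental")]

    def test_adding_an_evidence_source_never_shrinks_target_sets(self):
        proteins = [_human(i) for i in range(6)]
        base = self._collect(proteins,
                             interactor_lists={"p62": ["H0"], "LC3": ["H1"],
                                               "ATG16L1": []})
        more = self._collect(proteins,
                             interactor_lists={"p62": ["H0"], "LC3": ["H1"],
                                               "ATG16L1": []},
                             lir_list=["H2", "H3"])
        for receptor in ("p62", "LC3", "ATG16L1"):
            base_set = {e.human_id for e in base if e.receptor == receptor}
            more_set = {e.human_id for e in more if e.receptor == receptor}
            assert base_set <= more_set


class TestOverlapPartition:
    def test_enumerated_example(self):
        ev = [TargetEvidence("A", "p62", "experimental", ""),
              TargetEvidence("B", "LC3", "experimental", ""),
              TargetEvidence("B", "ATG16L1", "ddi", "x")]
        venn = overlap_partition(ev)
        assert venn.cell("p62") == 1
        assert venn.cell("LC3", "ATG16L1") == 1
        assert sum(venn.cells.values()) == venn.n_targeted == 2
        assert venn.fraction_multi == pytest.approx(0.5)

    def test_empty_evidence_flagged(self):
        venn = overlap_partition([])
        assert venn.empty and venn.fraction_multi == 0.0
        assert sum(venn.cells.values()) == 0

    def test_random_evidence_matches_set_algebra_oracle(self):
        rng = np.random.default_rng(9)
        receptors = ("p62", "LC3", "ATG16L1")
        ev = [TargetEvidence(f"P{rng.integers(0, 50)}",
                             receptors[rng.integers(0, 3)],
                             "experimental", "")
              for _ in range(120)]
        venn = overlap_partition(ev)
        sets = {r: {e.human_id for e in ev if e.receptor == r}
                for r in receptors}
        targeted = set().union(*sets.values())
        # brute-force set algebra for each of the 7 disjoint cells
        for r in range(1, 4):
            for combo in itertools.combinations(receptors, r):
                inside = set(targeted)
                for rec in receptors:
                    if rec in combo:
                        inside &= sets[rec]
                    else:
                        inside -= sets[rec]
                assert venn.cell(*combo) == len(inside)
        assert sum(venn.cells.values()) == len(targeted)
        multi = sum(1 for p in targeted
                    if sum(p in sets[r] for r in receptors) >= 2)
        assert venn.fraction_multi == pytest.approx(multi / len(targeted))
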