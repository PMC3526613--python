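"""Scoring core: base pairing, wMM arithmetic, window search, Tm."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fgarray import (
    HybClass,
    MatchSite,
    ProbeRecord,
    ScoringParams,
    TargetRecord,
    TmParams,
    batch_match,
    best_match,
    compute_tm,
    compute_wmm,
    gc_content,
    pair_bases,
)

from ._oracles import brute_best, nn_tm, window_score

DNA = "ACGT"


def _revcomp(seq):
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


class TestPairBases:
    @pytest.mark.parametrize(
        "probe,sense,match,rna",
        [
            ("A", "A", True, "U"),
            ("C", "C", True, "G"),
            ("G", "G", True, "C"),
            ("T", "T", True, "A"),
            ("G", "A", False, "U"),  # the dG.rU wobble pair
            ("T", "C", False, "G"),  # the dT.rG wobble pair
            ("A", "G", False, "C"),
        ],
    )
    def test_pairing_convention(self, probe, sense, match, rna):
        assert pair_bases(probe, sense) == (match, rna)

    def test_wobble_pairs_get_reduced_weights(self, scoring):
        _, rna = pair_bases("G", "A")
        assert scoring.basepair_weight("G", rna) == 0.7
        _, rna = pair_bases("T", "C")
        assert scoring.basepair_weight("T", rna) == 0.4

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            pair_bases("N", "A")


class TestComputeWmm:
    def test_perfect_match_scores_zero(self, probe20, scoring):
        assert compute_wmm(probe20, MatchSite("t", 1, ()), scoring) == 0.0

    def test_single_terminal_wobble(self, probe20, scoring):
        # dT.rG at probe position 1 of a 20-mer: 0.3 x 0.4
        site = MatchSite("t", 1, ((1, "T", "G"),))
        assert compute_wmm(probe20, site, scoring) == pytest.approx(0.12)

    def test_two_internal_mismatches(self, probe20, scoring):
        # dA.rC and dG.rU at internal positions: 1.2x1.2 + 1.2x0.7
        site = MatchSite("t", 1, ((8, "A", "C"), (12, "G", "U")))
        assert compute_wmm(probe20, site, scoring) == pytest.approx(2.28)

    def test_position_out_of_range_rejected(self, probe20, scoring):
        with pytest.raises(ValueError):
            compute_wmm(probe20, MatchSite("t", 1, ((21, "A", "C"),)), scoring)

    def test_position_weights_match_printed_table(self, scoring):
        L = 20
        weights = [scoring.position_weight(p, L) for p in range(1, L + 1)]
        assert weights[:3] == [0.3, 0.6, 1.0]
        assert weights[-3:] == [1.1, 0.8, 0.3]
        assert set(weights[3:-3]) == {1.2}

    def test_all_single_mismatch_variants_match_enumeration(self, probe20, scoring):
        """Brute-force oracle over every single-mismatch variant."""
        seq = probe20.sequence
        for pos in range(1, len(seq) + 1):
            for sub in DNA:
                if sub == seq[pos - 1]:
                    continue
                variant = seq[: pos - 1] + sub + seq[pos:]
                _, expected = window_score(seq, variant)
                _, rna = pair_bases(seq[pos - 1], sub)
                got = compute_wmm(probe20, MatchSite("t", 1, ((pos, seq[pos - 1], rna),)), scoring)
                assert got == pytest.approx(expected)


class TestBestMatch:
    def test_exact_substring_is_positive_at_its_offset(self, probe20, rng):
        target = TargetRecord("t", "GGGGG" + probe20.sequence + "CCCCC")
        score = best_match(probe20, target)
        assert score.wmm == 0.0
        assert score.predicted_class is HybClass.POSITIVE
        assert score.site.offset == 6
        assert score.site.mismatches == ()

    def test_budget_exhaustion_gives_no_match(self, probe20):
        # unrelated homopolymer: every window has >3 mismatches
        target = TargetRecord("t", "G" * 60)
        score = best_match(probe20, target)
        assert score.predicted_class is HybClass.NO_MATCH
        assert score.site is None

    def test_picks_lowest_wmm_window(self, probe20, scoring):
        seq = probe20.sequence
        # window A: two internal complement substitutions (wMM 2.4)
        worse = seq[:7] + "".join("T" if b == "A" else "A" for b in seq[7]) + seq[8:]
        worse = list(seq)
        worse[7] = {"A": "T", "T": "A", "C": "G", "G": "C"}[seq[7]]
        worse[11] = {"A": "T", "T": "A", "C": "G", "G": "C"}[seq[11]]
        # window B: single 5'-terminal dT.rG (wMM 0.12) needs probe T at pos 1
        probe = ProbeRecord("p", "T" + seq[1:])
        better = list(probe.sequence)
        better[0] = "C"
        target = TargetRecord("t", "".join(worse) + "GG" + "".join(better))
        score = best_match(probe, target, scoring)
        oracle = brute_best(probe.sequence, target.sequence)
        assert score.wmm == pytest.approx(oracle[1])
        assert score.site.offset == oracle[0]

    def test_tie_broken_by_smallest_offset(self, probe20):
        target = TargetRecord("t", probe20.sequence + "AT" + probe20.sequence)
        assert best_match(probe20, target).site.offset == 1

    def test_probe_longer_than_target_rejected(self, probe20):
        with pytest.raises(ValueError):
            best_match(probe20, TargetRecord("t", "ACGT"))

    def test_n_in_target_counts_as_default_mismatch(self, probe20, scoring):
        seq = probe20.sequence
        target = TargetRecord("t", seq[:9] + "N" + seq[10:])
        score = best_match(probe20, target, scoring)
        assert score.wmm == pytest.approx(1.2)  # internal x default weight

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(st.data())
    def test_agrees_with_brute_force_on_random_variants(self, data):
        """Window scan equals exhaustive enumeration on embedded <=2-mismatch
        variants of random probes in random flanks."""
        rng = np.random.default_rng(data.draw(st.integers(0, 2**31 - 1)))
        length = int(rng.integers(18, 29))
        seq = "".join(rng.choice(list(DNA), size=length))
        probe = ProbeRecord("p", seq)
        variant = list(seq)
        for pos in rng.choice(length, size=int(rng.integers(0, 3)), replace=False):
            variant[pos] = rng.choice([b for b in DNA if b != variant[pos]])
        flank = lambda: "".join(rng.choice(list(DNA), size=25))  # noqa: E731
        target = TargetRecord("t", flank() + "".join(variant) + flank())
        score = best_match(probe, target)
        oracle = brute_best(seq, target.sequence)
        assert oracle is not None
        assert score.wmm == pytest.approx(oracle[1])
        assert score.site.offset == oracle[0]

    def test_wmm_strictly_increases_with_added_mismatch(self, probe20, scoring):
        """Additivity: appending a mismatch raises wMM by >= 0.12."""
        base = MatchSite("t", 1, ((8, "A", "C"),))
        more = MatchSite("t", 1, ((8, "A", "C"), (1, "T", "G")))
        low = compute_wmm(probe20, base, scoring)
        high = compute_wmm(probe20, more, scoring)
        assert high >= low + 0.12 - 1e-12


class TestClassBoundaries:
    @pytest.mark.parametrize(
        "wmm,expected",
        [
            (0.0, HybClass.POSITIVE),
            (1.5, HybClass.POSITIVE),
            (1.62, HybClass.POTENTIAL),  # 1.5 + one minimal increment
            (2.5, HybClass.POTENTIAL),
            (2.62, HybClass.NEGATIVE),
        ],
    )
    def test_closed_lower_open_upper(self, scoring, wmm, expected):
        assert scoring.classify(wmm) is expected

    def test_boundary_from_computed_sums(self, scoring):
        # 0.3 + 1.2 computed in floats must still classify POSITIVE
        assert scoring.classify(0.3 + 1.2) is HybClass.POSITIVE


class TestBatchMatch:
    def test_cartesian_order_and_size(self, rng):
        probes = [
            ProbeRecord(f"p{i}", "".join(rng.choice(list(DNA), size=20))) for i in range(3)
        ]
        targets = [
            TargetRecord(f"t{j}", "".join(rng.choice(list(DNA), size=40))) for j in range(4)
        ]
        scores = batch_match(probes, targets)
        assert len(scores) == 12
        assert [(s.probe_name, s.target_name) for s in scores[:4]] == [
            ("p0", "t0"), ("p0", "t1"), ("p0", "t2"), ("p0", "t3"),
        ]
        rerun = batch_match(probes, targets)  # determinism (NaN-safe compare)
        key = lambda s: (s.probe_name, s.target_name, repr(s.wmm), s.predicted_class)  # noqa: E731
        assert [key(s) for s in scores] == [key(s) for s in rerun]

    def test_empty_targets(self, probe20):
        assert batch_match([probe20], []) == []

    def test_group_mismatch_rejected(self, probe20):
        with pytest.raises(ValueError):
            batch_match([probe20], [TargetRecord("t", "A" * 30, array_group="AOB")])


class TestTm:
    def test_matches_independent_nn_evaluator(self):
        for seq in ["AGCGTACGTTAGCCGATAGC", "ACGGCTTAGCAATCGGCATT", "TTGACCGGTAACGTTAGGCA"]:
            assert compute_tm(seq) == pytest.approx(nn_tm(seq), abs=1e-6)

    def test_duplex_symmetry(self):
        seq = "AGCGTACGTTAGCCGATAGC"
        assert compute_tm(seq) == pytest.approx(compute_tm(_revcomp(seq)), abs=1e-6)

    def test_gc_rich_melts_higher_than_at_rich(self):
        assert compute_tm("G" * 10 + "C" * 10) > compute_tm("A" * 10 + "T" * 10)

    def test_ambiguous_base_rejected(self):
        with pytest.raises(ValueError):
            compute_tm("ACGTN")

    def test_concentration_params_validated(self):
        with pytest.raises(ValueError):
            TmParams(oligo_nM=0)


@pytest.mark.parametrize(
    "seq,expected", [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5)]
)
def test_gc_content(seq, expected):
    assert gc_content(seq) == expected


def test_scoring_params_validation():
    with pytest.raises(ValueError):
        ScoringParams(positive_threshold=3.0)
    with pytest.raises(ValueError):
        ScoringParams(internal_weight=0.0)
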