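"""Hairpin discovery: anchors, windows, star inference, the five criteria,
best-hairpin choice and gene deduplication."""

import itertools

import numpy as np
import pytest

from vunmir.fold import FoldResult, fold_builtin
from vunmir.hairpin import (
    CriteriaThresholds,
    HairpinCandidate,
    LocalRead,
    choose_best_hairpin,
    deduplicate_genes,
    enumerate_windows,
    evaluate_criteria,
    infer_star,
    reevaluate,
    select_anchors,
)
from vunmir.preprocess import MappingHit, UniqueRead
from vunmir.seqs import revcomp


def _read(seq, *counts):
    return UniqueRead(seq, np.array(counts))


class TestSelectAnchors:
    def test_total_ten_is_anchor_nine_is_not(self):
        reads = [_read("A" * 20, 10), _read("C" * 20, 9)]
        assert select_anchors(reads) == [reads[0]]

    def test_counts_summed_across_libraries(self):
        r = _read("ACGT" * 5, 6, 5, 0, 0)
        assert select_anchors([r]) == [r]


class TestEnumerateWindows:
    def test_interior_anchor_yields_22_windows_containing_read(self):
        hit = MappingHit("A" * 21, "ref", 200, "+", 0)
        windows = enumerate_windows(hit, 1000)
        assert len(windows) == 22
        assert all(s <= 200 and e >= 221 for s, e in windows)

    def test_window_lengths_follow_100_to_300_step_20(self):
        hit = MappingHit("A" * 21, "ref", 500, "+", 0)
        lengths = {e - s for s, e in enumerate_windows(hit, 2000)}
        assert lengths == set(range(100, 301, 20))

    def test_clipping_near_reference_start_drops_short_windows(self):
        hit = MappingHit("A" * 21, "ref", 50, "+", 0)
        windows = enumerate_windows(hit, 10_000)
        assert all(e - s >= 100 for s, e in windows)
        assert all(s >= 0 for s, _ in windows)
        # right-anchored windows longer than the upstream room are clipped
        # onto the same interval, leaving fewer distinct windows
        assert len(set(windows)) < 22


def _perfect_hairpin(mature, loop_len=10, flank=15, rng=None):
    """flank + mature + loop + revcomp(mature) + flank, with A-flanks that
    cannot pair, and the mature fully duplexed."""
    seq = "A" * flank + mature + "C" * loop_len + revcomp(mature) + "A" * flank
    return seq, (flank, flank + len(mature))


class TestInferStar:
    def test_perfect_stem_star_has_two_nt_overhangs(self):
        mature = "GTGCATGCGTCAGTACGATCG"
        seq, (a, b) = _perfect_hairpin(mature)
        fr = fold_builtin(seq)
        star = infer_star(fr, (a, b))
        assert star is not None
        # star arm starts two in from the duplex end opposite the mature 3'
        pairs = fr.pairs()
        assert star == (pairs[b - 3], pairs[a] + 3)
        lo, hi = star
        assert hi - lo == len(mature)

    def test_mature_inside_terminal_loop_has_no_star(self):
        stem = "GCGCGCATAT"
        seq = stem + "A" * 24 + revcomp(stem)
        fr = fold_builtin(seq)
        assert infer_star(fr, (len(stem) + 2, len(stem) + 22)) is None

    def test_symmetric_internal_loop_spanned_contiguously(self):
        m = "GACGTACGGATCCATGCACGT"
        arm = list(revcomp(m))
        arm[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arm[10]]  # 1x1 loop
        seq = "A" * 12 + m + "CCCCCCCCCC" + "".join(arm) + "A" * 12
        fr = fold_builtin(seq)
        star = infer_star(fr, (12, 12 + len(m)))
        assert star is not None
        lo, hi = star
        assert hi - lo >= len(m) - 2  # one contiguous interval across the loop


@pytest.fixture(scope="module")
def hairpin():
    mature = "GCACGTTGACGTACGGATCCA"
    seq, iv = _perfect_hairpin(mature, flank=20)
    return fold_builtin(seq), iv


class TestEvaluateCriteria:
    """Boundary behaviour of each criterion, using a constructed hairpin
    whose duplex is perfect so single criteria can be toggled."""

    def _stack(self, iv, star, sense_count=80, anti_count=0, outside_count=0):
        reads = [LocalRead(iv[0], iv[1], True, sense_count)]
        if star:
            reads.append(LocalRead(star[0], star[1], True, max(1, sense_count // 10)))
        if anti_count:
            reads.append(LocalRead(iv[0] + 1, iv[1] + 1, False, anti_count))
        if outside_count:
            reads.append(LocalRead(2, 20, True, outside_count))
        return reads

    def test_free_energy_boundary_inclusive(self, hairpin):
        fr, iv = hairpin
        star = infer_star(fr, iv)
        at = FoldResult(fr.structure, -35.0)
        above = FoldResult(fr.structure, -34.9)
        c_at, _ = evaluate_criteria(at, iv, self._stack(iv, star), star_interval=star)
        c_above, _ = evaluate_criteria(above, iv, self._stack(iv, star), star_interval=star)
        assert c_at.delta_g_ok and not c_above.delta_g_ok

    def test_five_duplex_mismatches_fail(self, hairpin):
        fr, iv = hairpin
        thr = CriteriaThresholds()
        assert thr.max_duplex_mismatches == 4
        # a mature shifted into the flank leaves >=5 positions unpaired
        bad_iv = (iv[0] - 6, iv[1] - 6)
        c, _ = evaluate_criteria(fr, bad_iv, self._stack(bad_iv, None))
        assert c.duplex_mismatches >= 5 and not c.duplex_ok

    def test_strand_bias_boundary(self, hairpin):
        fr, iv = hairpin
        star = infer_star(fr, iv)
        c, _ = evaluate_criteria(
            fr, iv, [LocalRead(*iv, True, 80), LocalRead(*iv, False, 20)],
            star_interval=star,
        )
        assert c.strand_bias == pytest.approx(0.80) and c.strand_ok
        c, _ = evaluate_criteria(
            fr, iv, [LocalRead(*iv, True, 79), LocalRead(*iv, False, 21)],
            star_interval=star,
        )
        assert c.strand_bias == pytest.approx(0.79) and not c.strand_ok

    def test_precise_fraction_boundary(self, hairpin):
        fr, iv = hairpin
        star = infer_star(fr, iv)
        c, _ = evaluate_criteria(
            fr, iv, self._stack(iv, None, sense_count=75, outside_count=25),
            star_interval=star,
        )
        assert c.precise_fraction == pytest.approx(0.75) and c.precise_ok
        c, _ = evaluate_criteria(
            fr, iv, self._stack(iv, None, sense_count=74, outside_count=26),
            star_interval=star,
        )
        assert not c.precise_ok

    def test_clean_planted_stack_passes_all_five(self, hairpin):
        fr, iv = hairpin
        star = infer_star(fr, iv)
        c, _ = evaluate_criteria(fr, iv, self._stack(iv, star), star_interval=star)
        assert c.overall, c


def _cand(expr, dg, length, start=0, seq=None, mature="ACGTACGTACGTACGTACGTA"):
    seq = seq or ("A" * 10 + mature + "C" * (length - 10 - len(mature)))
    fr = FoldResult("." * len(seq), dg)
    from vunmir.hairpin import CriteriaResult

    crit = CriteriaResult(dg, 0, 0, 0, 1.0, 1.0, True, True, True, True, True, True)
    return HairpinCandidate(
        "genome", "ref", start, start + length, "+", seq, fr,
        (10, 10 + len(mature)), None, expr, crit,
    )


class TestChooseBestHairpin:
    def test_highest_mature_expression_wins(self):
        a, b = _cand(100, -40, 120), _cand(50, -80, 100)
        assert choose_best_hairpin([a, b]) is a

    def test_free_energy_breaks_expression_tie(self):
        a, b = _cand(100, -40, 120), _cand(100, -36, 100)
        assert choose_best_hairpin([a, b]) is a

    def test_shortest_window_breaks_remaining_tie(self):
        a, b = _cand(100, -40, 160), _cand(100, -40, 120)
        assert choose_best_hairpin([a, b]) is b

    def test_selection_is_a_total_order(self):
        cands = [
            _cand(100, -40, 120, start=0),
            _cand(100, -40, 120, start=5),
            _cand(80, -60, 100, start=2),
            _cand(100, -45, 140, start=1),
        ]
        picks = {
            choose_best_hairpin(list(p)).start
            for p in itertools.permutations(cands)
        }
        assert len(picks) == 1

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            choose_best_hairpin([])


class TestDeduplicateGenes:
    def test_identical_precursors_merge(self):
        a = _cand(100, -40, 120, start=0)
        b = _cand(100, -40, 120, start=0)
        b.reference_set = "ests"
        genes = deduplicate_genes([a, b])
        assert len(genes) == 1

    def test_contained_precursor_merges(self):
        mature = "ACGTACGTACGTACGTACGTA"
        long_seq = "A" * 10 + mature + "C" * 130
        a = _cand(100, -40, 160, seq=long_seq, mature=mature)
        b = _cand(90, -40, 120, seq=long_seq[:120], mature=mature)
        assert len(deduplicate_genes([a, b])) == 1

    def test_same_mature_distinct_loci_stay_distinct(self):
        import numpy as np

        rng = np.random.default_rng(4)
        mature = "ACGTACGTACGTACGTACGTA"
        mk = lambda: "".join(rng.choice(list("ACGT"), size=40)) + mature + "".join(
            rng.choice(list("ACGT"), size=60)
        )
        a = _cand(100, -40, 121, start=0, seq=mk(), mature=mature)
        b = _cand(100, -40, 121, start=5000, seq=mk(), mature=mature)
        a.mature_interval = b.mature_interval = (40, 61)
        genes = deduplicate_genes([a, b])
        assert len(genes) == 2
        assert len({g.mature_seq for g in genes}) == 1


class TestOnPredictions:
    def test_reported_genes_reevaluate_to_pass(self, small_result):
        assert small_result.genes
        for g in small_result.genes:
            assert reevaluate(g.precursor).overall

    def test_tightening_thresholds_never_adds_genes(self, small_result):
        """Monotonicity: stricter criteria can only shrink the passing set."""
        base = small_result.candidates
        tighter = [
            CriteriaThresholds(delta_g_max=-45.0),
            CriteriaThresholds(max_duplex_mismatches=2),
            CriteriaThresholds(min_strand_bias=0.95),
            CriteriaThresholds(min_precise_fraction=0.9),
            CriteriaThresholds(max_asym_bulges=0),
        ]
        for thr in tighter:
            still = [c for c in base if reevaluate(c, thr).overall]
            assert len(still) <= len(base)
            assert set(id(c) for c in still) <= set(id(c) for c in base)
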