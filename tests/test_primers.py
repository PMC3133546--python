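import numpy as np
import pytest

from refscaf.align import reverse_complement
from refscaf.io_formats import SequenceRecord
from refscaf.primers import (
    MAX_PAIR_TM_DIFF,
    PrimerConstraints,
    count_putatively_closed,
    design_gap_primers,
    gc_fraction,
    melting_temperature,
    occurrence_count,
    passes_filters,
    three_prime_complementarity,
)
from refscaf.scaffold import Placement, PseudoContig, build_pseudocontig, order_contigs

from _oracles import naive_occurrence_count


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _pseudo_from_seqs(seqs, n_counts):
    """Hand-build a pseudocontig: seqs joined by N runs."""
    placements = [
        Placement(contig_id=f"c{i}", replicon_id="r", orientation="+",
                  anchor=0, sequence=s)
        for i, s in enumerate(seqs)
    ]
    # anchors consistent with order
    pos = 0
    for i, p in enumerate(placements):
        p.anchor = pos
        pos += p.length + (n_counts[i] if i < len(n_counts) else 0)
    ordered = order_contigs(placements)
    gaps = [(i, n, n) for i, n in enumerate(n_counts)]
    return build_pseudocontig(ordered, gaps)


class TestGcTm:
    @pytest.mark.parametrize("seq,gc", [("GGCC", 1.0), ("ATAT", 0.0), ("ACGT", 0.5)])
    def test_gc_examples(self, seq, gc):
        assert gc_fraction(seq) == gc

    def test_gc_empty_errors(self):
        with pytest.raises(ValueError):
            gc_fraction("")

    def test_tm_hand_value(self):
        # 20-mer with 10 G/C: 64.9 + 41*(10-16.4)/20 = 51.78
        assert melting_temperature("ACGTACGTACGTACGTACGT") == 51.78

    def test_tm_differencing(self):
        # swapping one A for one G in a 20-mer raises Tm by 41/20 = 2.05
        a = "ATATATATATGCGCGCGCGC"  # 10 GC
        b = "GTATATATATGCGCGCGCGC"  # 11 GC
        assert melting_temperature(b) - melting_temperature(a) == pytest.approx(2.05)

    def test_tm_depends_only_on_length_and_gc(self):
        assert melting_temperature("GGGGGAAAAATTTTTCCCCC") == melting_temperature(
            "GCGCGCGCGCATATATATAT"
        )

    def test_tm_length_range(self):
        with pytest.raises(ValueError):
            melting_temperature("ACGTACG")


class TestPassesFilters:
    def test_tm_too_low(self):
        assert not passes_filters("ACGTACGTACGTACGTACGT")  # Tm 51.78 < 57

    def test_homopolymer_rejected(self):
        c = PrimerConstraints(max_homopolymer=4)
        seq = "GCAAAAAGCGCGCATGCGCG"
        assert not passes_filters(seq, c)

    def test_n_rejected(self):
        assert not passes_filters("GCGCATNGCATGCGCGCATG")

    def test_brute_force_window_scan(self, rng):
        # every 18-mer of a 60 bp window: accepted set equals an independent
        # re-check of each constraint
        window = _random_seq(rng, 60)
        c = PrimerConstraints()
        for i in range(len(window) - 17):
            seq = window[i : i + 18]
            n_gc = sum(ch in "GC" for ch in seq)
            tm = round(64.9 + 41 * (n_gc - 16.4) / 18, 2)
            runs = max(
                len(seq) - len("".join(ch for ch in seq)), 0
            )  # placeholder, recompute below
            best_run = 1
            cur = 1
            for a, b in zip(seq, seq[1:]):
                cur = cur + 1 if a == b else 1
                best_run = max(best_run, cur)
            comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
            self_comp = 0
            for j in range(len(seq)):
                r = 0
                while (
                    r < len(seq)
                    and j + r < len(seq)
                    and comp[seq[-1 - r]] == seq[j + r]
                ):
                    r += 1
                self_comp = max(self_comp, r)
            expected = (
                c.min_tm <= tm <= c.max_tm
                and c.min_gc <= 100 * n_gc / 18 <= c.max_gc
                and best_run <= c.max_homopolymer
                and self_comp <= c.max_three_prime_complementarity
            )
            assert passes_filters(seq, c) == expected, seq


class TestOccurrenceCount:
    def test_single_occurrence(self, rng):
        contigs = [SequenceRecord("a", "", _random_seq(rng, 500)),
                   SequenceRecord("b", "", _random_seq(rng, 500))]
        primer = contigs[0].sequence[100:120]
        assert occurrence_count(primer, contigs) == 1

    def test_revcomp_counts(self, rng):
        seq = _random_seq(rng, 300)
        primer = seq[50:70]
        contigs = [SequenceRecord("a", "", seq),
                   SequenceRecord("b", "", reverse_complement(primer) + _random_seq(rng, 100))]
        assert occurrence_count(primer, contigs) == 2

    def test_overlapping_counted(self):
        contigs = [SequenceRecord("a", "", "G" * 30)]
        # 11 overlapping forward occurrences; the revcomp C*20 is absent
        assert occurrence_count("G" * 20, contigs) == 11

    def test_naive_oracle(self, rng):
        contigs = [SequenceRecord(f"c{i}", "", _random_seq(rng, 400)) for i in range(4)]
        for _ in range(20):
            which = int(rng.integers(0, 4))
            start = int(rng.integers(0, 380))
            primer = contigs[which].sequence[start : start + 20]
            assert occurrence_count(primer, contigs) == naive_occurrence_count(
                primer, [c.sequence for c in contigs]
            )


class TestDesignGapPrimers:
    def test_two_contig_gap_seed7(self):
        rng = np.random.default_rng(7)
        seqs = [_random_seq(rng, 2000), _random_seq(rng, 2000)]
        pc = _pseudo_from_seqs(seqs, [300])
        contigs = [SequenceRecord("c0", "", seqs[0]), SequenceRecord("c1", "", seqs[1])]
        pairs = design_gap_primers(pc, contigs)
        assert len(pairs) == 1
        pp = pairs[0]
        c = PrimerConstraints()
        assert pp.product_size <= 300 + 2 * c.window
        assert abs(pp.tm_left - pp.tm_right) <= MAX_PAIR_TM_DIFF
        # coordinates consistent with sequences
        assert pc.sequence[pp.left_start : pp.left_start + len(pp.left_seq)] == pp.left_seq
        site = pc.sequence[pp.right_start - len(pp.right_seq) + 1 : pp.right_start + 1]
        assert reverse_complement(site) == pp.right_seq
        assert pp.product_size == pp.right_start - pp.left_start + 1

    def test_duplicated_flank_reported_unpaired(self):
        rng = np.random.default_rng(9)
        up = _random_seq(rng, 2000)
        down = _random_seq(rng, 2000)
        pc = _pseudo_from_seqs([up, down], [200])
        # a third contig duplicating the upstream flank kills uniqueness
        contigs = [
            SequenceRecord("c0", "", up),
            SequenceRecord("c1", "", down),
            SequenceRecord("dup", "", up[-600:] + _random_seq(rng, 100)),
        ]
        assert design_gap_primers(pc, contigs) == []

    def test_zero_gaps(self, rng):
        pc = _pseudo_from_seqs([_random_seq(rng, 2000)], [])
        assert design_gap_primers(pc, [SequenceRecord("c0", "", pc.sequence)]) == []

    def test_determinism(self):
        rng = np.random.default_rng(21)
        seqs = [_random_seq(rng, 2000), _random_seq(rng, 2000)]
        contigs = [SequenceRecord(f"c{i}", "", s) for i, s in enumerate(seqs)]
        a = design_gap_primers(_pseudo_from_seqs(seqs, [250]), contigs)
        b = design_gap_primers(_pseudo_from_seqs(seqs, [250]), contigs)
        assert a == b

    def test_emitted_primers_pass_all_constraints(self):
        rng = np.random.default_rng(13)
        seqs = [_random_seq(rng, 1500) for _ in range(4)]
        contigs = [SequenceRecord(f"c{i}", "", s) for i, s in enumerate(seqs)]
        pc = _pseudo_from_seqs(seqs, [150, 400, 90])
        c = PrimerConstraints()
        for pp in design_gap_primers(pc, contigs, c):
            assert passes_filters(pp.left_seq, c)
            assert passes_filters(pp.right_seq, c)
            assert occurrence_count(pp.left_seq, contigs) == 1
            assert occurrence_count(pp.right_seq, contigs) == 1
            assert pp.unique


class TestCountPutativelyClosed:
    def _placements(self, ids):
        ps = [Placement(contig_id=c, replicon_id="r", orientation="+", anchor=i,
                        sequence="A", order_index=i) for i, c in enumerate(ids)]
        return ps

    def _pair(self, left, right):
        from refscaf.primers import PrimerPair
        return PrimerPair("g", "A" * 20, "T" * 20, 0, 100, 60, 60, 50, 50, 101,
                          True, left, right)

    def test_adjacent_with_primers(self):
        ps = self._placements(["a", "b"])
        adj = {frozenset(("a", "b"))}
        assert count_putatively_closed(ps, [self._pair("a", "b")], adj) == 1

    def test_adjacent_without_primers(self):
        ps = self._placements(["a", "b"])
        assert count_putatively_closed(ps, [], {frozenset(("a", "b"))}) == 0

    def test_not_adjacent(self):
        ps = self._placements(["a", "b"])
        assert count_putatively_closed(ps, [self._pair("a", "b")], set()) == 0

    def test_set_intersection_oracle(self, rng):
        ids = [f"c{i}" for i in range(10)]
        ps = self._placements(ids)
        # random truth adjacency and random paired subset
        adjacent = {
            frozenset((ids[i], ids[i + 1])) for i in range(9) if rng.random() < 0.6
        }
        paired = [
            self._pair(ids[i], ids[i + 1]) for i in range(9) if rng.random() < 0.5
        ]
        expected = sum(
            1
            for i in range(9)
            if frozenset((ids[i], ids[i + 1])) in adjacent
            and any(p.left_contig == ids[i] and p.right_contig == ids[i + 1] for p in paired)
        )
        assert count_putatively_closed(ps, paired, adjacent) == expected


class TestThreePrimeComplementarity:
    def test_self_hairpin(self):
        # 3' end ...ACGT anneals onto the leading ACGT? complement run ending at 3'
        assert three_prime_complementarity("AAAAAACGT", "AAAAAACGT") >= 3

    def test_no_complement(self):
        assert three_prime_complementarity("AAAA", "AAAA") == 0
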