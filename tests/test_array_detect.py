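import numpy as np
import pytest

from crisprscreen.array_detect import (
    CrisprArray,
    DetectorParams,
    consensus_repeat,
    extend_partial_repeats,
    find_arrays,
    merge_arrays,
)
from crisprscreen.formats import Config, GenomeRecord
from crisprscreen.repeat_cluster import reverse_complement
from crisprscreen.synthetic import random_dna

from oracles import bruteforce_has_array

PARAMS = DetectorParams()


def build_array_genome(rng, repeat, spacers, flank=1000, mutate_copy=None):
    """R S1 R S2 ... R embedded in random flanks; returns (record, start0, seq)."""
    copies = []
    for i in range(len(spacers) + 1):
        c = repeat
        if mutate_copy is not None and i == mutate_copy[0]:
            c = list(repeat)
            for pos, base in mutate_copy[1]:
                c[pos] = base
            c = "".join(c)
        copies.append(c)
    body = copies[0]
    for sp, cp in zip(spacers, copies[1:]):
        body += sp + cp
    seq = random_dna(rng, flank) + body + random_dna(rng, flank)
    return GenomeRecord("g", seq), flank, body


class TestConsensus:
    @pytest.mark.parametrize(
        "repeats,expected",
        [
            (["ACGT", "ACGT", "ACGT"], "ACGT"),  # identity
            (["ACGT", "ACGA", "ACGT"], "ACGT"),  # column majority
            (["ACGT", "ACGA"], "ACGT"),  # tie -> first-occurring base
        ],
    )
    def test_examples(self, repeats, expected):
        assert consensus_repeat(repeats) == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            consensus_repeat([])

    def test_length_deviant_excluded(self):
        # the 10-mer deviates >20% from modal length 4 and must not vote
        assert consensus_repeat(["ACGT", "ACGT", "TTTTTTTTTT"]) == "ACGT"


class TestFindArrays:
    def test_random_sequence_no_arrays(self):
        for seed in range(5):
            g = GenomeRecord("r", random_dna(np.random.default_rng(seed), 1000))
            assert find_arrays(g, PARAMS) == []
            assert not bruteforce_has_array(g.seq, PARAMS)

    def test_planted_array_structure(self, rng):
        repeat = random_dna(rng, 25)
        spacers = [random_dna(rng, 32) for _ in range(3)]
        g, start0, body = build_array_genome(rng, repeat, spacers)
        arrs = find_arrays(g, PARAMS)
        assert len(arrs) == 1
        a = arrs[0]
        assert a.n_repeats == 4 and a.n_spacers == 3
        assert abs(a.start - (start0 + 1)) <= 2
        assert abs(a.end - (start0 + len(body))) <= 2
        # consensus equals the planted repeat up to the <=2 bp boundary slop
        assert repeat in a.consensus_repeat or a.consensus_repeat in repeat
        # every repeat/spacer substring equals the genome slice at its coordinates
        for s, e, sub in a.repeats + a.spacers:
            assert g.slice(s, e) == sub

    def test_mismatched_copy_tolerated(self, rng):
        repeat = random_dna(rng, 25)
        spacers = [random_dna(rng, 32) for _ in range(3)]
        mut = [(5, "A" if repeat[5] != "A" else "C"), (12, "G" if repeat[12] != "G" else "T")]
        g, _, _ = build_array_genome(rng, repeat, spacers, mutate_copy=(1, mut))
        arrs = find_arrays(g, PARAMS)
        assert len(arrs) == 1
        assert arrs[0].n_repeats == 4  # 2/25 = 8% < 20% tolerance

    def test_short_sequence_returns_empty(self):
        g = GenomeRecord("tiny", "ACGT" * 10)
        assert find_arrays(g, PARAMS) == []

    def test_deterministic(self, rng):
        repeat = random_dna(rng, 30)
        spacers = [random_dna(rng, 30) for _ in range(4)]
        g, _, _ = build_array_genome(rng, repeat, spacers)
        a1 = find_arrays(g, PARAMS)
        a2 = find_arrays(g, PARAMS)
        assert a1 == a2

    def test_reverse_complement_mirror(self, rng):
        repeat = random_dna(rng, 25)
        spacers = [random_dna(rng, 32) for _ in range(4)]
        g, _, _ = build_array_genome(rng, repeat, spacers)
        fwd = find_arrays(g, PARAMS)
        rc = find_arrays(GenomeRecord("g_rc", reverse_complement(g.seq)), PARAMS)
        assert len(fwd) == len(rc) == 1
        n = g.length
        # mirrored coordinates (within boundary slop) and RC repeat content
        assert abs(rc[0].start - (n - fwd[0].end + 1)) <= 2
        assert abs(rc[0].end - (n - fwd[0].start + 1)) <= 2
        assert (
            reverse_complement(fwd[0].consensus_repeat) in rc[0].consensus_repeat
            or rc[0].consensus_repeat in reverse_complement(fwd[0].consensus_repeat)
        )


class TestPartialRepeats:
    def make(self, rng, trunc_len):
        repeat = random_dna(rng, 25)
        spacers = [random_dna(rng, 32) for _ in range(3)]
        body = repeat
        for sp in spacers:
            body += sp + repeat
        tail_spacer = random_dna(rng, 32)
        body += tail_spacer + repeat[:trunc_len]
        g = GenomeRecord("g", random_dna(rng, 800) + body + random_dna(rng, 800))
        arrs = find_arrays(g, PARAMS)
        assert len(arrs) == 1
        truth_end = 800 + len(body)
        return g, arrs[0], truth_end

    def test_truncated_15_of_25_extends(self, rng):
        g, arr, truth_end = self.make(rng, 15)
        ext = extend_partial_repeats(arr, g, PARAMS)
        assert ext.partial_3p
        assert abs(ext.end - truth_end) <= 2
        assert ext.n_repeats == arr.n_repeats + 1
        assert ext.n_spacers == arr.n_spacers + 1

    def test_truncated_8_of_25_unchanged(self, rng):
        g, arr, _ = self.make(rng, 8)
        ext = extend_partial_repeats(arr, g, PARAMS)
        assert not ext.partial_3p
        assert ext.end == arr.end

    def test_no_flank_similarity_identity(self, rng):
        repeat = random_dna(rng, 25)
        spacers = [random_dna(rng, 32) for _ in range(3)]
        g, _, _ = build_array_genome(rng, repeat, spacers)
        (arr,) = find_arrays(g, PARAMS)
        assert extend_partial_repeats(arr, g, PARAMS) == arr

    def test_five_prime_partial(self, rng):
        repeat = random_dna(rng, 25)
        spacers = [random_dna(rng, 32) for _ in range(3)]
        body = repeat[-15:] + random_dna(rng, 32) + repeat
        for sp in spacers:
            body += sp + repeat
        g = GenomeRecord("g", random_dna(rng, 800) + body + random_dna(rng, 800))
        (arr,) = find_arrays(g, PARAMS)
        ext = extend_partial_repeats(arr, g, PARAMS)
        assert ext.partial_5p
        assert abs(ext.start - 801) <= 2


def exact_array(seq, start0, repeat, spacers, genome_id="g"):
    """CrisprArray with exact coordinates for a planted R S R S ... R body."""
    repeats, spacer_ivals = [], []
    pos = start0  # 0-based
    for sp in spacers + [None]:
        repeats.append((pos + 1, pos + len(repeat), seq[pos : pos + len(repeat)]))
        pos += len(repeat)
        if sp is not None:
            spacer_ivals.append((pos + 1, pos + len(sp), seq[pos : pos + len(sp)]))
            pos += len(sp)
    return CrisprArray(
        genome_id=genome_id, start=repeats[0][0], end=repeats[-1][1],
        repeats=repeats, spacers=spacer_ivals,
        consensus_repeat=repeat,
    )


class TestMerge:
    def make_pair(self, rng, distance, second_repeat=None):
        """Two planted arrays whose inter-array distance (start2 - end1) is exact."""
        repeat = random_dna(rng, 25)
        r2 = second_repeat or repeat
        spacers1 = [random_dna(rng, 32) for _ in range(3)]
        spacers2 = [random_dna(rng, 32) for _ in range(3)]
        b1 = repeat + "".join(s + repeat for s in spacers1)
        b2 = r2 + "".join(s + r2 for s in spacers2)
        seq = random_dna(rng, 600) + b1 + random_dna(rng, distance - 1) + b2 + random_dna(rng, 600)
        g = GenomeRecord("g", seq)
        arrs = [
            exact_array(seq, 600, repeat, spacers1),
            exact_array(seq, 600 + len(b1) + distance - 1, r2, spacers2),
        ]
        assert arrs[1].start - arrs[0].end == distance
        return g, arrs

    def test_150bp_same_repeat_merges(self, rng):
        g, arrs = self.make_pair(rng, 150)
        merged = merge_arrays(arrs, g, Config())
        assert len(merged) == 1
        assert merged[0].n_repeats == 8

    def test_201bp_not_merged(self, rng):
        g, arrs = self.make_pair(rng, 201)
        assert len(merge_arrays(arrs, g, Config())) == 2

    def test_dissimilar_repeats_not_merged(self, rng):
        g, arrs = self.make_pair(rng, 150, second_repeat=random_dna(rng, 25))
        assert len(merge_arrays(arrs, g, Config())) == 2

    def test_idempotent(self, rng):
        g, arrs = self.make_pair(rng, 150)
        once = merge_arrays(arrs, g, Config())
        assert merge_arrays(once, g, Config()) == once

    def test_long_gap_recorded_as_spacer_or_insertion(self, rng):
        g, arrs = self.make_pair(rng, 150)
        (m,) = merge_arrays(arrs, g, Config())
        # distance 150 -> 149 intervening bases > max spacer: recorded as insertion
        assert m.insertions and m.n_spacers == 6

    def test_merge_boundary_at_exact_gap(self, rng):
        g, arrs = self.make_pair(rng, 200)
        assert len(merge_arrays(arrs, g, Config())) == 1


class TestBruteforceAgreement:
    """The detector and the fixed-period enumerator agree on array presence."""

    def test_random_genomes(self):
        for seed in range(620, 640):
            seq = random_dna(np.random.default_rng(seed), 3000)
            g = GenomeRecord("r", seq)
            assert bool(find_arrays(g, PARAMS)) == bruteforce_has_array(seq, PARAMS)

    def test_planted_genomes(self):
        for seed in range(40, 50):
            rng = np.random.default_rng(seed)
            repeat = random_dna(rng, 25)
            spacers = [random_dna(rng, 32) for _ in range(3)]
            body = repeat + "".join(s + repeat for s in spacers)
            seq = random_dna(rng, 1500) + body + random_dna(rng, 1500)
            g = GenomeRecord("p", seq)
            assert bool(find_arrays(g, PARAMS)) and bruteforce_has_array(seq, PARAMS)
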