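import math

import numpy as np
import pytest

from crisprscreen.false_crispr import (
    ClassifierParams,
    best_tandem_score,
    classify_element,
    detect_simple,
    detect_tandem,
    expand_motif,
    find_real_clusters,
    match_star,
    rescue_distance,
    shannon_entropy,
    STAR_MOTIF,
)
from crisprscreen.repeat_cluster import RepeatCluster, reverse_complement
from crisprscreen.synthetic import random_dna

from oracles import oracle_tandem_score


def mutate_at(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestRescueDistance:
    def test_identical_zero(self, rng):
        r = random_dna(rng, 30)
        assert rescue_distance(r, [r]) == 0

    def test_two_substitutions(self, rng):
        r = random_dna(rng, 30)
        assert rescue_distance(mutate_at(r, [3, 17]), [r]) == 2

    def test_minimum_over_set(self, rng):
        r1, r2 = random_dna(rng, 30), random_dna(rng, 30)
        cand = mutate_at(r1, [1, 5, 9, 13, 17, 21, 25])
        assert rescue_distance(cand, [r2, r1]) == 7

    def test_length_difference_counts(self, rng):
        r = random_dna(rng, 30)
        assert rescue_distance(r + "ACG", [r]) == 3

    def test_empty_real_set_infinite(self):
        assert rescue_distance("ACGTACGT", []) == math.inf


class TestStarMotif:
    def test_all_twelve_instantiations_and_reverse_complements(self):
        instances = expand_motif(STAR_MOTIF)
        assert len(instances) == 12
        for inst in instances:
            assert match_star(inst) and match_star(inst)[0] == (1, "+")
            assert match_star(reverse_complement(inst))[0][1] == "-"

    def test_example_hits(self):
        assert match_star("TGTGTTGGGGCCCC")[0] == (1, "+")
        assert match_star("TATGTTGTGGCCCA")[0] == (1, "+")

    def test_no_hit(self):
        assert match_star("A" * 14) == []

    def test_position_within_context(self, rng):
        inst = expand_motif(STAR_MOTIF)[0]
        seq = "A" * 37 + inst + "A" * 20
        assert (38, "+") in match_star(seq)


class TestDetectTandem:
    def test_clean_five_mer_tandem(self):
        call = detect_tandem("ACGTA" * 10)
        assert call is not None
        assert call.period == 5
        assert call.copies == pytest.approx(10.0, abs=0.3)
        assert call.coverage == pytest.approx(1.0, abs=0.05)
        assert call.unit in ("ACGTA", "CGTAA", "GTAAC", "TAACG", "AACGT")

    def test_crispr_array_is_not_tandem(self, rng):
        repeat = random_dna(rng, 25)
        spacers = [random_dna(rng, 32) for _ in range(3)]
        region = repeat + "".join(s + repeat for s in spacers)
        assert detect_tandem(region) is None

    def test_random_region_no_call(self):
        for seed in (7, 8, 9):
            region = random_dna(np.random.default_rng(seed), 300)
            assert detect_tandem(region) is None

    def test_mutated_tandem_still_called(self, rng):
        unit = random_dna(rng, 20)
        region = "".join(mutate_at(unit, [int(rng.integers(20))]) for _ in range(8))
        call = detect_tandem(region)
        # the best-scoring period is the planted unit or a multiple of it (two
        # long near-identical copies can outscore many short mutated copies)
        assert call is not None and call.period % 20 == 0

    @pytest.mark.parametrize("unit_len,copies", [(5, 20), (11, 9), (20, 8), (33, 6)])
    def test_score_equals_exhaustive_oracle(self, rng, unit_len, copies):
        """On regions short enough for the exhaustive period scan, the
        detector's best score equals an independent aligner's exhaustive score."""
        unit = random_dna(rng, unit_len)
        region = unit * copies
        assert len(region) <= 200
        assert best_tandem_score(region) == oracle_tandem_score(region)

    def test_score_matches_oracle_with_mutations(self, rng):
        unit = random_dna(rng, 15)
        region = "".join(mutate_at(unit, [int(rng.integers(15))]) for _ in range(10))
        assert best_tandem_score(region) == oracle_tandem_score(region)

    def test_score_matches_oracle_on_random(self, rng):
        region = random_dna(rng, 120)
        assert best_tandem_score(region) == oracle_tandem_score(region)


class TestDetectSimple:
    def test_gccgtt_twelve_copies(self):
        call = detect_simple("GCCGTT" * 12)
        assert call is not None and call.trigger == "short_unit_tandem"
        assert len(call.unit) == 6 and call.copies == pytest.approx(12, abs=0.5)

    def test_a_rich_region(self, rng):
        # 43% adenine, remainder random: triggers the mononucleotide criterion
        bases = ["A"] * 129 + [random_dna(rng, 1) for _ in range(171)]
        rng.shuffle(bases)
        region = "".join(bases)
        frac = region.count("A") / len(region)
        if frac >= 0.40:  # construction guarantees >= 43% minus random A draws
            call = detect_simple(region)
            assert call is not None and call.trigger == "mono_frac"

    def test_balanced_random_none(self):
        region = random_dna(np.random.default_rng(11), 300)
        counts = {b: region.count(b) for b in "ACGT"}
        assert max(counts.values()) / 300 < 0.40
        assert shannon_entropy(region) > 1.5
        assert detect_simple(region) is None

    def test_low_entropy_trigger(self):
        region = ("ACACACAAAC" * 30)[:290]  # two-letter alphabet, entropy < 1.5
        call = detect_simple(region)
        assert call is not None


class TestFindRealClusters:
    def cluster(self, cid, keys):
        return RepeatCluster(cluster_id=cid, representative="ACGT" * 7,
                             members=[(k, "ACGT" * 7) for k in keys])

    def test_cas_near_member_propagates(self):
        clusters = [self.cluster("C1", ["a1", "a2"])]
        real, false = find_real_clusters(clusters, {"a1": "CO_LOCATED", "a2": "ORPHAN"})
        assert real == {"C1"} and false == set()

    def test_no_cas_near_member(self):
        clusters = [self.cluster("C1", ["a1", "a2"])]
        real, false = find_real_clusters(clusters, {"a1": "ISOLATED_REMOTE", "a2": "ORPHAN"})
        assert false == {"C1"}

    def test_empty(self):
        assert find_real_clusters([], {}) == (set(), set())


class TestClassifyCascade:
    def classify(self, region, consensus, cluster_real=False, colocation="ORPHAN",
                 real_repeats=(), **kw):
        return classify_element(
            array_id="a1", region_sequence=region, consensus_repeat=consensus,
            cluster_id="C1", cluster_is_real=cluster_real, colocation_label=colocation,
            diversity_status="NOT_DIVERSE", real_repeats=list(real_repeats), **kw,
        )

    def test_cluster_real_wins(self, rng):
        region = random_dna(rng, 200)
        cls = self.classify(region, region[:30], cluster_real=True, colocation="CO_LOCATED")
        assert cls.label == "REAL" and cls.evidence.cas_near

    def test_rescue_below_limit_is_real(self, rng):
        real = random_dna(rng, 30)
        cand = mutate_at(real, [2, 9])
        cls = self.classify(random_dna(rng, 200), cand, real_repeats=[real])
        assert cls.label == "REAL" and cls.evidence.rescue_distance == 2

    def test_rescue_at_limit_not_real(self, rng):
        real = random_dna(rng, 30)
        cand = mutate_at(real, [2, 6, 10, 14, 18])  # exactly 5 mismatches
        cls = self.classify(random_dna(rng, 200), cand, real_repeats=[real])
        assert cls.label != "REAL" and cls.evidence.rescue_distance == 5

    def test_star_element(self, rng):
        inst = expand_motif(STAR_MOTIF)[3]
        unit = random_dna(rng, 12) + inst + random_dna(rng, 14)
        linker = random_dna(rng, 30)
        region = unit + "".join(linker + unit for _ in range(4))
        cls = self.classify(region, unit)
        assert cls.label == "STAR" and cls.evidence.star_hits

    def test_tandem_element(self, rng):
        unit = random_dna(rng, 60)
        cls = self.classify(unit * 6, unit[:42])
        assert cls.label == "TANDEM"
        assert cls.evidence.tandem_call.period == 60

    def test_simple_element(self, rng):
        region = mutate_at("A" * 290, list(range(0, 290, 20)))
        cls = self.classify(region, "A" * 21)
        assert cls.label == "SIMPLE"

    def test_unknown_fallthrough(self, rng):
        region = random_dna(rng, 250)
        cls = self.classify(region, region[:25])
        assert cls.label == "UNKNOWN"

    def test_adding_cas_only_moves_toward_real(self, rng):
        """Flipping a cluster to cas-near can only change labels to REAL."""
        unit = random_dna(rng, 60)
        without = self.classify(unit * 6, unit[:42], cluster_real=False)
        with_cas = self.classify(unit * 6, unit[:42], cluster_real=True, colocation="CO_LOCATED")
        assert without.label == "TANDEM" and with_cas.label == "REAL"

    def test_strict_diversity_demotes_rescued_orphan(self, rng):
        real = random_dna(rng, 30)
        cand = mutate_at(real, [4])
        loose = self.classify(random_dna(rng, 200), cand, real_repeats=[real])
        strict = self.classify(random_dna(rng, 200), cand, real_repeats=[real],
                               strict_diversity=True)
        assert loose.label == "REAL" and strict.label != "REAL"
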