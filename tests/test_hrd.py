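"""HRD scar components against worked examples and brute-force oracles on
randomized segment sets."""

import itertools

import numpy as np
import pytest

from ecpdx.core import AllelicSegment, mini_genome
from ecpdx.hrd import (
    compute_hrd_loh,
    compute_lst,
    compute_ntai,
    score_hrd,
)

MB = 1_000_000


def seg(chrom, start_mb, end_mb, total, minor):
    return AllelicSegment(str(chrom), int(start_mb * MB) + 1, int(end_mb * MB),
                          total, minor)


# ---------------------------------------------------------------------------
# brute-force oracles: direct enumeration of merged runs from the definitions

def _runs(segs, pred):
    """Merged runs of consecutive segments satisfying pred, as
    (start, end, covered) tuples, per chromosome-sorted input."""
    out = []
    for flag, grp in itertools.groupby(segs, key=pred):
        grp = list(grp)
        if flag:
            out.append((grp[0].start_bp, grp[-1].end_bp,
                        sum(s.length_bp for s in grp)))
    return out


def oracle_hrd_loh(segments, genome):
    n = 0
    for c in genome.chromosomes:
        segs = sorted([s for s in segments if s.chrom == c.name],
                      key=lambda s: s.start_bp)
        for start, end, covered in _runs(
                segs, lambda s: s.minor_cn == 0 and s.total_cn >= 1):
            if covered > 15 * MB and (end - start + 1) < 0.9 * c.length_bp:
                n += 1
    return n


def oracle_ntai(segments, genome):
    n = 0
    for c in genome.chromosomes:
        segs = sorted([s for s in segments if s.chrom == c.name],
                      key=lambda s: s.start_bp)
        if not segs:
            continue
        mid = c.centromere_mid_bp
        for start, end, _ in _runs(segs, lambda s: 2 * s.minor_cn != s.total_cn):
            touches = start == segs[0].start_bp or end == segs[-1].end_bp
            if touches and not (start <= mid <= end):
                n += 1
    return n


def oracle_lst(segments, genome):
    n = 0
    for c in genome.chromosomes:
        segs = sorted([s for s in segments if s.chrom == c.name],
                      key=lambda s: s.start_bp)
        mid = c.centromere_mid_bp
        for lo, hi in ((1, mid), (mid + 1, c.length_bp)):
            pieces = []
            for s in segs:
                a, b = max(s.start_bp, lo), min(s.end_bp, hi)
                if b >= a:
                    pieces.append([s.state, b - a + 1])
            # smooth: drop the smallest sub-3Mb piece, re-merge, repeat
            def merge(ps):
                out = []
                for st, ln in ps:
                    if out and out[-1][0] == st:
                        out[-1][1] += ln
                    else:
                        out.append([st, ln])
                return out
            pieces = merge(pieces)
            while True:
                small = [p for p in pieces if p[1] < 3 * MB]
                if not small or len(pieces) <= 1:
                    break
                pieces.remove(min(small, key=lambda p: p[1]))
                pieces = merge(pieces)
            for (sa, la), (sb, lb) in zip(pieces, pieces[1:]):
                if sa != sb and la >= 10 * MB and lb >= 10 * MB:
                    n += 1
    return n


# ---------------------------------------------------------------------------

class TestHrdLoh:
    def test_diploid_heterozygous_genome_scores_zero(self, small_genome):
        segs = [seg(c.name, 0, 200, 2, 1) for c in small_genome.chromosomes]
        assert compute_hrd_loh(segs, small_genome) == 0

    def test_only_the_20mb_loh_counts(self, small_genome):
        segs = [seg(1, 0, 60, 2, 1), seg(1, 60, 80, 2, 0),    # 20 Mb LOH
                seg(1, 80, 150, 2, 1), seg(1, 150, 160, 1, 0),  # 10 Mb LOH
                seg(1, 160, 200, 2, 1)]
        assert compute_hrd_loh(segs, small_genome) == 1

    def test_whole_chromosome_loh_excluded(self, small_genome):
        segs = [seg(1, 0, 200, 2, 0)]
        assert compute_hrd_loh(segs, small_genome) == 0

    def test_split_loh_run_still_counts_once(self, small_genome):
        whole = [seg(1, 0, 60, 2, 1), seg(1, 60, 90, 1, 0), seg(1, 90, 200, 2, 1)]
        split = [seg(1, 0, 60, 2, 1), seg(1, 60, 75, 1, 0), seg(1, 75, 90, 1, 0),
                 seg(1, 90, 200, 2, 1)]
        assert (compute_hrd_loh(whole, small_genome)
                == compute_hrd_loh(split, small_genome) == 1)


class TestLst:
    def test_single_state_arm_scores_zero(self, small_genome):
        segs = [seg(1, 0, 200, 3, 1)]
        assert compute_lst(segs, small_genome) == 0

    def test_small_interruption_is_smoothed_away(self, small_genome):
        # q arm (100-200 Mb): A(30) | B(2) | A(rest) -> merges to one state
        segs = [seg(1, 0, 100, 2, 1), seg(1, 100, 130, 3, 1),
                seg(1, 130, 132, 2, 1), seg(1, 132, 200, 3, 1)]
        assert compute_lst(segs, small_genome) == 0

    def test_three_large_states_give_two_transitions(self, small_genome):
        # q arm: A(30) | B(20) | C(50)
        segs = [seg(1, 0, 100, 2, 1), seg(1, 100, 130, 3, 1),
                seg(1, 130, 150, 2, 0), seg(1, 150, 200, 4, 1)]
        assert compute_lst(segs, small_genome) == 2


class TestNtai:
    def test_balanced_genome_scores_zero(self, small_genome):
        segs = [seg(c.name, 0, 200, 2, 1) for c in small_genome.chromosomes]
        assert compute_ntai(segs, small_genome) == 0

    def test_telomeric_imbalance_short_of_centromere_counts(self, small_genome):
        segs = [seg(1, 0, 10, 3, 1), seg(1, 10, 200, 2, 1)]
        assert compute_ntai(segs, small_genome) == 1

    def test_whole_chromosome_imbalance_crosses_centromere(self, small_genome):
        segs = [seg(1, 0, 200, 3, 1)]
        assert compute_ntai(segs, small_genome) == 0


class TestScoreHrd:
    def test_diploid_genome_is_all_zero_and_negative(self, small_genome):
        segs = [seg(c.name, 0, 200, 2, 1) for c in small_genome.chromosomes]
        s = score_hrd(segs, small_genome)
        assert (s.ntai, s.lst, s.hrd_loh, s.sum, s.hrd_call) == (0, 0, 0, 0, False)

    def test_qualifying_loh_run_adds_exactly_one_to_the_sum(self, small_genome):
        # extending a borderline 15 Mb LOH run past the threshold changes
        # hrd_loh (and hence the sum) by exactly 1, leaving LST/NtAI untouched
        base = [seg(1, 0, 80, 2, 1), seg(1, 80, 95, 1, 0), seg(1, 95, 200, 2, 1)]
        more = [seg(1, 0, 80, 2, 1), seg(1, 80, 97, 1, 0), seg(1, 97, 200, 2, 1)]
        s0, s1 = score_hrd(base, small_genome), score_hrd(more, small_genome)
        assert (s1.ntai, s1.lst) == (s0.ntai, s0.lst)
        assert s1.hrd_loh == s0.hrd_loh + 1
        assert s1.sum == s0.sum + 1


STATES = [(2, 1), (2, 0), (1, 0), (3, 1), (4, 2), (3, 0), (4, 1)]


def _random_segments(genome, rng):
    segs = []
    for c in genome.chromosomes:
        n = int(rng.integers(1, 9))
        cuts = np.sort(rng.choice(np.arange(1, c.length_bp // MB), size=n - 1,
                                  replace=False)) * MB if n > 1 else np.array([], dtype=int)
        bounds = [0, *cuts.tolist(), c.length_bp]
        for a, b in zip(bounds, bounds[1:]):
            t, m = STATES[int(rng.integers(len(STATES)))]
            segs.append(AllelicSegment(c.name, a + 1, b, t, m))
    return segs


@pytest.mark.parametrize("component,oracle", [
    (compute_hrd_loh, oracle_hrd_loh),
    (compute_lst, oracle_lst),
    (compute_ntai, oracle_ntai),
])
def test_components_match_brute_force_on_random_segment_sets(component, oracle,
                                                             small_genome):
    rng = np.random.default_rng(2024)
    for _ in range(200):
        segs = _random_segments(small_genome, rng)
        assert component(segs, small_genome) == oracle(segs, small_genome)


def test_components_invariant_to_order_and_splitting(small_genome):
    rng = np.random.default_rng(7)
    for _ in range(20):
        segs = _random_segments(small_genome, rng)
        shuffled = list(segs)
        rng.shuffle(shuffled)
        split = []
        for s in segs:
            if s.length_bp > 2 * MB:
                mid = s.start_bp + s.length_bp // 2
                split.append(AllelicSegment(s.chrom, s.start_bp, mid,
                                            s.total_cn, s.minor_cn))
                split.append(AllelicSegment(s.chrom, mid + 1, s.end_bp,
                                            s.total_cn, s.minor_cn))
            else:
                split.append(s)
        for fn in (compute_hrd_loh, compute_lst, compute_ntai):
            assert fn(segs, small_genome) == fn(shuffled, small_genome)
            assert fn(segs, small_genome) == fn(split, small_genome)
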