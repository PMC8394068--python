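"""Sliding-window scan: scoring, merging, calibration, circular handling."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stescan import (
    DEFAULT_QUERY,
    DEFAULT_SCHEME,
    STE_MOTIF,
    GenomeRecord,
    MotifQuery,
    ScoringScheme,
    calibrate_threshold,
    generate_background,
    merge_hits,
    min_matches_for_percent,
    plant_motif_copy,
    reverse_complement,
    scan_genome,
    scan_sequence,
    window_score,
)
from stescan.scan import MotifHit

from .conftest import RM_FREQS

W = DEFAULT_QUERY.W


def brute_force_hits(target, motif=STE_MOTIF, k=16):
    """Independent oracle: plain Hamming count of every window."""
    out = []
    for i in range(len(target) - len(motif) + 1):
        window = target[i : i + len(motif)]
        m = sum(a == b and a in "ACGT" for a, b in zip(window, motif))
        if m >= k:
            out.append((i, m))
    return out


class TestWindowScore:
    def test_motif_vs_itself(self):
        assert window_score(STE_MOTIF, DEFAULT_QUERY) == (22, 110)

    def test_threshold_score(self):
        seq = plant_motif_copy("T" * W, DEFAULT_QUERY, 16, "+", 0, seed=0)
        assert window_score(seq, DEFAULT_QUERY) == (16, 56)

    def test_all_ambiguous(self):
        assert window_score("N" * W, DEFAULT_QUERY) == (0, -88)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            window_score("ACGT", DEFAULT_QUERY)

    def test_score_identity_equivalence(self):
        """With (+5, -4) over 22 bp, S >= 56 iff m >= 16, for every m."""
        for m in range(W + 1):
            S = DEFAULT_SCHEME.score(m, W)
            assert (S >= 56) == (m >= 16)
        assert DEFAULT_SCHEME.min_identities(W) == 16


class TestMinMatchesForPercent:
    @pytest.mark.parametrize(
        "pct,expected",
        [(72.7, 16), (77.3, 17), (81.8, 18), (95.5, 21), (100.0, 22), (0.0, 0)],
    )
    def test_reported_percent_to_identity_count(self, pct, expected):
        assert min_matches_for_percent(pct, W) == expected

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            min_matches_for_percent(101, W)


class TestScanSequence:
    def test_planted_copy_found(self):
        bg = generate_background(100, RM_FREQS, seed=4)
        target = plant_motif_copy(bg, DEFAULT_QUERY, 22, "+", 39, seed=5)
        hits = scan_sequence(target)
        assert [(h.start, h.strand, h.m) for h in hits] == [(39, "+", 22)]

    def test_short_target(self):
        assert scan_sequence("ACGT") == []

    def test_strand_symmetry(self):
        bg = generate_background(300, RM_FREQS, seed=6)
        target = plant_motif_copy(bg, DEFAULT_QUERY, 19, "-", 120, seed=7)
        fwd_of_rc = scan_sequence(reverse_complement(target), strand_mode="forward")
        minus = [h for h in scan_sequence(target) if h.strand == "-"]
        n = len(target)
        assert [(n - h.start - W, h.m) for h in minus] == [
            (h.start, h.m) for h in fwd_of_rc
        ]

    @settings(max_examples=25, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_agrees_with_brute_force(self, seed):
        """Vectorized scan equals the all-windows Hamming oracle on 1 kb."""
        target = generate_background(1000, (0.3, 0.2, 0.2, 0.3), seed=seed)
        target = plant_motif_copy(target, DEFAULT_QUERY, 17, "+", seed % 900, seed=seed)
        got = [
            (h.start, h.m)
            for h in scan_sequence(target, strand_mode="forward", merge=False)
        ]
        assert got == brute_force_hits(target)

    def test_self_hit_at_any_threshold(self):
        target = "TTTT" + STE_MOTIF + "GGGG"
        for ts in (0, 56, 110):
            hits = scan_sequence(target, scheme=ScoringScheme(Ts=ts), strand_mode="forward")
            assert any(h.start == 4 and h.m == 22 for h in hits)


class TestMergeHits:
    def mk(self, start, m, strand="+"):
        return MotifHit("t", start, strand, m, DEFAULT_SCHEME.score(m, W), 100 * m / W, W)

    def test_adjacent_windows_merge(self):
        merged = merge_hits([self.mk(0, 16), self.mk(1, 17)])
        assert [(h.start, h.m) for h in merged] == [(1, 17)]

    def test_distant_windows_stay(self):
        merged = merge_hits([self.mk(0, 16), self.mk(50, 16)])
        assert len(merged) == 2

    def test_tie_prefers_leftmost(self):
        merged = merge_hits([self.mk(0, 16), self.mk(1, 16)])
        assert [(h.start,) for h in merged] == [(0,)]

    def test_strands_do_not_merge(self):
        merged = merge_hits([self.mk(0, 16), self.mk(1, 16, "-")])
        assert len(merged) == 2

    def test_three_planted_copies(self):
        bg = generate_background(1000, RM_FREQS, seed=8)
        target = bg
        for i, m in enumerate([22, 21, 16]):
            target = plant_motif_copy(target, DEFAULT_QUERY, m, "+", 100 + 200 * i, seed=i)
        hits = scan_sequence(target, strand_mode="forward")
        assert [(h.start, h.m) for h in hits] == [(100, 22), (300, 21), (500, 16)]


class TestScanGenome:
    def test_hit_in_rrna_antisense(self, simple_genome):
        genome, _ = simple_genome
        rrna = next(f for f in genome.features if f.kind == "rRNA")
        s, _ = rrna.interval
        seq = list(genome.sequence)
        seq[s + 10 : s + 10 + W] = reverse_complement(STE_MOTIF)
        g2 = GenomeRecord(genome.id, "".join(seq), True, genome.features)
        hits = scan_genome(g2)
        target = [h for h in hits if h.start == s + 10 and h.strand == "-"]
        assert len(target) == 1
        assert target[0].context.startswith("in_feature:rRNA")
        assert "antisense" in target[0].context

    def test_circular_hit_reported_once(self):
        seq = STE_MOTIF[10:] + generate_background(400, RM_FREQS, seed=10) + STE_MOTIF[:10]
        g = GenomeRecord("wrap", seq, True, [])
        hits = scan_genome(g, strand_mode="forward", annotate=False)
        wrap_hits = [h for h in hits if h.start == len(seq) - 10]
        assert len(wrap_hits) == 1
        assert wrap_hits[0].wrapped

    def test_no_hits_at_max_threshold_on_random(self):
        g = GenomeRecord("r", generate_background(5000, (0.25, 0.25, 0.25, 0.25), seed=11), True, [])
        assert scan_genome(g, scheme=ScoringScheme(Ts=110), annotate=False) == []


class TestCalibration:
    @staticmethod
    def reference(ms, seed):
        seq = generate_background(2000, RM_FREQS, seed=seed)
        for i, m in enumerate(ms):
            seq = plant_motif_copy(seq, DEFAULT_QUERY, m, "+", 100 + 250 * i, seed=seed * 7 + i)
        return seq

    def test_published_threshold_recovered(self):
        """Copies at m=(22,21,16), (17), (16) pin the threshold to 56."""
        refs = [
            (self.reference([22, 21, 16], 1), 3),
            (self.reference([17], 2), 1),
            (self.reference([16], 3), 1),
        ]
        ts, curve = calibrate_threshold(DEFAULT_QUERY, refs)
        assert ts == 56

    def test_single_exact_copy_gives_max_threshold(self):
        refs = [(self.reference([22], 4), 1)]
        ts, _ = calibrate_threshold(DEFAULT_QUERY, refs)
        assert ts == 110

    def test_infeasible_expectation(self):
        """A single-window reference can never yield two hits."""
        with pytest.raises(ValueError, match="feasible"):
            calibrate_threshold(DEFAULT_QUERY, [(STE_MOTIF, 2)], strand_mode="forward")

    def test_curve_monotone_non_increasing(self):
        """Lower thresholds admit more matches: merged-hit counts are
        non-increasing in T over the meaningful (non-negative) range.
        Below T=0 nearly every window is accepted and overlap-merging
        coalesces clusters, so counts there are not informative."""
        refs = [(self.reference([22, 18, 16], 6), 3)]
        _, curve = calibrate_threshold(DEFAULT_QUERY, refs)
        counts = [curve[t][0] for t in sorted(curve) if t >= 0]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_raw_window_count_monotone_everywhere(self):
        """Unmerged accepted-window counts are rigorously non-increasing in T."""
        seq = self.reference([22, 18, 16], 6)
        counts = [
            len(scan_sequence(seq, scheme=ScoringScheme(Ts=t), merge=False))
            for t in range(-88, 111)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))
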