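"""Calibrated sliding-window motif scan (dotplot-style window scoring).

A query motif of length W is slid over a target; each window is scored
ungapped with an exact match/mismatch scheme (no ambiguous matches: any
non-ACGT base mismatches everything). Windows at or above the acceptance
threshold Ts are kept, and overlapping accepted windows on the same strand
are merged into a single hit represented by their best-scoring window.

With the default scheme (+5 match, -4 mismatch, W = 22) the score of a
window with m identities is S = 9m - 88, so the published acceptance
threshold Ts = 56 is exactly the 16-of-22 (72.7%) identity boundary.

The threshold itself can be re-derived from labelled reference sequences
with :func:`calibrate_threshold`, which sweeps every integer threshold and
returns the largest one at which every reference yields exactly its
expected number of merged hits (the conservative end of the feasible band).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from ._seq import encode, window_identities

#: the functional 22 bp sperm transmission element from the
#: Mytilus galloprovincialis recently-masculinized control region
STE_MOTIF = "CCATAAATGTTTGAAAATAAGG"


@dataclass(frozen=True)
class MotifQuery:
    """A query motif; the scan window length W equals the motif length."""

    sequence: str
    name: str = "STE"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq or any(b not in "ACGT" for b in seq):
            raise ValueError("motif must be a non-empty string over A/C/G/T")
        object.__setattr__(self, "sequence", seq)

    @property
    def W(self) -> int:
        return len(self.sequence)

    @property
    def codes(self) -> np.ndarray:
        return encode(self.sequence)


#: the default query: the known STE motif
DEFAULT_QUERY = MotifQuery(STE_MOTIF)


@dataclass(frozen=True)
class ScoringScheme:
    match_score: int = 5
    mismatch_score: int = -4
    Ts: int = 56

    def __post_init__(self) -> None:
        if not (self.match_score > 0 > self.mismatch_score):
            raise ValueError("need match_score > 0 > mismatch_score")

    def score(self, m: int, W: int) -> int:
        return m * self.match_score + (W - m) * self.mismatch_score

    def min_identities(self, W: int) -> int:
        """Smallest identity count m with score(m) >= Ts."""
        span = self.match_score - self.mismatch_score
        k = math.ceil((self.Ts - W * self.mismatch_score) / span)
        return max(0, k)


DEFAULT_SCHEME = ScoringScheme()


@dataclass
class MotifHit:
    """One accepted (or merged) window on the forward coordinate axis."""

    target_id: str
    start: int
    strand: str
    m: int
    score: int
    pct: float
    W: int
    context: str = ""
    wrapped: bool = False

    @property
    def end(self) -> int:
        return self.start + self.W


def window_score(window: str, motif: MotifQuery, scheme: ScoringScheme = DEFAULT_SCHEME) -> tuple[int, int]:
    """Identity count and score of one window against the motif.

    Only identical unambiguous bases count as matches; N (or any other
    non-ACGT code) always mismatches.
    """
    if len(window) != motif.W:
        raise ValueError(f"window length {len(window)} != motif length {motif.W}")
    m = int(window_identities(encode(window), motif.codes)[0])
    return m, scheme.score(m, motif.W)


def min_matches_for_percent(pct: float, W: int) -> int:
    """Smallest identity count k whose percent identity reaches ``pct``.

    A half-tenth tolerance absorbs one-decimal rounding of reported
    percentages, e.g. 72.7% over 22 bp maps to k = 16 (16/22 = 72.73%).
    """
    if not 0 <= pct <= 100:
        raise ValueError("percent must be in [0, 100]")
    k = math.ceil((pct - 0.05) * W / 100)
    return min(max(k, 0), W)


def scan_sequence(
    target: str,
    motif: MotifQuery = DEFAULT_QUERY,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    strand_mode: str = "both",
    target_id: str = "",
    merge: bool = True,
) -> list[MotifHit]:
    """Scan a linear target; report windows scoring >= Ts, merged by default.

    Reverse-strand hits come from scanning the reverse complement and are
    mapped back to forward-axis start positions.
    """
    if strand_mode not in ("forward", "both"):
        raise ValueError("strand_mode must be 'forward' or 'both'")
    codes = encode(target)
    W = motif.W
    k = scheme.min_identities(W)
    raw: list[MotifHit] = []
    n = codes.size

    def _collect(search_codes: np.ndarray, strand: str) -> None:
        ident = window_identities(search_codes, motif.codes)
        for pos in np.nonzero(ident >= k)[0]:
            m = int(ident[pos])
            start = int(pos) if strand == "+" else n - int(pos) - W
            raw.append(
                MotifHit(
                    target_id=target_id,
                    start=start,
                    strand=strand,
                    m=m,
                    score=scheme.score(m, W),
                    pct=round(100.0 * m / W, 1),
                    W=W,
                )
            )

    _collect(codes, "+")
    if strand_mode == "both":
        from ._seq import revcomp_codes

        _collect(revcomp_codes(codes), "-")
    raw.sort(key=lambda h: (h.start, h.strand))
    return merge_hits(raw) if merge else raw


def merge_hits(raw_windows: Sequence[MotifHit]) -> list[MotifHit]:
    """Collapse overlapping accepted windows on the same strand.

    Each overlap cluster is represented by its maximum-score window
    (leftmost on ties); non-overlapping windows stay distinct.
    """
    merged: list[MotifHit] = []
    open_clusters: dict[str, MotifHit] = {}
    cluster_end: dict[str, int] = {}
    for hit in sorted(raw_windows, key=lambda h: (h.start, h.strand)):
        best = open_clusters.get(hit.strand)
        if best is not None and hit.start < cluster_end[hit.strand]:
            cluster_end[hit.strand] = max(cluster_end[hit.strand], hit.end)
            if hit.score > best.score:
                open_clusters[hit.strand] = hit
        else:
            if best is not None:
                merged.append(best)
            open_clusters[hit.strand] = hit
            cluster_end[hit.strand] = hit.end
    merged.extend(open_clusters.values())
    merged.sort(key=lambda h: (h.start, h.strand))
    return merged


def scan_genome(
    genome,
    motif: MotifQuery = DEFAULT_QUERY,
    scheme: ScoringScheme = DEFAULT_SCHEME,
    strand_mode: str = "both",
    annotate: bool = True,
) -> list[MotifHit]:
    """Scan a whole genome on both strands, handling circular wrap.

    For circular records the first W-1 bases are appended so windows that
    span the origin are seen once; their start positions are reported
    modulo the genome length with ``wrapped=True``.
    """
    seq = genome.sequence
    n = len(seq)
    W = motif.W
    target = seq + seq[: W - 1] if genome.circular and n >= W else seq
    hits = scan_sequence(
        target, motif, scheme, strand_mode=strand_mode, target_id=genome.id, merge=True
    )
    for h in hits:
        if h.start >= n or h.end > n:
            h.wrapped = h.end > n
            h.start = h.start % n
    # duplicates can only arise if a hit is seen in both the head copy and
    # the tail extension; drop exact repeats after normalisation
    seen: set[tuple[int, str]] = set()
    unique: list[MotifHit] = []
    for h in hits:
        key = (h.start, h.strand)
        if key not in seen:
            seen.add(key)
            unique.append(h)
    if annotate:
        from .pipeline import annotate_hits

        unique = annotate_hits(genome, unique)
    return unique


def calibrate_threshold(
    motif: MotifQuery,
    references: Sequence[tuple[str, int]],
    match_score: int = 5,
    mismatch_score: int = -4,
    strand_mode: str = "both",
) -> tuple[int, dict[int, list[int]]]:
    """Derive the acceptance threshold Ts from labelled reference sequences.

    ``references`` is a list of (sequence, expected merged hit count).
    Every integer threshold from W*mismatch to W*match is evaluated; the
    returned Ts is the LARGEST threshold at which each reference yields
    exactly its expected count — the conservative choice, trading missed
    divergent copies for fewer false positives. The full threshold -> hit
    count table (the calibration curve) is returned alongside.
    """
    if not references:
        raise ValueError("need at least one reference sequence")
    W = motif.W
    curve: dict[int, list[int]] = {}
    feasible: list[int] = []
    lo, hi = mismatch_score * W, match_score * W
    for T in range(lo, hi + 1):
        scheme = ScoringScheme(match_score, mismatch_score, Ts=T)
        counts = [
            len(scan_sequence(seq, motif, scheme, strand_mode=strand_mode))
            for seq, _ in references
        ]
        curve[T] = counts
        if all(c == exp for c, (_, exp) in zip(counts, references)):
            feasible.append(T)
    if not feasible:
        ranges = []
        for i, (_, exp) in enumerate(references):
            ok = [T for T, counts in curve.items() if counts[i] == exp]
            ranges.append(
                f"reference {i}: expected {exp}, feasible T "
                + (f"{min(ok)}..{max(ok)}" if ok else "none")
            )
        raise ValueError("no threshold satisfies all references; " + "; ".join(ranges))
    return max(feasible), curve
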