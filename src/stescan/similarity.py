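"""Similarity of putative STEs to the known motif, and upstream flanks.

Two similarity measures are provided: plain ungapped identity over
equal-length windows, and a global pairwise alignment (match +5,
mismatch -4, affine gaps, defaults -10 open / -0.5 extend) whose percent
is matches over ALL alignment columns — gap columns count against
similarity, so a 24-column alignment with 15 matches reports 62.5%.

The 30 bp flank immediately 5' of each hit (on the hit's strand) is also
reported with descriptive adenine statistics: published mytilid STEs sit
downstream of characteristic adenine runs, so the A-fraction and longest
consecutive-A run are useful screening descriptors. No significance test
is attached to them.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio import Align

from .genome_io import reverse_complement
from .scan import MotifHit


@dataclass
class SimilarityRecord:
    hit_ref: str
    aligned_length: int
    matches: int
    pct: float
    flank30: str = ""
    flank_A_fraction: float = 0.0
    flank_longest_A_run: int = 0
    flank_truncated: bool = False


def ungapped_identity(a: str, b: str) -> float:
    """Percent identity of two equal-length strings (exact base equality)."""
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    if not a:
        raise ValueError("empty sequences")
    matches = sum(x == y and x in "ACGT" for x, y in zip(a.upper(), b.upper()))
    return 100.0 * matches / len(a)


def _make_aligner(gap_open: float, gap_extend: float) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 5
    aligner.mismatch_score = -4
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def gapped_similarity(
    a: str,
    b: str,
    gap_open: float = -10.0,
    gap_extend: float = -0.5,
) -> tuple[int, int, float]:
    """Global-alignment similarity: (aligned_length, matches, pct).

    Percent = 100 * matches / alignment columns, so opened gaps lower the
    reported similarity. The optimal alignment is chosen deterministically
    (first traceback of the aligner).
    """
    if not a or not b:
        raise ValueError("empty sequences")
    a, b = a.upper(), b.upper()
    aligner = _make_aligner(gap_open, gap_extend)
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    aligned_length = aln.length
    matches = counts.identities
    return aligned_length, matches, 100.0 * matches / aligned_length


def alignment_score(a: str, b: str, gap_open: float = -10.0, gap_extend: float = -0.5) -> float:
    """Optimal global alignment score under the package scoring scheme."""
    return float(_make_aligner(gap_open, gap_extend).score(a.upper(), b.upper()))


def _longest_a_run(flank: str) -> int:
    runs = re.findall(r"A+", flank.upper())
    return max((len(r) for r in runs), default=0)


def upstream_flank(
    region: str,
    hit: MotifHit,
    flank: int = 30,
    circular: bool = False,
) -> SimilarityRecord:
    """The ``flank`` bp immediately 5' of a hit, on the hit's strand.

    For a forward hit this is the sequence left of the hit start; for a
    reverse hit, the reverse complement of the sequence right of the hit
    end. The flank truncates at the region boundary unless ``circular``.
    The A-fraction uses the nominal flank length as denominator (a
    truncated flank is flagged and its missing part counts as non-A).
    """
    n = len(region)
    if not 0 <= hit.start < n or (not circular and hit.end > n):
        raise ValueError("hit lies outside the region")
    if hit.strand == "+":
        lo = hit.start - flank
        if lo >= 0:
            seq = region[lo : hit.start]
        elif circular:
            seq = region[lo % n :] + region[: hit.start]
        else:
            seq = region[: hit.start]
    else:
        end = hit.end % n if circular and hit.end > n else hit.end
        hi = end + flank
        if hi <= n:
            seq = region[end:hi]
        elif circular:
            seq = region[end:] + region[: hi % n]
        else:
            seq = region[end:]
        seq = reverse_complement(seq)
    truncated = len(seq) < flank
    a_count = seq.upper().count("A")
    return SimilarityRecord(
        hit_ref=f"{hit.target_id}:{hit.start}{hit.strand}",
        aligned_length=hit.W,
        matches=hit.m,
        pct=hit.pct,
        flank30=seq,
        flank_A_fraction=a_count / flank if flank else 0.0,
        flank_longest_A_run=_longest_a_run(seq),
        flank_truncated=truncated,
    )
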