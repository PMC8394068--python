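"""Synthetic annotated mitogenomes with known ground truth.

Every downstream stage (LUR extraction, scanning, calibration, the null
model) is exercised against genomes built here: circular records with a
configurable gene complement, a single long unannotated region (the LUR)
of specified length and base composition, and motif copies planted at
controlled identity. The generator emulates the layout of a typical
bivalve mitogenome — 13 protein-coding genes, 2 rRNAs, 22 tRNAs — but not
codon structure, tRNA folding, or recombination; gene order is fully
configurable because the scan must not depend on it.

Intergenic spacers outside the LUR are a fixed 20 bp low-complexity GC
repeat, so the LUR is unambiguously the longest unannotated stretch and
the ground truth is unique.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from ._seq import decode, encode, revcomp_codes
from .genome_io import BOUNDARY_KINDS, Feature, GenomeRecord
from .null_model import _validate_freqs, generate_background_codes
from .scan import DEFAULT_QUERY, MotifQuery

SPACER = "GC" * 10  # fixed low-complexity intergenic filler

#: (kind, length, strand) template approximating a bivalve mtDNA gene
#: complement: 13 OXPHOS protein genes, 2 rRNAs, 22 tRNAs.
_PCG_LENGTHS = [1536, 690, 783, 1140, 900, 960, 351, 1320, 282, 1650, 480, 678, 156]
_PCG_NAMES = ["cox1", "cox2", "cox3", "cob", "nd1", "nd2", "nd3", "nd4", "nd4l", "nd5", "nd6", "atp6", "atp8"]


def default_gene_template() -> list[tuple[str, int, str]]:
    """13 protein-coding + 2 rRNA + 22 tRNA features, tRNAs interspersed.

    The template ends with the two rRNAs so the trailing LUR is bounded by
    an rRNA on one side and (wrapping the origin) cox1 on the other.
    """
    template: list[tuple[str, int, str]] = []
    trnas = 22
    for i, length in enumerate(_PCG_LENGTHS):
        template.append(("protein_coding", length, "+"))
        for _ in range(2 if i < 9 else 1):  # 2*9 + 4*1 = 22 tRNAs
            if trnas > 0:
                template.append(("tRNA", 66, "+"))
                trnas -= 1
    template.append(("rRNA", 830, "+"))
    template.append(("rRNA", 1250, "+"))
    return template


@dataclass
class SynthSpec:
    """Recipe for one synthetic genome.

    ``planted_copies`` entries are (m, strand, offset): a motif copy with
    exactly ``m`` of W positions identical, installed at ``offset`` within
    the LUR (reverse-complemented on the genome when strand is '-').
    ``rotation`` shifts the sequence origin; a rotation that lands inside
    the LUR produces an origin-wrapping LUR.
    """

    seed: int
    lur_length: int = 1000
    lur_freqs: tuple[float, float, float, float] = (0.30, 0.15, 0.20, 0.35)
    gene_template: list[tuple[str, int, str]] = field(default_factory=default_gene_template)
    planted_copies: list[tuple[int, str, int]] = field(default_factory=list)
    genome_length: int | None = None
    rotation: int = 0
    genome_id: str = "synth"

    def validate(self, W: int) -> None:
        _validate_freqs(self.lur_freqs)
        spans: list[tuple[int, int]] = []
        for m, strand, offset in self.planted_copies:
            if not 0 <= m <= W:
                raise ValueError(f"planted identity count {m} outside [0, {W}]")
            if strand not in ("+", "-"):
                raise ValueError(f"bad strand {strand!r}")
            if offset < 0 or offset + W > self.lur_length:
                raise ValueError(f"planted copy at offset {offset} leaves the LUR")
            spans.append((offset, offset + W))
        spans.sort()
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError("planted copies overlap")
        feat_total = sum(length for _, length, _ in self.gene_template)
        if self.genome_length is not None and feat_total + self.lur_length > self.genome_length:
            raise ValueError("gene template plus LUR exceed genome_length")
        if not self.gene_template:
            raise ValueError("gene template must contain at least one feature")
        if (
            self.gene_template[0][0] not in BOUNDARY_KINDS
            or self.gene_template[-1][0] not in BOUNDARY_KINDS
        ):
            raise ValueError(
                "gene template must start and end with a protein_coding or rRNA "
                "feature so the LUR is uniquely bounded"
            )


@dataclass
class SynthTruth:
    """Ground truth for one synthetic genome (0-based half-open coords)."""

    genome_id: str
    lur_interval: tuple[int, int]
    planted_hits: list[tuple[int, str, int]]  # (genome position, strand, m)


def generate_background(length: int, freqs: Sequence[float], seed: int) -> str:
    """Random nucleotide string of i.i.d. draws from ``freqs`` (T,C,G,A)."""
    rng = np.random.default_rng(seed)
    return decode(generate_background_codes(length, freqs, rng))


def _degrade_motif(motif_codes: np.ndarray, m: int, rng: np.random.Generator) -> np.ndarray:
    """Copy of the motif with exactly W - m mismatching positions.

    Mismatch positions are chosen uniformly without replacement; the
    substituted base is drawn uniformly from the three bases that differ
    from the motif base at that position.
    """
    W = motif_codes.size
    out = motif_codes.copy()
    n_mut = W - m
    positions = rng.choice(W, size=n_mut, replace=False)
    for pos in positions:
        alternatives = [b for b in range(4) if b != motif_codes[pos]]
        out[pos] = alternatives[rng.integers(3)]
    return out


def plant_motif_copy(
    background: str,
    motif: MotifQuery,
    m: int,
    strand: str,
    offset: int,
    seed: int,
) -> str:
    """Overwrite a window of ``background`` with a degraded motif copy.

    The planted window (read on ``strand``) has exactly ``m`` identities to
    the motif; the rest of the background is untouched.
    """
    W = motif.W
    if not 0 <= m <= W:
        raise ValueError(f"m={m} outside [0, {W}]")
    if offset < 0 or offset + W > len(background):
        raise ValueError(f"offset {offset} out of range for background of {len(background)}")
    rng = np.random.default_rng(seed)
    copy = _degrade_motif(motif.codes, m, rng)
    if strand == "-":
        copy = revcomp_codes(copy)
    elif strand != "+":
        raise ValueError(f"bad strand {strand!r}")
    codes = encode(background)
    codes[offset : offset + W] = copy
    return decode(codes)


def generate_annotated_genome(
    spec: SynthSpec, motif: MotifQuery = DEFAULT_QUERY
) -> tuple[GenomeRecord, SynthTruth]:
    """Build a circular annotated genome with a planted-truth LUR.

    Layout: each template feature followed by a fixed 20 bp spacer, then
    the LUR filling the remainder of the circle back to the origin. Any
    slack against an explicit ``genome_length`` widens the spacer before
    the LUR (never the LUR itself). Deterministic per ``spec.seed``.
    """
    spec.validate(motif.W)
    rng = np.random.default_rng(spec.seed)
    parts: list[str] = []
    features: list[Feature] = []
    pos = 0
    n_feat = len(spec.gene_template)
    # slack against an explicit genome_length widens the spacer after the
    # first feature so the LUR stays tightly bounded by its flanking genes
    slack = 0
    if spec.genome_length is not None:
        base = sum(l for _, l, _ in spec.gene_template) + len(SPACER) * (n_feat - 1) + spec.lur_length
        slack = spec.genome_length - base
        if slack < 0:
            raise ValueError("gene template plus spacers plus LUR exceed genome_length")
    for i, (kind, length, strand) in enumerate(spec.gene_template):
        seq = decode(generate_background_codes(length, (0.25, 0.25, 0.25, 0.25), rng))
        features.append(Feature(kind=kind, strand=strand, interval=(pos, pos + length), name=f"{kind}_{i}"))
        parts.append(seq)
        pos += length
        if i < n_feat - 1:  # no spacer between the last feature and the LUR
            pad = len(SPACER) + (slack if i == 0 else 0)
            parts.append(("GC" * (pad // 2 + 1))[:pad])
            pos += pad
    lur_start = pos
    lur = generate_background_codes(spec.lur_length, spec.lur_freqs, rng)
    lur_seq = decode(lur)
    planted: list[tuple[int, str, int]] = []
    for j, (m, strand, offset) in enumerate(spec.planted_copies):
        lur_seq = plant_motif_copy(lur_seq, motif, m, strand, offset, seed=int(rng.integers(2**31)))
        planted.append((lur_start + offset, strand, m))
    parts.append(lur_seq)
    pos += spec.lur_length
    genome_length = pos
    sequence = "".join(parts)
    assert len(sequence) == genome_length

    # truth LUR: with the last template feature a boundary kind and the
    # first feature starting at the origin, the maximal unannotated
    # stretch is exactly the composed segment [lur_start, genome_length)
    truth_start = lur_start
    truth_end = genome_length  # wraps to 0 where feature[0] starts at 0
    rot = spec.rotation % genome_length
    if rot:
        sequence = sequence[rot:] + sequence[:rot]
        features = [
            Feature(
                kind=f.kind,
                strand=f.strand,
                interval=((f.interval[0] - rot) % genome_length, (f.interval[1] - rot) % genome_length or genome_length),
                name=f.name,
            )
            for f in features
        ]
        planted = [((p - rot) % genome_length, strand, m) for p, strand, m in planted]
        truth_start = (truth_start - rot) % genome_length
        truth_end = (truth_end - rot) % genome_length
        if truth_end == 0:
            truth_end = genome_length
    genome = GenomeRecord(
        id=spec.genome_id,
        sequence=sequence,
        circular=True,
        features=features,
        description=f"synthetic bivalve-like mitogenome ({spec.genome_id})",
    )
    truth = SynthTruth(
        genome_id=spec.genome_id,
        lur_interval=(truth_start, truth_end),
        planted_hits=planted,
    )
    return genome, truth


def write_truth_table(truths: Sequence[SynthTruth], path: str | Path) -> None:
    """Truth TSV: genome_id, lur_start, lur_end, hit_pos, strand, identities."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "lur_start", "lur_end", "hit_pos", "strand", "identities"])
        for t in truths:
            s, e = t.lur_interval
            if not t.planted_hits:
                w.writerow([t.genome_id, s, e, "", "", ""])
            for pos, strand, m in t.planted_hits:
                w.writerow([t.genome_id, s, e, pos, strand, m])
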